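"""Similarity/distance statistics and full distance-matrix assembly.

For one ordered sample pair the similarity over the ``k`` retained match
rows is::

    S = sum_i nident_i / sum_i (length_i - gaps_i)

and the distance is ``D = 1 - S``; both are dimensionless ratios of base
pairs.  For two samples the gene match table is used directly; for three or
more, the match tables are first restricted to genes in ideal components of
the gene matches graph so that every pair is compared over the same strictly
orthologous gene set.

A k-mer Jaccard baseline (and a hybrid mode that applies the ideal-component
filter before the baseline) is provided for comparison: the baseline
distance between two samples is one minus the Jaccard similarity of their
k-mer sets, both first intersected with the set of k-mers seen in at least
two samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import orthograph
from .exceptions import EmptyMatchTableError, NoComparableOrthologsError, NoIdealComponentsError
from .hsp import DEFAULT_EVALUE_CUTOFF, builtin_pairwise_hsps, run_reciprocal_blastn
from .matching import GeneMatchTable, gene_match_table
from .transcripts import Transcriptome, select_top_genes

__all__ = [
    "PairStats",
    "DistanceMatrix",
    "similarity_and_distance",
    "pairwise_hsp_tables",
    "match_tables_from_hsps",
    "distance_matrix",
    "matrix_from_match_tables",
    "kmer_jaccard_matrix",
    "hybrid_ideal_then_jaccard",
]


@dataclass(frozen=True)
class PairStats:
    """Aggregated alignment statistics for one sample pair."""

    sum_ident: int
    sum_length: int
    sum_gaps: int
    row_count: int

    @property
    def similarity(self) -> float:
        return self.sum_ident / (self.sum_length - self.sum_gaps)

    @property
    def distance(self) -> float:
        return 1.0 - self.similarity


@dataclass
class DistanceMatrix:
    """Square matrix of pairwise dissimilarities in [0, 1], zero diagonal."""

    sample_ids: list
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        s = len(self.sample_ids)
        if self.values.shape != (s, s):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{s} sample IDs"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def mean_offdiagonal(self) -> float:
        s = len(self.sample_ids)
        mask = ~np.eye(s, dtype=bool)
        return float(self.values[mask].mean())

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.12g")
        return path

    def to_phylip(self, path) -> Path:
        """PHYLIP square (full) distance matrix format."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"{len(self.sample_ids)}\n")
            for sid, row in zip(self.sample_ids, self.values):
                cells = " ".join(f"{v:.12g}" for v in row)
                fh.write(f"{str(sid)[:10]:<10} {cells}\n")
        return path

    def write_metadata(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"sample_ids": [str(s) for s in self.sample_ids], **_plain(self.metadata)},
                fh,
                sort_keys=True,
            )
        return path


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def similarity_and_distance(t: GeneMatchTable) -> tuple[float, float]:
    """``(S, D)`` for one gene match table; raises on an empty table."""
    stats = pair_stats(t)
    return stats.similarity, stats.distance


def pair_stats(t: GeneMatchTable) -> PairStats:
    if not len(t.df):
        raise NoComparableOrthologsError(
            f"no comparable orthologs between {t.sample1_id!r} and "
            f"{t.sample2_id!r}: the gene match table is empty, so the "
            "similarity statistic is undefined"
        )
    df = t.df
    return PairStats(
        sum_ident=int(df["nident"].sum()),
        sum_length=int(df["length"].sum()),
        sum_gaps=int(df["gaps"].sum()),
        row_count=len(df),
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def pairwise_hsp_tables(
    samples: list,
    aligner: str = "builtin",
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    min_identity_fraction: float = 0.7,
    workdir=None,
) -> dict:
    """Forward/reverse HSP tables for every unordered sample pair.

    Keys are index pairs ``(i, j)`` with ``i < j``; the forward table has
    sample ``i`` as query (sample 1 role).
    """
    ids = [t.sample_id for t in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample IDs: {ids}")
    out = {}
    for i, j in combinations(range(len(samples)), 2):
        if aligner == "builtin":
            fwd, rev = builtin_pairwise_hsps(
                samples[i], samples[j], min_identity_fraction=min_identity_fraction
            )
        elif aligner == "blastn":
            fwd, rev = run_reciprocal_blastn(
                samples[i], samples[j], evalue_cutoff=evalue_cutoff, workdir=workdir
            )
        else:
            raise ValueError(f"unknown aligner {aligner!r}")
        out[(i, j)] = (fwd, rev)
    return out


def match_tables_from_hsps(
    hsp_tables: dict, N: int = 1, dedupe_ties: bool = False, swap_orientation: bool = False
) -> dict:
    """Reduce every pair's HSP tables to gene match tables.

    With ``swap_orientation=True`` sample ``j`` takes the sample 1 role,
    which is the opposite of the default (used to probe orientation
    asymmetry of the distance).
    """
    out = {}
    for (i, j), (fwd, rev) in hsp_tables.items():
        if swap_orientation:
            fwd, rev = rev, fwd
        out[(i, j)] = gene_match_table(fwd, rev, N=N, dedupe_ties=dedupe_ties)
    return out


def matrix_from_match_tables(
    tables: dict,
    sample_ids: list,
    mode: str = "ideal_filtered",
) -> tuple[np.ndarray, dict]:
    """Distance values from per-pair match tables.

    Returns ``(values, component_counts)``; the counts dict is empty in
    ``two_sample_direct`` mode.
    """
    s = len(sample_ids)
    values = np.zeros((s, s), dtype=float)
    counts: dict = {}
    if mode == "two_sample_direct":
        if s != 2:
            raise ValueError("two_sample_direct mode requires exactly 2 samples")
        used = tables
    elif mode == "ideal_filtered":
        graph = orthograph.build_graph(list(tables.values()), sample_ids)
        report = orthograph.classify_components(graph)
        pairs = orthograph.ideal_gene_pairs(graph, report)
        counts = dict(report.counts)
        used = {
            key: orthograph.filter_table_to_ideal(t, pairs) for key, t in tables.items()
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    empty = [key for key, t in used.items() if not len(t.df)]
    if empty:
        names = [
            f"({used[key].sample1_id!r}, {used[key].sample2_id!r})" for key in empty
        ]
        raise EmptyMatchTableError(
            "no surviving match rows for sample pair(s): " + ", ".join(names)
        )
    for (i, j), t in used.items():
        _, d = similarity_and_distance(t)
        values[i, j] = values[j, i] = d
    return values, counts


def distance_matrix(
    samples: list,
    n: int = 50000,
    N: int = 1,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    mode: str = "auto",
    aligner: str = "builtin",
    min_identity_fraction: float = 0.7,
    dedupe_ties: bool = False,
    symmetrize: str | None = None,
    workdir=None,
) -> DistanceMatrix:
    """End-to-end distance matrix for two or more transcriptomes.

    ``mode="auto"`` (the default) uses the direct two-sample computation for
    exactly two samples and ideal-component filtering otherwise.  The entry
    for samples ``(i, j)`` with ``i < j`` is computed with sample ``i`` in
    the sample 1 role; ``symmetrize="mean"`` averages the two orientations
    instead.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if mode == "auto":
        mode = "two_sample_direct" if len(samples) == 2 else "ideal_filtered"
    selected = [select_top_genes(t, n) for t in samples]
    ids = [t.sample_id for t in selected]
    hsps = pairwise_hsp_tables(
        selected,
        aligner=aligner,
        evalue_cutoff=evalue_cutoff,
        min_identity_fraction=min_identity_fraction,
        workdir=workdir,
    )
    tables = match_tables_from_hsps(hsps, N=N, dedupe_ties=dedupe_ties)
    values, counts = matrix_from_match_tables(tables, ids, mode=mode)
    if symmetrize == "mean":
        swapped = match_tables_from_hsps(
            hsps, N=N, dedupe_ties=dedupe_ties, swap_orientation=True
        )
        values2, _ = matrix_from_match_tables(swapped, ids, mode=mode)
        values = 0.5 * (values + values2)
    elif symmetrize is not None:
        raise ValueError(f"unknown symmetrize option {symmetrize!r}")
    meta = {
        "n": n,
        "N": N,
        "evalue_cutoff": evalue_cutoff,
        "mode": mode,
        "aligner": aligner,
        "min_identity_fraction": min_identity_fraction,
        "dedupe_ties": dedupe_ties,
        "symmetrize": symmetrize,
        "component_counts": counts,
    }
    return DistanceMatrix(sample_ids=ids, values=values, metadata=meta)


# ---------------------------------------------------------------------------
# k-mer Jaccard baseline and hybrid mode
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _canonical_kmers(t: Transcriptome, k: int) -> set:
    """Distinct canonical k-mers (lexicographic min of strand pair)."""
    out: set = set()
    for iso in t.iter_isotigs():
        seq = iso.sequence
        rc = seq.translate(_COMPLEMENT)[::-1]
        L = len(seq)
        for i in range(L - k + 1):
            km = seq[i : i + k]
            rkm = rc[L - k - i : L - i]
            out.add(km if km <= rkm else rkm)
    return out


def kmer_jaccard_matrix(samples: list, k: int = 21) -> DistanceMatrix:
    """Alignment-free baseline distance: filtered k-mer Jaccard.

    ``D_ij = 1 - |K_i & K_j & V| / |(K_i | K_j) & V|`` where ``V`` is the
    set of k-mers present in at least two samples.  A pair whose filtered
    union is empty is assigned distance 1 with a warning (with only two
    samples the filtered sets coincide and all distances are 0, so three or
    more samples are needed for a non-degenerate result).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    sets = []
    for t in samples:
        ks = _canonical_kmers(t, k)
        if not ks:
            raise ValueError(
                f"k={k} is longer than every sequence of sample {t.sample_id!r}"
            )
        sets.append(ks)
    counts: dict = {}
    for ks in sets:
        for km in ks:
            counts[km] = counts.get(km, 0) + 1
    shared = {km for km, c in counts.items() if c >= 2}
    filtered = [ks & shared for ks in sets]
    s = len(samples)
    values = np.zeros((s, s), dtype=float)
    for i, j in combinations(range(s), 2):
        union = filtered[i] | filtered[j]
        if not union:
            warnings.warn(
                f"empty filtered k-mer union for samples "
                f"({samples[i].sample_id!r}, {samples[j].sample_id!r}); "
                "distance set to 1",
                stacklevel=2,
            )
            d = 1.0
        else:
            d = 1.0 - len(filtered[i] & filtered[j]) / len(union)
        values[i, j] = values[j, i] = d
    ids = [t.sample_id for t in samples]
    return DistanceMatrix(
        sample_ids=ids, values=values, metadata={"mode": "kmer_jaccard", "k": k}
    )


def hybrid_ideal_then_jaccard(
    samples: list,
    n: int = 50000,
    N: int = 1,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    k: int = 21,
    aligner: str = "builtin",
    min_identity_fraction: float = 0.7,
    workdir=None,
) -> DistanceMatrix:
    """Ideal-component gene selection followed by the k-mer baseline."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    selected = [select_top_genes(t, n) for t in samples]
    ids = [t.sample_id for t in selected]
    hsps = pairwise_hsp_tables(
        selected,
        aligner=aligner,
        evalue_cutoff=evalue_cutoff,
        min_identity_fraction=min_identity_fraction,
        workdir=workdir,
    )
    tables = match_tables_from_hsps(hsps, N=N)
    graph = orthograph.build_graph(list(tables.values()), ids)
    report = orthograph.classify_components(graph)
    if report.counts["n_ideal"] == 0:
        raise NoIdealComponentsError(
            "the gene matches graph has no ideal components; the hybrid "
            "baseline has no gene set to work with"
        )
    by_sample = orthograph.ideal_genes_by_sample(graph, report)
    restricted = [t.restrict_to_genes(by_sample[t.sample_id]) for t in selected]
    dm = kmer_jaccard_matrix(restricted, k=k)
    dm.metadata.update(
        {
            "mode": "hybrid_ideal_then_jaccard",
            "n": n,
            "N": N,
            "evalue_cutoff": evalue_cutoff,
            "aligner": aligner,
            "component_counts": dict(report.counts),
        }
    )
    return dm
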