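"""Transcriptome containers, FASTA parsing, and top-``n`` gene selection.

A *transcriptome* here is one sample's set of assembled transcripts
("isotigs"), partitioned into genes (isotig sets).  Each isotig carries a
k-mer coverage value assigned by the assembler; a gene's coverage is the
maximum over its isotigs, and the pipeline starts by keeping only the top
``n`` genes by that coverage.

Two header dialects are supported for resolving the gene/isoform/coverage
structure from FASTA record IDs:

``rnaspades``
    rnaSPAdes-style IDs such as ``NODE_1_length_2661_cov_39.839195_g0_i0``:
    the coverage is the float after ``cov_`` and the trailing ``_g<int>_i<int>``
    names the gene and isoform.

``mapping_file``
    Any other naming, resolved through a tab-separated table with columns
    ``record_id``, ``gene_id``, ``isotig_id`` and an optional ``coverage``
    column (missing coverage defaults to 1.0).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    DuplicateRecordError,
    FastaParseError,
    HeaderSchemeError,
    SequenceAlphabetError,
)

__all__ = [
    "Isotig",
    "Transcriptome",
    "parse_fasta_transcriptome",
    "read_mapping",
    "gene_coverage",
    "select_top_genes",
    "write_fasta",
]

_DNA_ALPHABET = frozenset("ACGTN")

#: Default header dialect: coverage after ``cov_``, gene/isoform at the tail.
RNASPADES_HEADER_RE = re.compile(
    r"cov_(?P<cov>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?).*_g(?P<gene>\d+)_i(?P<iso>\d+)$"
)


@dataclass(frozen=True)
class Isotig:
    """One assembled transcript with its gene/isoform assignment."""

    sample_id: str
    gene_id: object
    isotig_id: object
    sequence: str
    kmer_coverage: float
    record_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SequenceAlphabetError(
                f"isotig ({self.gene_id}, {self.isotig_id}) has an empty sequence"
            )
        seq = self.sequence.upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"isotig ({self.gene_id}, {self.isotig_id}) contains characters "
                f"outside {{A,C,G,T,N}}: {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)
        cov = float(self.kmer_coverage)
        if not math.isfinite(cov) or cov < 0:
            raise ValueError(
                f"isotig ({self.gene_id}, {self.isotig_id}) has invalid "
                f"k-mer coverage {self.kmer_coverage!r}"
            )
        object.__setattr__(self, "kmer_coverage", cov)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Transcriptome:
    """One sample's genes, each a non-empty list of isotigs."""

    sample_id: str
    genes: dict = field(default_factory=dict)

    @classmethod
    def from_isotigs(cls, sample_id: str, isotigs: Iterable[Isotig]) -> "Transcriptome":
        genes: dict = {}
        seen: set = set()
        for iso in isotigs:
            if iso.sample_id != sample_id:
                raise ValueError(
                    f"isotig sample_id {iso.sample_id!r} != transcriptome "
                    f"sample_id {sample_id!r}"
                )
            key = (iso.gene_id, iso.isotig_id)
            if key in seen:
                raise DuplicateRecordError(
                    f"duplicate (gene_id, isotig_id) = {key!r} in sample {sample_id!r}"
                )
            seen.add(key)
            genes.setdefault(iso.gene_id, []).append(iso)
        return cls(sample_id=sample_id, genes=genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_isotigs(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def iter_isotigs(self) -> Iterator[Isotig]:
        for isotigs in self.genes.values():
            yield from isotigs

    def record_id_map(self) -> dict:
        """Map each record ID to its (gene_id, isotig_id) pair."""
        out: dict = {}
        for iso in self.iter_isotigs():
            rid = iso.record_id if iso.record_id is not None else _synthetic_id(iso)
            out[rid] = (iso.gene_id, iso.isotig_id)
        return out

    def restrict_to_genes(self, gene_ids: Iterable) -> "Transcriptome":
        keep = set(gene_ids)
        return Transcriptome(
            sample_id=self.sample_id,
            genes={g: list(v) for g, v in self.genes.items() if g in keep},
        )


def _synthetic_id(iso: Isotig) -> str:
    return (
        f"NODE_{iso.gene_id}_length_{len(iso.sequence)}_"
        f"cov_{iso.kmer_coverage:.6f}_g{iso.gene_id}_i{iso.isotig_id}"
    )


def read_mapping(path) -> pd.DataFrame:
    """Read a record_id -> (gene_id, isotig_id[, coverage]) mapping table."""
    df = pd.read_csv(path, sep="\t", dtype={"record_id": str})
    required = {"record_id", "gene_id", "isotig_id"}
    missing = required - set(df.columns)
    if missing:
        raise HeaderSchemeError(
            f"mapping file {path} lacks required columns: {sorted(missing)}"
        )
    return df


def _parse_rnaspades_header(record_id: str):
    m = RNASPADES_HEADER_RE.search(record_id)
    if m is None:
        raise HeaderSchemeError(
            f"record ID {record_id!r} does not match the rnaspades header scheme "
            "(expected '...cov_<float>..._g<int>_i<int>'); provide a mapping file "
            "for other naming conventions"
        )
    return int(m.group("gene")), int(m.group("iso")), float(m.group("cov"))


def parse_fasta_transcriptome(
    path,
    sample_id: str,
    header_scheme: str = "rnaspades",
    mapping: pd.DataFrame | Mapping | None = None,
) -> Transcriptome:
    """Read one sample's FASTA into a :class:`Transcriptome`.

    Parameters
    ----------
    path
        FASTA file of assembled transcripts.
    sample_id
        Label for the sample; propagated to every isotig.
    header_scheme
        ``"rnaspades"`` (default) or ``"mapping_file"``.
    mapping
        For ``mapping_file``: a DataFrame from :func:`read_mapping`, a path to
        such a TSV, or a dict ``record_id -> (gene_id, isotig_id[, coverage])``.
        Must cover every record in the file.
    """
    path = Path(path)
    if header_scheme not in ("rnaspades", "mapping_file"):
        raise ValueError(f"unknown header_scheme {header_scheme!r}")
    map_lookup = None
    if header_scheme == "mapping_file":
        if mapping is None:
            raise HeaderSchemeError("header_scheme='mapping_file' requires a mapping")
        if isinstance(mapping, (str, Path)):
            mapping = read_mapping(mapping)
        if isinstance(mapping, pd.DataFrame):
            map_lookup = {}
            has_cov = "coverage" in mapping.columns
            for row in mapping.itertuples(index=False):
                cov = float(getattr(row, "coverage")) if has_cov else 1.0
                map_lookup[str(row.record_id)] = (row.gene_id, row.isotig_id, cov)
        else:
            map_lookup = {
                str(k): (v[0], v[1], float(v[2]) if len(v) > 2 else 1.0)
                for k, v in mapping.items()
            }

    isotigs = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FastaParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"no records in FASTA {path}")
    for rec in records:
        rid = rec.id
        if map_lookup is not None:
            if rid not in map_lookup:
                raise HeaderSchemeError(
                    f"record ID {rid!r} not covered by the mapping file"
                )
            gene, iso, cov = map_lookup[rid]
        else:
            gene, iso, cov = _parse_rnaspades_header(rid)
        isotigs.append(
            Isotig(
                sample_id=sample_id,
                gene_id=gene,
                isotig_id=iso,
                sequence=str(rec.seq),
                kmer_coverage=cov,
                record_id=rid,
            )
        )
    return Transcriptome.from_isotigs(sample_id, isotigs)


def gene_coverage(gene: list) -> float:
    """Coverage of a gene: the maximum k-mer coverage among its isotigs."""
    if not gene:
        raise ValueError("gene has no isotigs")
    return max(iso.kmer_coverage for iso in gene)


def _gene_sort_key(gene_id):
    # ascending gene_id tie-break; numeric IDs sort numerically, text IDs
    # lexicographically, and the two kinds never interleave
    if isinstance(gene_id, (int, float)):
        return (0, gene_id, "")
    return (1, 0, str(gene_id))


def select_top_genes(t: Transcriptome, n: int) -> Transcriptome:
    """Keep the ``min(n, n_genes)`` genes with highest coverage.

    Coverage ties at the n-th rank are broken by ascending gene ID, which
    makes the selection deterministic and nested across increasing ``n``.
    All isotigs of a selected gene are retained.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranked = sorted(
        t.genes.items(),
        key=lambda kv: (-gene_coverage(kv[1]), _gene_sort_key(kv[0])),
    )
    keep = ranked[: min(n, len(ranked))]
    return Transcriptome(sample_id=t.sample_id, genes={g: list(v) for g, v in keep})


def write_fasta(t: Transcriptome, path) -> Path:
    """Write a transcriptome to FASTA, preserving original record IDs."""
    path = Path(path)
    records = []
    for iso in t.iter_isotigs():
        rid = iso.record_id if iso.record_id is not None else _synthetic_id(iso)
        records.append(SeqRecord(Seq(iso.sequence), id=rid, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")
    return path
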