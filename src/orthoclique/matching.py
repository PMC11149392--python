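"""Reduce forward/reverse HSP tables to a gene match table.

The four-stage reduction identifies, for each gene of sample 1, its most
likely ortholog in sample 2:

1. per direction, keep the top ``N`` HSPs (by bitscore) for each query gene,
   retaining rows tied with the N-th;
2. re-orient both tables onto (sample 1 gene, sample 2 gene) columns and keep
   only gene pairs present in *both* directions, concatenating the survivors
   (each surviving pair therefore contributes at least two rows);
3. keep the best-bitscore row(s) per gene pair;
4. keep the best-bitscore row(s) per sample 1 gene.

Ties are retained at every stage; ``dedupe_ties=True`` additionally keeps a
single row per surviving gene pair (lowest isotig IDs) for users worried
about double counting in the similarity sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import HspValidationError, SampleMismatchError
from .hsp import HSPTable

__all__ = [
    "MATCH_COLUMNS",
    "GeneMatchTable",
    "select_top_hsps",
    "orient_matches",
    "reciprocal_merge",
    "best_per_gene_pair",
    "best_per_s1_gene",
    "gene_match_table",
]

MATCH_COLUMNS = ["s1gene", "s1iso", "s2gene", "s2iso", "bitscore", "nident", "length", "gaps"]


@dataclass
class GeneMatchTable:
    """Best-ortholog rows for one ordered sample pair."""

    sample1_id: str
    sample2_id: str
    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MATCH_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in MATCH_COLUMNS if c not in self.df.columns]
        if missing:
            raise HspValidationError(f"gene match table lacks columns {missing}")
        self.df = canonical_sort(self.df[MATCH_COLUMNS])

    def __len__(self) -> int:
        return len(self.df)

    def gene_pairs(self) -> set:
        return set(zip(self.df["s1gene"], self.df["s2gene"]))

    def to_tsv(self, path) -> Path:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path, sample1_id: str, sample2_id: str) -> "GeneMatchTable":
        df = pd.read_csv(path, sep="\t")
        return cls(sample1_id=sample1_id, sample2_id=sample2_id, df=df)


def canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order regardless of input ordering."""
    if not len(df):
        return df.reset_index(drop=True)
    key = df.astype({c: str for c in df.columns})
    order = key.sort_values(list(df.columns), kind="mergesort").index
    return df.loc[order].reset_index(drop=True)


def select_top_hsps(t: HSPTable, N: int = 1) -> HSPTable:
    """Keep the top ``N`` HSPs per query gene, plus ties with the N-th."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    df = t.df
    if not len(df):
        return HSPTable(t.query_sample, t.subject_sample, df.copy())

    def threshold(scores: pd.Series) -> float:
        top = scores.nlargest(min(N, len(scores)))
        return top.iloc[-1]

    thr = df.groupby("qgene")["bitscore"].transform(threshold)
    out = df[df["bitscore"] >= thr].reset_index(drop=True)
    return HSPTable(t.query_sample, t.subject_sample, out)


def orient_matches(t: HSPTable, sample1_id: str) -> pd.DataFrame:
    """Rename HSP columns onto (sample 1, sample 2) roles.

    If the table's query sample is *sample1_id* the query columns become the
    sample 1 columns; otherwise the subject columns do.
    """
    df = t.df
    if t.query_sample == sample1_id:
        ren = {"qgene": "s1gene", "qiso": "s1iso", "sgene": "s2gene", "siso": "s2iso"}
    elif t.subject_sample == sample1_id:
        ren = {"qgene": "s2gene", "qiso": "s2iso", "sgene": "s1gene", "siso": "s1iso"}
    else:
        raise SampleMismatchError(
            f"sample {sample1_id!r} is neither query ({t.query_sample!r}) nor "
            f"subject ({t.subject_sample!r}) of this table"
        )
    return df.rename(columns=ren)[MATCH_COLUMNS]


def reciprocal_merge(forward: HSPTable, reverse: HSPTable) -> pd.DataFrame:
    """Keep gene pairs matched in both directions; concatenate survivors."""
    if (
        forward.query_sample != reverse.subject_sample
        or forward.subject_sample != reverse.query_sample
    ):
        raise SampleMismatchError(
            f"forward ({forward.query_sample!r} vs {forward.subject_sample!r}) and "
            f"reverse ({reverse.query_sample!r} vs {reverse.subject_sample!r}) "
            "tables do not describe the same sample pair"
        )
    s1 = forward.query_sample
    fwd = orient_matches(forward, s1)
    rev = orient_matches(reverse, s1)
    fwd_pairs = set(zip(fwd["s1gene"], fwd["s2gene"]))
    rev_pairs = set(zip(rev["s1gene"], rev["s2gene"]))
    both = fwd_pairs & rev_pairs

    def keep(df: pd.DataFrame) -> pd.DataFrame:
        if not len(df):
            return df
        mask = [pair in both for pair in zip(df["s1gene"], df["s2gene"])]
        return df[mask]

    return pd.concat([keep(fwd), keep(rev)], ignore_index=True)


def _max_rows(df: pd.DataFrame, by) -> pd.DataFrame:
    """Rows achieving the maximum bitscore within each group; ties kept."""
    if not len(df):
        return df.reset_index(drop=True)
    top = df.groupby(by)["bitscore"].transform("max")
    return df[df["bitscore"] >= top].reset_index(drop=True)


def best_per_gene_pair(rows: pd.DataFrame) -> pd.DataFrame:
    """Best-bitscore row(s) for each (sample 1 gene, sample 2 gene) pair."""
    return _max_rows(rows, ["s1gene", "s2gene"])


def best_per_s1_gene(rows: pd.DataFrame) -> pd.DataFrame:
    """Best-bitscore row(s) for each sample 1 gene."""
    return _max_rows(rows, ["s1gene"])


def gene_match_table(
    forward: HSPTable,
    reverse: HSPTable,
    N: int = 1,
    dedupe_ties: bool = False,
) -> GeneMatchTable:
    """Full reduction from a forward/reverse HSP table pair.

    The forward table's query sample plays the sample 1 role.
    """
    fwd = select_top_hsps(forward, N)
    rev = select_top_hsps(reverse, N)
    merged = reciprocal_merge(fwd, rev)
    reduced = best_per_s1_gene(best_per_gene_pair(merged))
    if dedupe_ties and len(reduced):
        reduced = (
            reduced.sort_values(
                ["s1gene", "s2gene", "s1iso", "s2iso"],
                key=lambda s: s.astype(str),
                kind="mergesort",
            )
            .drop_duplicates(subset=["s1gene", "s2gene"], keep="first")
            .reset_index(drop=True)
        )
    return GeneMatchTable(
        sample1_id=forward.query_sample,
        sample2_id=forward.subject_sample,
        df=reduced,
    )
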