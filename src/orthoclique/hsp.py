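"""High-scoring segment pair (HSP) tables.

Pairwise HSPs between two samples' selected genes are produced either by
driving external BLASTn in both directions (the production path) or by a
built-in all-vs-all global aligner intended for desk-scale inputs (tests,
simulations).  Either way the result is a pair of tables with one row per
HSP carrying ``(qgene, qiso, sgene, siso, bitscore, nident, length, gaps)``,
where ``gaps`` counts gap *characters* so that ``length - gaps`` is the
number of aligned base pairs and ``nident <= length - gaps`` always holds.
"""

from __future__ import annotations

import math
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .exceptions import (
    BlastNotFoundError,
    BlastRuntimeError,
    HspValidationError,
    SampleMismatchError,
)
from .transcripts import Transcriptome, write_fasta

__all__ = [
    "HSP",
    "HSPTable",
    "HSP_COLUMNS",
    "parse_hsp_table",
    "write_hsp_table",
    "run_reciprocal_blastn",
    "builtin_pairwise_hsps",
]

HSP_COLUMNS = ["qgene", "qiso", "sgene", "siso", "bitscore", "nident", "length", "gaps"]

#: BLAST tabular fields requested so output maps 1:1 onto the row schema.
BLAST_OUTFMT = "6 qseqid sseqid bitscore nident length gaps evalue"

#: Fixed e-value cutoff used throughout: stringent enough that only
#: homologous sequences are reported.
DEFAULT_EVALUE_CUTOFF = 1e-99


@dataclass(frozen=True)
class HSP:
    """One high-scoring segment pair (one local alignment segment)."""

    query_gene: object
    query_isotig: object
    subject_gene: object
    subject_isotig: object
    bitscore: float
    nident: int
    length: int
    gaps: int
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise HspValidationError(f"bitscore must be > 0, got {self.bitscore}")
        if self.length < 1:
            raise HspValidationError(f"length must be >= 1, got {self.length}")
        if not (0 <= self.gaps <= self.length):
            raise HspValidationError(
                f"gaps must satisfy 0 <= gaps <= length, got gaps={self.gaps}, "
                f"length={self.length}"
            )
        if not (0 <= self.nident <= self.length - self.gaps):
            raise HspValidationError(
                f"nident must satisfy 0 <= nident <= length - gaps, got "
                f"nident={self.nident}, length={self.length}, gaps={self.gaps}"
            )


@dataclass
class HSPTable:
    """All HSPs from one directed search (query sample vs subject sample)."""

    query_sample: str
    subject_sample: str
    df: pd.DataFrame = field(default_factory=lambda: _empty_frame())

    def __post_init__(self) -> None:
        if self.query_sample == self.subject_sample:
            raise SampleMismatchError(
                f"query and subject sample must differ, both are "
                f"{self.query_sample!r}"
            )
        missing = [c for c in HSP_COLUMNS if c not in self.df.columns]
        if missing:
            raise HspValidationError(f"HSP table lacks columns {missing}")
        if "evalue" not in self.df.columns:
            self.df = self.df.assign(evalue=np.nan)
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_hsps(cls, query_sample: str, subject_sample: str, hsps) -> "HSPTable":
        rows = [
            (
                h.query_gene,
                h.query_isotig,
                h.subject_gene,
                h.subject_isotig,
                h.bitscore,
                h.nident,
                h.length,
                h.gaps,
                np.nan if h.evalue is None else h.evalue,
            )
            for h in hsps
        ]
        df = pd.DataFrame(rows, columns=HSP_COLUMNS + ["evalue"])
        if not rows:
            df = _empty_frame()
        return cls(query_sample=query_sample, subject_sample=subject_sample, df=df)

    def __len__(self) -> int:
        return len(self.df)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "qgene": pd.Series(dtype=object),
            "qiso": pd.Series(dtype=object),
            "sgene": pd.Series(dtype=object),
            "siso": pd.Series(dtype=object),
            "bitscore": pd.Series(dtype=float),
            "nident": pd.Series(dtype=int),
            "length": pd.Series(dtype=int),
            "gaps": pd.Series(dtype=int),
            "evalue": pd.Series(dtype=float),
        }
    )


def _validate_rows(df: pd.DataFrame, source: str) -> None:
    for col in ("bitscore", "nident", "length", "gaps"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 1
            raise HspValidationError(f"{source}: non-numeric {col!r} at data row {row}")
        df[col] = vals
    bad = ~(
        (df["bitscore"] > 0)
        & (df["length"] >= 1)
        & (df["gaps"] >= 0)
        & (df["gaps"] <= df["length"])
        & (df["nident"] >= 0)
        & (df["nident"] <= df["length"] - df["gaps"])
    )
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise HspValidationError(
            f"{source}: HSP invariant violated at data row {row} "
            "(need bitscore>0, 1<=length, 0<=gaps<=length, 0<=nident<=length-gaps)"
        )


def parse_hsp_table(path, query_sample: str, subject_sample: str) -> HSPTable:
    """Read a tab-separated HSP table (with header row) and validate it."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HSP_COLUMNS if c not in df.columns]
    if missing:
        raise HspValidationError(f"{path}: missing columns {missing}")
    if len(df):
        _validate_rows(df, str(path))
        df["nident"] = df["nident"].astype(int)
        df["length"] = df["length"].astype(int)
        df["gaps"] = df["gaps"].astype(int)
    if "evalue" not in df.columns:
        df["evalue"] = np.nan
    if not len(df):
        df = _empty_frame()
    return HSPTable(query_sample=query_sample, subject_sample=subject_sample, df=df)


def write_hsp_table(table: HSPTable, path) -> Path:
    path = Path(path)
    table.df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# External BLASTn
# ---------------------------------------------------------------------------


def _require_executable(name: str) -> str:
    exe = shutil.which(name)
    if exe is None:
        raise BlastNotFoundError(
            f"required executable {name!r} not found on PATH; install NCBI BLAST+"
        )
    return exe


def _run(cmd: list[str]) -> None:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise BlastRuntimeError(
            f"command {' '.join(cmd)} exited with status {proc.returncode}:\n"
            f"{proc.stderr.strip()}"
        )


def _blastn_one_direction(
    query: Transcriptome,
    subject: Transcriptome,
    db_prefix: Path,
    query_fa: Path,
    evalue_cutoff: float,
    out_tsv: Path,
    task: str | None,
) -> HSPTable:
    cmd = [
        _require_executable("blastn"),
        "-query",
        str(query_fa),
        "-db",
        str(db_prefix),
        "-evalue",
        f"{evalue_cutoff:g}",
        "-outfmt",
        BLAST_OUTFMT,
        "-out",
        str(out_tsv),
    ]
    if task is not None:
        cmd += ["-task", task]
    _run(cmd)
    qmap = query.record_id_map()
    smap = subject.record_id_map()
    rows = []
    with open(out_tsv) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            qid, sid, bits, nident, length, gaps, ev = line.split("\t")
            qgene, qiso = qmap[qid]
            sgene, siso = smap[sid]
            rows.append(
                (
                    qgene,
                    qiso,
                    sgene,
                    siso,
                    float(bits),
                    int(nident),
                    int(length),
                    int(gaps),
                    float(ev),
                )
            )
    df = pd.DataFrame(rows, columns=HSP_COLUMNS + ["evalue"]) if rows else _empty_frame()
    return HSPTable(
        query_sample=query.sample_id, subject_sample=subject.sample_id, df=df
    )


def run_reciprocal_blastn(
    t1: Transcriptome,
    t2: Transcriptome,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    workdir=None,
    task: str | None = None,
) -> tuple[HSPTable, HSPTable]:
    """Run BLASTn in both directions between two transcriptomes.

    Only the e-value cutoff is imposed; all other BLASTn parameters are the
    tool's defaults (``task=None`` leaves the default megablast task).
    Returns ``(forward, reverse)`` where *forward* has ``t1`` as query.
    Intermediate files are written under *workdir* (a temporary directory by
    default) with deterministic names ``<s1>__vs__<s2>.tsv``.
    """
    if t1.n_genes == 0 or t2.n_genes == 0:
        raise ValueError("both transcriptomes must be non-empty")
    _require_executable("makeblastdb")
    own_tmp = workdir is None
    workdir = Path(tempfile.mkdtemp(prefix="orthoclique_blast_")) if own_tmp else Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    try:
        fastas = {}
        dbs = {}
        for t in (t1, t2):
            fa = workdir / f"{t.sample_id}.fasta"
            write_fasta(t, fa)
            db = workdir / f"{t.sample_id}.db"
            _run(
                [
                    _require_executable("makeblastdb"),
                    "-in",
                    str(fa),
                    "-dbtype",
                    "nucl",
                    "-out",
                    str(db),
                ]
            )
            fastas[t.sample_id] = fa
            dbs[t.sample_id] = db
        forward = _blastn_one_direction(
            t1,
            t2,
            dbs[t2.sample_id],
            fastas[t1.sample_id],
            evalue_cutoff,
            workdir / f"{t1.sample_id}__vs__{t2.sample_id}.tsv",
            task,
        )
        reverse = _blastn_one_direction(
            t2,
            t1,
            dbs[t1.sample_id],
            fastas[t2.sample_id],
            evalue_cutoff,
            workdir / f"{t2.sample_id}__vs__{t1.sample_id}.tsv",
            task,
        )
        return forward, reverse
    finally:
        if own_tmp:
            shutil.rmtree(workdir, ignore_errors=True)


# ---------------------------------------------------------------------------
# Built-in desk-scale aligner
# ---------------------------------------------------------------------------

#: Scoring scheme used to assign bitscores to built-in alignments
#: (the gap-opening base costs 5, each further gap base 2).
BUILTIN_SCORING = dict(
    match_score=2.0, mismatch_score=-3.0, open_gap_score=-5.0, extend_gap_score=-2.0
)

#: Below this sequence length the shared-k-mer candidate prefilter is skipped.
_MIN_SEEDED_LENGTH = 25

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(mode="global", **BUILTIN_SCORING)


def alignment_stats(alignment) -> tuple[int, int, int]:
    """Return (nident, length, gaps) read off a Biopython global alignment."""
    c = alignment.counts()
    return int(c.identities), int(alignment.length), int(c.gaps)


def _edlib_align(a: str, b: str):
    """Global alignment via edlib; returns (nident, length, gaps, score).

    The optimal edit path (unit costs) is scored post hoc under
    :data:`BUILTIN_SCORING`.  For the near-identical, substitution-dominated
    sequences this aligner targets, the edit path coincides with the
    affine-scoring optimum; the exact affine core (``core="affine"``) is
    available for cross-checking.
    """
    result = edlib.align(a, b, mode="NW", task="path")
    nident = mismatches = gap_chars = gap_runs = 0
    for count, op in _CIGAR_RE.findall(result["cigar"]):
        count = int(count)
        if op == "=":
            nident += count
        elif op in "XM":
            mismatches += count
        else:  # I or D
            gap_chars += count
            gap_runs += 1
    length = nident + mismatches + gap_chars
    score = (
        BUILTIN_SCORING["match_score"] * nident
        + BUILTIN_SCORING["mismatch_score"] * mismatches
        + BUILTIN_SCORING["open_gap_score"] * gap_runs
        + BUILTIN_SCORING["extend_gap_score"] * (gap_chars - gap_runs)
    )
    return nident, length, gap_chars, score


def _affine_align(a: str, b: str, aligner: Align.PairwiseAligner):
    alignment = aligner.align(a, b)[0]
    nident, length, gaps = alignment_stats(alignment)
    return nident, length, gaps, float(alignment.score)


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def builtin_pairwise_hsps(
    t1: Transcriptome,
    t2: Transcriptome,
    min_identity_fraction: float = 0.7,
    seed_k: int = 11,
    min_seed_matches: int = 3,
    core: str = "edit",
) -> tuple[HSPTable, HSPTable]:
    """All-vs-all global alignment between two small transcriptomes.

    Intended for desk-scale inputs (up to roughly a thousand isotigs per
    sample).  Candidate isotig pairs must share at least ``min_seed_matches``
    distinct forward-strand ``seed_k``-mers (the prefilter is skipped for
    sequences shorter than 25 bp); each candidate pair is globally aligned
    and scored with match +2 / mismatch -3 / gap open -5 / gap extend -2
    (the opening base costs 5, each further base 2).  A pair yields one HSP
    when its identity ``nident / (length - gaps)`` reaches
    ``min_identity_fraction`` and its score is positive; the bitscore is the
    raw alignment score (a proportional stand-in for BLAST bits).

    ``core`` selects the alignment engine: ``"edit"`` (default) takes the
    optimal unit-cost edit path (edlib) and scores it under the scheme
    above — for the near-identical sequences this aligner targets the two
    optima coincide and the edit core is orders of magnitude faster;
    ``"affine"`` optimises the affine scheme itself (Biopython).

    The returned forward/reverse tables are exact mirrors of each other,
    as befits a symmetric scoring scheme.
    """
    if not (0 < min_identity_fraction <= 1):
        raise ValueError("min_identity_fraction must be in (0, 1]")
    if core not in ("edit", "affine"):
        raise ValueError(f"unknown core {core!r}")
    aligner = _make_aligner() if core == "affine" else None
    iso1 = list(t1.iter_isotigs())
    iso2 = list(t2.iter_isotigs())

    index: dict = {}
    for j, iso in enumerate(iso2):
        if len(iso.sequence) >= _MIN_SEEDED_LENGTH:
            for km in _kmer_set(iso.sequence, seed_k):
                index.setdefault(km, []).append(j)
    short2 = [j for j, iso in enumerate(iso2) if len(iso.sequence) < _MIN_SEEDED_LENGTH]

    fwd_rows = []
    for a in iso1:
        if len(a.sequence) < _MIN_SEEDED_LENGTH:
            candidates = range(len(iso2))
        else:
            counts: dict = {}
            for km in _kmer_set(a.sequence, seed_k):
                for j in index.get(km, ()):
                    counts[j] = counts.get(j, 0) + 1
            candidates = [j for j, c in counts.items() if c >= min_seed_matches]
            candidates.extend(short2)
        for j in candidates:
            b = iso2[j]
            if core == "edit":
                nident, length, gaps, score = _edlib_align(a.sequence, b.sequence)
            else:
                nident, length, gaps, score = _affine_align(
                    a.sequence, b.sequence, aligner
                )
            if score <= 0:
                continue
            aligned = length - gaps
            if aligned <= 0 or nident / aligned < min_identity_fraction:
                continue
            fwd_rows.append(
                (
                    a.gene_id,
                    a.isotig_id,
                    b.gene_id,
                    b.isotig_id,
                    score,
                    nident,
                    length,
                    gaps,
                    math.nan,
                )
            )

    fwd_df = (
        pd.DataFrame(fwd_rows, columns=HSP_COLUMNS + ["evalue"])
        if fwd_rows
        else _empty_frame()
    )
    rev_df = fwd_df.rename(
        columns={"qgene": "sgene", "qiso": "siso", "sgene": "qgene", "siso": "qiso"}
    )[HSP_COLUMNS + ["evalue"]]
    forward = HSPTable(
        query_sample=t1.sample_id, subject_sample=t2.sample_id, df=fwd_df
    )
    reverse = HSPTable(
        query_sample=t2.sample_id, subject_sample=t1.sample_id, df=rev_df
    )
    return forward, reverse
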