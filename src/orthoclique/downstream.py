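"""Downstream analyses: neighbor joining, PCoA, tree comparison, sweeps.

Neighbor joining and principal coordinates analysis are implemented to
their textbook definitions (Saitou-Nei agglomeration; classical metric
scaling of the double-centered squared-distance matrix) so that desk-scale
runs carry no extra dependencies; library implementations serve as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import distance as _distance
from . import orthograph
from .distance import DistanceMatrix
from .transcripts import select_top_genes

__all__ = [
    "neighbor_joining",
    "pcoa",
    "robinson_foulds",
    "SweepRecord",
    "sweep_components",
    "write_sweep_tsv",
]


def _as_matrix(m) -> tuple[np.ndarray, list]:
    if isinstance(m, DistanceMatrix):
        return np.asarray(m.values, dtype=float), [str(s) for s in m.sample_ids]
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {arr.shape}")
    return arr, [f"S{i}" for i in range(arr.shape[0])]


def neighbor_joining(m, labels: list | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    The input is symmetrized by averaging with its transpose first.  The
    minimum-Q pair is chosen with a lowest-index tie-break; negative branch
    lengths (possible for noisy, non-additive input) are clamped to zero.
    For two samples the result is a single edge carrying the distance.
    """
    D, default_labels = _as_matrix(m)
    labels = [str(x) for x in labels] if labels is not None else default_labels
    s = D.shape[0]
    if len(labels) != s:
        raise ValueError("label count does not match matrix size")
    D = 0.5 * (D + D.T)
    if s < 2:
        raise ValueError("need at least 2 samples")
    if s == 2:
        newick = f"({labels[0]}:{D[0, 1] / 2:.10g},{labels[1]}:{D[0, 1] / 2:.10g});"
        return _read_unrooted(newick)

    dist = {(i, j): D[i, j] for i in range(s) for j in range(i + 1, s)}

    def d(i, j):
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(s))
    subtree = {i: f"{labels[i]}" for i in range(s)}
    nxt = s
    while len(active) > 3:
        r = len(active)
        totals = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for i, j in combinations(active, 2):
            q = (r - 2) * d(i, j) - totals[i] - totals[j]
            if best is None or q < best[0] - 1e-12:
                best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = d(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        subtree[nxt] = f"({subtree[i]}:{li:.10g},{subtree[j]}:{lj:.10g})"
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, nxt), max(k, nxt))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [a for a in active if a not in (i, j)] + [nxt]
        nxt += 1
    i, j, k = active
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    newick = (
        f"({subtree[i]}:{max(li, 0.0):.10g},{subtree[j]}:{max(lj, 0.0):.10g},"
        f"{subtree[k]}:{max(lk, 0.0):.10g});"
    )
    return _read_unrooted(newick)


def _read_unrooted(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def pcoa(m, dims: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling (principal coordinates analysis).

    Double-centers ``-0.5 * D**2``, eigendecomposes, and returns the top
    *dims* coordinate axes ordered by eigenvalue together with the full
    eigenvalue spectrum.  Axes with negative eigenvalues (non-Euclidean
    input) are reported in the spectrum but never returned as coordinates;
    *dims* greater than ``s - 1`` is clamped with a warning.
    """
    D, labels = _as_matrix(m)
    s = D.shape[0]
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims > s - 1:
        warnings.warn(f"dims={dims} clamped to s-1={s - 1}", stacklevel=2)
        dims = max(s - 1, 1)
    D = 0.5 * (D + D.T)
    J = np.eye(s) - np.full((s, s), 1.0 / s)
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = min(dims, int((eigvals > 1e-12).sum()))
    coords = eigvecs[:, :keep] * np.sqrt(eigvals[:keep])
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{i + 1}" for i in range(keep)]
    )
    return frame, eigvals


def _nontrivial_splits(tree: dendropy.Tree) -> tuple[set, frozenset]:
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else leaves - below
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits, leaves


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance: non-trivial splits in exactly one tree.

    Zero if and only if the two trees are topologically identical (as
    unrooted trees).  Both trees must carry the same leaf label set.
    """
    s1, leaves1 = _nontrivial_splits(t1)
    s2, leaves2 = _nontrivial_splits(t2)
    if leaves1 != leaves2:
        raise ValueError(
            f"leaf label sets differ: only in first {sorted(leaves1 - leaves2)}, "
            f"only in second {sorted(leaves2 - leaves1)}"
        )
    return len(s1 ^ s2)


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepRecord:
    """Component counts for one (n, sample subset) pipeline run."""

    n: int
    s: int
    subset: tuple
    n_small: int
    n_large: int
    n_ideal: int
    n_large_nonideal: int


def _counts_for_subset(match_tables: dict, ids: list, subset_idx: tuple) -> dict:
    keep = set(subset_idx)
    sub_ids = [ids[i] for i in subset_idx]
    tables = [t for (i, j), t in match_tables.items() if i in keep and j in keep]
    graph = orthograph.build_graph(tables, sub_ids)
    return orthograph.classify_components(graph).counts


def sweep_components(
    samples: list,
    n_values: list,
    subset_strategy: str = "all",
    permutation: list | None = None,
    time_budget: float | None = None,
    trials_per_size: int | None = None,
    seed: int | None = None,
    aligner: str = "builtin",
    N: int = 1,
    evalue_cutoff: float = _distance.DEFAULT_EVALUE_CUTOFF,
    min_identity_fraction: float = 0.7,
) -> list:
    """Record gene-matches-graph component counts over ``n`` and subsets.

    Strategies: ``all`` uses the full sample set once per ``n``; ``prefix``
    uses the size-2..s prefixes of *permutation* (nested subsets, so the
    ideal count is exactly non-increasing in s); ``fair`` draws subsets
    uniformly at random per size and allocates trials so the time spent per
    size is approximately equal (sizes with lower accumulated cost are tried
    first, using running per-size mean runtimes), stopping on *time_budget*
    seconds or *trials_per_size* trials per size.

    Match tables for the full sample set are computed once per ``n`` and
    shared by every subset, which leaves pairwise tables identical across
    nested subsets by construction.
    """
    ids = [t.sample_id for t in samples]
    s_total = len(samples)
    if subset_strategy == "prefix":
        if permutation is None:
            raise ValueError("prefix strategy requires a permutation of sample IDs")
        perm_idx = [ids.index(p) for p in permutation]
        if len(perm_idx) > s_total:
            raise ValueError("permutation longer than the sample list")
    if subset_strategy == "fair":
        if time_budget is None and trials_per_size is None:
            raise ValueError("fair strategy requires time_budget or trials_per_size")
        rng = np.random.default_rng(seed)

    records = []
    for n in n_values:
        selected = [select_top_genes(t, n) for t in samples]
        hsps = _distance.pairwise_hsp_tables(
            selected,
            aligner=aligner,
            evalue_cutoff=evalue_cutoff,
            min_identity_fraction=min_identity_fraction,
        )
        tables = _distance.match_tables_from_hsps(hsps, N=N)

        def record(subset_idx: tuple) -> None:
            counts = _counts_for_subset(tables, ids, subset_idx)
            records.append(
                SweepRecord(
                    n=n,
                    s=len(subset_idx),
                    subset=tuple(ids[i] for i in subset_idx),
                    **counts,
                )
            )

        if subset_strategy == "all":
            record(tuple(range(s_total)))
        elif subset_strategy == "prefix":
            for size in range(2, len(perm_idx) + 1):
                record(tuple(perm_idx[:size]))
        elif subset_strategy == "fair":
            sizes = list(range(2, s_total + 1))
            spent = {k: 0.0 for k in sizes}
            trials = {k: 0 for k in sizes}
            start = time.monotonic()
            while True:
                open_sizes = [
                    k
                    for k in sizes
                    if trials_per_size is None or trials[k] < trials_per_size
                ]
                if not open_sizes:
                    break
                if time_budget is not None and time.monotonic() - start > time_budget:
                    break
                size = min(open_sizes, key=lambda k: spent[k])
                subset_idx = tuple(sorted(rng.choice(s_total, size=size, replace=False)))
                t0 = time.monotonic()
                record(subset_idx)
                spent[size] += time.monotonic() - t0
                trials[size] += 1
                if time_budget is None and trials_per_size is None:
                    break
        else:
            raise ValueError(f"unknown subset_strategy {subset_strategy!r}")
    return records


def write_sweep_tsv(records: list, path) -> Path:
    path = Path(path)
    rows = [
        (
            r.n,
            r.s,
            ";".join(map(str, r.subset)),
            r.n_small,
            r.n_large,
            r.n_ideal,
            r.n_large_nonideal,
        )
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["n", "s", "subset", "n_small", "n_large", "n_ideal", "n_large_nonideal"],
    ).to_csv(path, sep="\t", index=False)
    return path
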