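"""Synthetic transcriptome generator with a known phylogeny.

The generator reproduces a standard validation design for distance methods:
a birth-death tree over ``n_taxa`` extant taxa, i.i.d. random root
transcripts, substitution-only HKY85 evolution of every transcript down the
tree (branch length times ``site_rate`` is the expected number of
substitutions per site), and per-taxon transcriptome FASTA emission in the
rnaSPAdes header convention with synthetic per-isotig coverage values so
that top-``n`` gene selection is exercised downstream.  Each simulated gene
has exactly one transcript (isotig) per taxon, and the true ortholog
correspondences are recorded for scoring.

All randomness flows from a single seed through named substreams (tree,
lengths, roots, evolution, coverage), so each stage is independently
reproducible.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from dendropy.simulate import treesim
from dendropy.utility.error import TreeSimTotalExtinctionException
from scipy.linalg import expm

from .exceptions import SimulationError
from .transcripts import Isotig, Transcriptome, write_fasta

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_birth_death_tree",
    "balanced_binary_tree",
    "sample_root_transcripts",
    "hky85_rate_matrix",
    "evolve_hky85",
    "simulate_transcriptomes",
    "emit_transcriptomes",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SUBSTREAMS = ("tree", "lengths", "roots", "evolution", "coverage")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults are the full-scale validation design: 16 extant taxa from a
    birth-death process (birth 1, death 0.5), 50000 transcripts, HKY85 with
    site rate 0.01.  Tests and examples scale ``n_taxa``/``n_transcripts``
    down; the model stays the same.
    """

    birth_rate: float = 1.0
    death_rate: float = 0.5
    n_taxa: int = 16
    n_transcripts: int = 50000
    site_rate: float = 0.01
    kappa: float = 3.0
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    length_distribution: object = None  # None -> bundled log-normal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if self.site_rate < 0 or not math.isfinite(self.site_rate):
            raise ValueError("site_rate must be finite and >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        freqs = tuple(float(f) for f in self.base_freqs)
        if len(freqs) != 4 or abs(sum(freqs) - 1.0) > 1e-9 or min(freqs) < 0:
            raise ValueError("base_freqs must be 4 non-negative reals summing to 1")
        object.__setattr__(self, "base_freqs", freqs)

    def substream(self, name: str) -> np.random.Generator:
        idx = _SUBSTREAMS.index(name)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return np.random.default_rng(ss)

    def to_dict(self) -> dict:
        return {
            "birth_rate": self.birth_rate,
            "death_rate": self.death_rate,
            "n_taxa": self.n_taxa,
            "n_transcripts": self.n_transcripts,
            "site_rate": self.site_rate,
            "kappa": self.kappa,
            "base_freqs": list(self.base_freqs),
            "length_distribution": (
                None
                if self.length_distribution is None
                else [list(map(float, x)) for x in self.length_distribution]
            ),
            "seed": self.seed,
        }


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: dendropy.Tree
    transcriptomes: list = field(default_factory=list)
    ortholog_map: pd.DataFrame | None = None


def simulate_birth_death_tree(cfg: SimulationConfig, max_attempts: int = 1000) -> dendropy.Tree:
    """Birth-death tree run until exactly ``cfg.n_taxa`` extant taxa exist.

    Deterministic given ``cfg.seed``.  Full-lineage extinction triggers a
    retry; after *max_attempts* failed attempts a :class:`SimulationError`
    is raised advising different rates.
    """
    seed = int(cfg.substream("tree").integers(0, 2**31 - 1))
    rng = random.Random(seed)
    for _ in range(max_attempts):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=cfg.birth_rate,
                death_rate=cfg.death_rate,
                num_extant_tips=cfg.n_taxa,
                rng=rng,
                repeat_until_success=False,
            )
        except TreeSimTotalExtinctionException:
            continue
        return tree
    raise SimulationError(
        f"no surviving tree with {cfg.n_taxa} extant taxa after {max_attempts} "
        f"attempts (birth={cfg.birth_rate}, death={cfg.death_rate}); "
        "consider a birth rate further above the death rate"
    )


def balanced_binary_tree(n_taxa: int, height: float) -> dendropy.Tree:
    """Fully balanced ultrametric tree (``n_taxa`` a power of two).

    Every edge at a given level has the same length and every root-to-leaf
    path has length *height*, so the maximum leaf-to-leaf path is
    ``2 * height``.  Useful as a designated fixed topology for controlled
    rate sweeps, where a random birth-death tree would confound the sweep
    with tree-depth variation.
    """
    levels = int(math.log2(n_taxa))
    if 2**levels != n_taxa:
        raise ValueError(f"n_taxa must be a power of two, got {n_taxa}")
    edge = height / levels
    labels = iter(f"T{i + 1}" for i in range(n_taxa))

    def build(depth: int) -> str:
        if depth == levels:
            return f"{next(labels)}:{edge:.10g}"
        left = build(depth + 1)
        right = build(depth + 1)
        if depth == 0:
            return f"({left},{right})"
        return f"({left},{right}):{edge:.10g}"

    newick = build(0) + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


_DEFAULT_LOGNORMAL = dict(median=500.0, sigma=0.7, minimum=200)


def sample_root_transcripts(cfg: SimulationConfig) -> list:
    """Random root sequences: i.i.d. bases, lengths from the configured law.

    ``length_distribution`` may be ``(lengths, weights)`` (an empirical
    frequency distribution) or ``None`` for the bundled log-normal fit
    (median 500 bp, sigma 0.7, minimum 200 bp), a stand-in with the same
    median and right tail shape as real plant transcriptome length spreads.
    """
    len_rng = cfg.substream("lengths")
    root_rng = cfg.substream("roots")
    if cfg.length_distribution is None:
        mu = math.log(_DEFAULT_LOGNORMAL["median"])
        draws = np.exp(len_rng.normal(mu, _DEFAULT_LOGNORMAL["sigma"], cfg.n_transcripts))
        lengths = np.maximum(np.rint(draws).astype(int), _DEFAULT_LOGNORMAL["minimum"])
    else:
        lengths_list, weights = cfg.length_distribution
        lengths_arr = np.asarray(list(lengths_list), dtype=int)
        weights_arr = np.asarray(list(weights), dtype=float)
        if lengths_arr.size == 0:
            raise ValueError("empty length distribution")
        weights_arr = weights_arr / weights_arr.sum()
        lengths = len_rng.choice(lengths_arr, size=cfg.n_transcripts, p=weights_arr)
    seqs = []
    p = np.asarray(cfg.base_freqs)
    for L in lengths:
        states = root_rng.choice(4, size=int(L), p=p)
        seqs.append(_BASES[states].tobytes().decode("ascii"))
    return seqs


def hky85_rate_matrix(kappa: float, base_freqs) -> np.ndarray:
    """HKY85 generator matrix normalized to one expected event per unit time.

    Base order A, C, G, T; transitions (A<->G, C<->T) are ``kappa`` times
    faster than transversions.
    """
    pi = np.asarray(base_freqs, dtype=float)
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu > 0:
        Q /= mu
    return Q


def _encode(seqs: list) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in seqs], dtype=int)
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    states = np.empty(raw.size, dtype=np.uint8)
    for code, byte in enumerate(_BASES):
        states[raw == byte] = code
    return states, lengths


def _mutate(states: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(states)
    cum = np.cumsum(P, axis=1)
    u = rng.random(states.size)
    for parent in range(4):
        mask = states == parent
        if not mask.any():
            continue
        out[mask] = np.searchsorted(cum[parent], u[mask], side="right")
    return np.minimum(out, 3).astype(np.uint8)


def evolve_hky85(tree: dendropy.Tree, roots: list, cfg: SimulationConfig) -> dict:
    """Evolve every root transcript down the tree; no indels.

    Returns a mapping ``taxon label -> list of sequences`` (one per root,
    same order and lengths).  The expected number of substitutions per site
    along a branch is ``branch_length * cfg.site_rate``.
    """
    rng = cfg.substream("evolution")
    Q = hky85_rate_matrix(cfg.kappa, cfg.base_freqs)
    root_states, lengths = _encode(roots)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    leaf_seqs: dict = {}

    def visit(node, states):
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * cfg.site_rate
            if t > 0:
                P = expm(Q * t)
                child_states = _mutate(states, P, rng)
            else:
                child_states = states
            if child.is_leaf():
                text = _BASES[child_states].tobytes().decode("ascii")
                leaf_seqs[child.taxon.label] = [
                    text[bounds[k] : bounds[k + 1]] for k in range(len(roots))
                ]
            else:
                visit(child, child_states)

    root = tree.seed_node
    if root.is_leaf():  # degenerate single-node tree
        raise SimulationError("tree has no internal structure to evolve over")
    visit(root, root_states)
    return leaf_seqs


def transcriptomes_from_leaf_sequences(
    leaf_seqs: dict, cfg: SimulationConfig
) -> tuple[list, pd.DataFrame]:
    """Package evolved sequences as per-taxon transcriptomes plus truth map.

    Gene IDs are the transcript indices; every taxon gets one isotig (i0)
    per gene with a synthetic k-mer coverage drawn log-uniform in [1, 1000]
    (shared across taxa for a gene, as read support tracks the gene).
    """
    cov_rng = cfg.substream("coverage")
    n = cfg.n_transcripts
    coverages = np.exp(cov_rng.uniform(np.log(1.0), np.log(1000.0), size=n))
    transcriptomes = []
    rows = []
    for taxon in sorted(leaf_seqs, key=_taxon_sort_key):
        seqs = leaf_seqs[taxon]
        isotigs = []
        for g, seq in enumerate(seqs):
            rid = f"NODE_{g + 1}_length_{len(seq)}_cov_{coverages[g]:.6f}_g{g}_i0"
            isotigs.append(
                Isotig(
                    sample_id=taxon,
                    gene_id=g,
                    isotig_id=0,
                    sequence=seq,
                    kmer_coverage=float(coverages[g]),
                    record_id=rid,
                )
            )
            rows.append((g, taxon, rid))
        transcriptomes.append(Transcriptome.from_isotigs(taxon, isotigs))
    ortholog_map = pd.DataFrame(rows, columns=["gene_id", "taxon", "record_id"])
    return transcriptomes, ortholog_map


def _taxon_sort_key(label: str):
    if label.startswith("T") and label[1:].isdigit():
        return (0, int(label[1:]), label)
    return (1, 0, label)


def simulate_transcriptomes(
    cfg: SimulationConfig, tree: dendropy.Tree | None = None
) -> SimulationResult:
    """Full generator: tree (unless given), roots, evolution, packaging."""
    if tree is None:
        tree = simulate_birth_death_tree(cfg)
        n_leaves = len(tree.leaf_nodes())
    else:
        n_leaves = len(tree.leaf_nodes())
        if n_leaves != cfg.n_taxa:
            cfg = replace(cfg, n_taxa=n_leaves)
    roots = sample_root_transcripts(cfg)
    leaf_seqs = evolve_hky85(tree, roots, cfg)
    transcriptomes, ortholog_map = transcriptomes_from_leaf_sequences(leaf_seqs, cfg)
    return SimulationResult(
        config=cfg, tree=tree, transcriptomes=transcriptomes, ortholog_map=ortholog_map
    )


def emit_transcriptomes(result: SimulationResult, outdir) -> dict:
    """Write per-taxon FASTAs, ground-truth newick, ortholog map, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {"fastas": {}}
    for t in result.transcriptomes:
        fa = outdir / f"{t.sample_id}.fasta"
        write_fasta(t, fa)
        paths["fastas"][t.sample_id] = fa
    truth = outdir / "ground_truth.nwk"
    result.tree.write(path=str(truth), schema="newick")
    paths["tree"] = truth
    omap = outdir / "ortholog_map.tsv"
    result.ortholog_map.to_csv(omap, sep="\t", index=False)
    paths["ortholog_map"] = omap
    cfgpath = outdir / "config.yaml"
    with open(cfgpath, "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=True)
    paths["config"] = cfgpath
    return paths
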