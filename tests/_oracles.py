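"""Brute-force reference implementations used only as test oracles.

Each function applies the relevant definitions literally (plain loops over
rows, vertices, or k-mers) and stays independent of the library code paths
it is used to check.
"""

from itertools import combinations


def reduce_match_tables_bruteforce(fwd_rows, rev_rows, N=1):
    """Literal four-stage reduction of forward/reverse HSP row dicts.

    Rows are dicts with keys qgene, qiso, sgene, siso, bitscore, nident,
    length, gaps; the forward table's query sample plays the sample 1 role.
    Returns a sorted list of (s1gene, s1iso, s2gene, s2iso, bitscore,
    nident, length, gaps) tuples.
    """

    def top_n(rows):
        kept = []
        for gene in {r["qgene"] for r in rows}:
            group = [r for r in rows if r["qgene"] == gene]
            scores = sorted((r["bitscore"] for r in group), reverse=True)
            threshold = scores[min(N, len(scores)) - 1]
            kept.extend(r for r in group if r["bitscore"] >= threshold)
        return kept

    fwd = [
        dict(
            s1gene=r["qgene"], s1iso=r["qiso"], s2gene=r["sgene"], s2iso=r["siso"],
            bitscore=r["bitscore"], nident=r["nident"], length=r["length"],
            gaps=r["gaps"],
        )
        for r in top_n(fwd_rows)
    ]
    rev = [
        dict(
            s1gene=r["sgene"], s1iso=r["siso"], s2gene=r["qgene"], s2iso=r["qiso"],
            bitscore=r["bitscore"], nident=r["nident"], length=r["length"],
            gaps=r["gaps"],
        )
        for r in top_n(rev_rows)
    ]
    fwd_pairs = {(r["s1gene"], r["s2gene"]) for r in fwd}
    rev_pairs = {(r["s1gene"], r["s2gene"]) for r in rev}
    both = fwd_pairs & rev_pairs
    merged = [r for r in fwd + rev if (r["s1gene"], r["s2gene"]) in both]

    per_pair = []
    for pair in {(r["s1gene"], r["s2gene"]) for r in merged}:
        group = [r for r in merged if (r["s1gene"], r["s2gene"]) == pair]
        best = max(r["bitscore"] for r in group)
        per_pair.extend(r for r in group if r["bitscore"] == best)

    final = []
    for gene in {r["s1gene"] for r in per_pair}:
        group = [r for r in per_pair if r["s1gene"] == gene]
        best = max(r["bitscore"] for r in group)
        final.extend(r for r in group if r["bitscore"] == best)

    return sorted(
        (
            r["s1gene"], r["s1iso"], r["s2gene"], r["s2iso"],
            r["bitscore"], r["nident"], r["length"], r["gaps"],
        )
        for r in final
    )


def classify_components_bruteforce(vertices, edges, num_samples):
    """Naive component classification by BFS plus all-pairs adjacency probes.

    Returns a list of (frozenset component, class string) plus the count
    dict, with ideality decided by probing every vertex pair for adjacency.
    """
    adjacency = {v: set() for v in vertices}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    unseen = set(vertices)
    out = []
    counts = {"n_small": 0, "n_large": 0, "n_ideal": 0}
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nb in adjacency[node]:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        unseen -= comp
        if len(comp) < num_samples:
            cls = "small"
            counts["n_small"] += 1
        else:
            counts["n_large"] += 1
            complete = all(v in adjacency[u] for u, v in combinations(comp, 2))
            cls = "ideal" if (complete and len(comp) == num_samples) else "large"
            if cls == "ideal":
                counts["n_ideal"] += 1
        out.append((frozenset(comp), cls))
    counts["n_large_nonideal"] = counts["n_large"] - counts["n_ideal"]
    return out, counts


def kmer_jaccard_bruteforce(samples_seqs, k):
    """Filtered k-mer Jaccard distances by exhaustive set construction.

    ``samples_seqs`` is a list of sequence lists (one per sample); returns a
    dict {(i, j): distance} over i < j.
    """
    comp = str.maketrans("ACGTN", "TGCAN")

    def canon(km):
        rc = km.translate(comp)[::-1]
        return min(km, rc)

    sets = []
    for seqs in samples_seqs:
        ks = set()
        for seq in seqs:
            for i in range(len(seq) - k + 1):
                ks.add(canon(seq[i : i + k]))
        sets.append(ks)
    shared = set()
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if i < j:
                shared |= a & b
    out = {}
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a = sets[i] & shared
            b = sets[j] & shared
            union = a | b
            out[(i, j)] = 1.0 if not union else 1.0 - len(a & b) / len(union)
    return out
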