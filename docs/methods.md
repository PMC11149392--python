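# Methods

## The distance

Each sample is an assembled RNA-seq transcriptome: a set of transcripts
("isotigs") partitioned into genes (isotig sets), each isotig carrying the
assembler's k-mer coverage. A gene's coverage is the maximum over its
isotigs, and only the top *n* genes by coverage enter the analysis
(default *n* = 50000); genes with low read support rarely have orthologs
recoverable in every sample, so the tail mostly adds compute.

For a pair of samples, the selected genes are compared by BLASTn in both
directions. Every high-scoring segment pair (HSP) is one table row:
`(qgene, qiso, sgene, siso, bitscore, nident, length, gaps)`, with `gaps`
counting gap characters so `length − gaps` is the number of aligned base
pairs. The reduction to one best ortholog per sample-1 gene proceeds in
four stages: top-*N* HSPs per query gene per direction (default *N* = 1,
ties with the N-th kept); re-orientation onto (sample 1 gene, sample 2
gene) columns and retention of gene pairs found in *both* directions
(survivors of both tables are concatenated, so each pair keeps at least
two rows); best bitscore per gene pair; best bitscore per sample-1 gene.
Ties are retained throughout and all tied rows contribute to the sums
below; `dedupe_ties` collapses them to one row per gene pair (lowest
isotig IDs) for users worried about double counting.

Over the `k` retained rows the similarity and distance are

    S = Σ ι_i / Σ (λ_i − γ_i),        D = 1 − S,

with ι, λ, γ the identical bases, alignment length and gap characters of
row *i* — a dimensionless ratio of base pairs. An empty table is an
error, not S = 0: the statistic is undefined without comparable
orthologs.

With three or more samples, per-pair best-match gene sets differ between
pairs, which makes naive pairwise application unfair. The gene matches
graph fixes this: one vertex per (sample, gene), an edge exactly when the
gene pair appears in that sample pair's match table. A connected
component is *small* if it has fewer vertices than samples, *large*
otherwise, and *ideal* if it is a clique with exactly one gene per sample
— equivalently (because no edge joins genes of one sample) a complete
component with exactly *s* vertices. Match tables are restricted to gene
pairs inside ideal components before the similarity is computed, so every
pair of samples is compared over the same strictly orthologous gene set.
Completeness is decided by edge-count equality (`s(s−1)/2`), which equals
the all-pairs adjacency probe kept as the test oracle.

Orientation: for the matrix entry (i, j) with i < j, sample i takes the
"sample 1" role (samples ordered as given by the user). The statistic is
not provably symmetric; `symmetrize="mean"` recomputes the reduction with
roles swapped and averages the two orientations.

## Aligners

Production HSPs come from NCBI BLAST+ (`makeblastdb` + `blastn`), with
only the e-value cutoff imposed (default 1e−99, stringent enough that
only homologous sequences pass) and every other parameter left at the
tool's default, including the default megablast task. Gene and isotig
identifiers are recovered from the sequence IDs.

The built-in aligner exists so the complete pipeline can run at desk
scale (tests, simulations) without external processes. It performs
all-vs-all global alignment between two samples' isotigs with a
shared-k-mer candidate prefilter: a pair is aligned only if it shares at
least 3 distinct forward-strand 11-mers (skipped below 25 bp). Candidates
are aligned on the optimal unit-cost edit path (edlib) and the path is
scored as match +2, mismatch −3, gap open −5, gap extend −2 (opening base
5, each further base 2); an HSP is emitted when identity
`ι/(λ−γ)` ≥ `min_identity_fraction` (default 0.7) and the score is
positive, with the raw score standing in for the bitscore. An exact
affine-optimum core (Biopython `PairwiseAligner`, same scoring) is
available via `core="affine"` and is cross-checked against the edit core
in the tests; the two disagree only at divergences well beyond the
identity threshold's working range. The default identity floor of 0.7
plays the role the e-value cutoff plays for BLAST: on transcripts of a
few hundred bp, an e-value of 1e−99 under megablast scoring corresponds
to roughly 80% identity, so 0.7 is comparable and slightly permissive.
The built-in aligner searches the forward strand only — simulated
transcripts are emitted stranded — whereas BLASTn searches both.

## The k-mer baseline and hybrid mode

The alignment-free baseline distance between samples i and j is
`1 − |K_i ∩ K_j ∩ V| / |(K_i ∪ K_j) ∩ V|`, where K are the samples'
canonical k-mer sets (lexicographic minimum of a k-mer and its reverse
complement; default k = 21, both conventional choices) and V is the set
of k-mers present in at least two samples. With exactly two samples the
filtered sets coincide and all distances are zero, so three or more
samples are needed for a non-degenerate result; a pair with an empty
filtered union gets distance 1 with a warning rather than an error so
whole-matrix runs survive. The hybrid mode first restricts each sample to
genes in ideal components, then applies the baseline.

## The simulator

The generator reproduces a standard validation design: a birth-death tree
(birth 1, death 0.5) run until exactly `n_taxa` extant taxa (default 16),
i.i.d. uniform-base root transcripts (default 50000), and substitution-only
HKY85 evolution down the tree, with `branch length × site_rate` the
expected substitutions per site (default rate 0.01). κ (transition/
transversion rate ratio) and base frequencies are not pinned by the design
and default to 3.0 and uniform — conventional values, fully configurable.
Transcript lengths default to a log-normal law (median 500 bp, σ = 0.7,
minimum 200 bp), a bundled stand-in with the median and right tail of
real plant transcriptome length spreads; an empirical length/weight table
can be supplied instead. Emitted FASTAs use rnaSPAdes-style headers with
one isotig per gene and log-uniform coverages on [1, 1000] so top-n
selection is exercised, and the true ortholog map and newick tree are
written alongside. All randomness derives from one seed through named
substreams (tree, lengths, roots, evolution, coverage).

What the simulator does *not* model: indels, paralogy/homeology,
alternative splicing, sequencing error, or assembly artifacts. Passing
tests on simulated data therefore demonstrate correctness of the
orthology-filtering and distance machinery under clean substitution-only
divergence, not robustness to misassembly or polyploid gene families.

## Validation design and problem sizes

The test suite and the acceptance script run everything at desk scale
with the built-in aligner, chosen as the package's own study conditions:

- Oracle agreements: 200 random HSP-table pairs (≤ 50 rows) against a
  literal brute-force reduction; 200 random multipartite graphs
  (≤ 30 vertices, 3–6 samples) against all-pairs clique probing.
- Clone identity: 8 copies of one 200-gene transcriptome; all
  off-diagonal distances must be exactly zero in both modes (and with
  BLASTn where available).
- Topology recovery: 10 independent simulations, 8 taxa × 300
  transcripts at rate 0.01; the NJ tree must match the generating tree
  (Robinson–Foulds 0) for at least 9 of 10 seeds.
- Prefix sweeps: nested sample prefixes share identical pair tables, so
  the ideal-component count is non-increasing in s — checked exactly.
- Rate sweep: run on one designated balanced 8-taxon tree rather than a
  random birth-death tree, because tree depth varies roughly tenfold
  across random trees and would confound the sweep. The tree height was
  set by calibrating the built-in aligner directly: its per-pair
  acceptance probability is ~1 below 0.3 substitutions/site, ~0.6 at 0.5,
  and ~0 at 0.7 (the seed prefilter and the identity floor jointly drive
  rejection, and the edit-path core's measured identity saturates near
  0.75 at high divergence). Height 3.5 (maximum leaf-to-leaf path 7.0
  time units) places rate 0.05 at divergence 0.35 on the deepest pairs
  (acceptance ≈ 0.9, so a quarter of genes keep full cliques) and rate
  0.1 at divergence 0.7 (acceptance ≈ 0, so cliques vanish). Mean
  distance must increase strictly over rates {0.001, 0.01, 0.05}; at
  rate 0.1 the ideal-component count collapses below 1% of the gene
  count.

## Numerical and degenerate-input choices

- Coverage ties at the n-th rank break by ascending gene ID, making
  top-n selection deterministic and nested in n.
- NJ is implemented to the Saitou–Nei definition with a lowest-index
  tie-break on the minimum-Q pair; input is symmetrized by averaging
  first; negative branch lengths from non-additive noise are clamped to
  zero. PCoA double-centers −½D², eigendecomposes, drops axes with
  negative eigenvalues (reported in the returned spectrum) and clamps
  `dims > s − 1` with a warning. Robinson–Foulds compares unrooted
  non-trivial bipartitions.
- Isolated vertices are size-1 (small) components. Duplicate match rows
  produce a single edge.
- The "fair" subset sweep strategy equalizes time per subset size using
  running per-size mean runtimes, trying the size with the least
  accumulated time next; the allocator is intentionally simple and
  approximate.
- Birth-death simulation retries on full-lineage extinction up to an
  attempt cap, then raises advising different rates.

## Known limitations

- The distance is not a proven metric: symmetry and the triangle
  inequality are unverified in general (the orientation asymmetry is
  measurable via `symmetrize` and is small on realistic data).
- The built-in aligner is quadratic per candidate pair and intended for
  ≲ 10³ isotigs per sample; real datasets should use BLAST+.
- Very closely related samples may be indistinguishable above noise, and
  very distant samples (beyond the aligner stringency) leave no ideal
  components, which is reported as an explicit error rather than a
  distance.
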