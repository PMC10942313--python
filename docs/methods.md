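# Methods

## Problem formulation

A design task fixes a full-length reference sequence, a sorted set of
1-based designable positions (all external interfaces speak PDB-style
1-based numbering), a residue alphabet (default: the 20 standard amino
acids), and named conformational states. Candidates are value objects over
the designed residues only; equality and hashing ignore objective values,
which are derived state. This makes per-sequence caching and deduplication
decisions sound by construction. Noncanonical residues in the reference are
passed through verbatim outside the designable region and rejected inside
it.

All objectives follow a minimization convention. Scores that are naturally
maximized (folding-propensity composites, log-likelihoods) are negated, not
affinely rescaled, so reported values keep their natural units up to sign.

## NSGA-II core

The generational loop is the standard elitist scheme: initialize a fully
random population of size N, evaluate, then per iteration produce N
offspring (two binary tournaments per pair, two-point crossover with
probability 0.9, mutation with probability 1.0), evaluate, and truncate the
combined 2N pool by non-dominated sorting with crowding-distance
tie-breaking. Defaults are N = 100 and 50 iterations with mutation rate
0.3.

Choices the scheme leaves open, fixed here:

* **Offspring pairing.** Parent pairs are drawn until exactly N offspring
  exist; with odd N the final pair contributes one child. This keeps the
  2N pool exact. Tournament draws are without replacement within a
  tournament and with replacement across tournaments; full ties (equal
  rank and crowding distance) are broken by a fair coin.
* **Skipped crossover** (probability 0.1) passes the parents through
  verbatim before mutation.
* **Duplicates are retained.** Entropy and eCDF statistics are computed
  over the full population; deduplication would distort them.
* **Crowding distance** normalizes per-objective gaps by (max − min); a
  zero range contributes 0 rather than NaN. Fronts of ≤ 2 points are all
  boundary (infinite distance). Truncation sorts by descending distance
  with a stable order on ties.
* **Determinism.** One numpy PCG64 stream, seeded from the run config,
  drives every stochastic operator in a fixed documented order (tournament
  a, tournament b, crossover coin, cut points, then mutation per child).
  Two runs with the same config are bit-identical, and per-iteration rng
  state checkpoints are recorded so a run can be restarted exactly.
* **Caching.** Objective values are cached per unique designed sequence
  within a run. Because evaluators are required to be pure functions of
  the sequence, caching cannot change results — only skip recomputation.
* **Batched evaluation.** All evaluation flows through one contract point
  mapping a list of sequences to an objective matrix. Any order-preserving
  map (thread pool, process pool) may be substituted; the contract is
  result identity with the sequential map, which holds for pure
  evaluators.

## Variation operators

The n-point crossover samples n distinct cut junctions uniformly without
replacement (n = 2 by default); children are complementary.

The mutation operator composes a position selector and a residue proposer:

* *random selector*: independent Bernoulli(μ) per designable position,
  with an empty outcome replaced by one uniformly random position. The
  selected-count law is therefore the zero-patched binomial — Bin(n, μ)
  with the k = 0 mass moved to k = 1.
* *ranked selector*: the full spliced sequence is scored once (one pass,
  no masking) by a per-position ranker; the k = max(1, Bin(n, μ))
  lowest-scoring positions are redesigned. Ties break by stable ascending
  sort on (score, position index) — the paper-style procedure needs a
  deterministic completion for testability. The multi-chain case (choosing
  a random designable chain first) degenerates to the single designable
  chain supported here; multi-chain regions are out of scope.
* *uniform proposer*: independent uniform draws over the alphabet. The
  current residue may be re-drawn; no rejection loop is applied, which
  slightly lowers the effective mutation intensity relative to a
  forced-change convention and is the documented choice.
* *plugin proposers/rankers* register by name and receive the full spliced
  sequence context, so structure-conditioned models can condition on the
  non-designable residues.

## Objectives

**Composite fold score.** mean-pLDDT × pTM × TM-score(template,
prediction), all components in [0, 1], product in [0, 1], negated as an
objective. The component model calls live behind plugin contracts with
their fixed hyperparameters (1 recycle, gap-token template sequence,
sidechain deletion, glycine CB imputation; language-model scoring in a
single unmasked pass; inverse-folding scoring averaged over 5 repeats at
temperature 0.3). The neural networks themselves are never reimplemented
here.

**TM-score.** Computed over CA traces with fixed residue correspondence:
TM = max over superpositions of (1/L) Σ 1/(1 + (dᵢ/d0)²) with the
canonical d0(L) = 1.24·(L − 15)^⅓ − 1.8, floored at 0.5 Å. The search
seeds iterative Kabsch superposition from contiguous fragments and refines
by re-superposing on residues within an adaptive cutoff (d0 + 1 Å, grown
in 0.5 Å steps until ≥ 3 residues remain) until the aligned set is stable.
For L ≤ 32 the fragment seeds are exhaustive (all contiguous fragments of
length ≥ 4), which is affordable and matches the exhaustive-seed oracle
exactly; longer chains use the canonical coarse seeds (L, L/2, L/4 with
half-fragment stride). Kabsch superposition itself is the SVD algorithm
with the determinant correction guaranteeing a proper rotation; clouds
with a degenerate second singular value (collinear/coincident points)
are rejected rather than silently resolved.

**Surrogate objectives.** Each state carries a PSSM over the designable
positions (probabilities pseudo-count-smoothed, so all log-likelihoods are
finite). Two scorers are derived: the mean log-likelihood (negated: a
per-position-averaged negative log-likelihood, the analog of an
inverse-folding state score), and a saturating composite surrogate
exp(mean-LL − max-attainable-mean-LL) ∈ (0, 1], equal to 1 exactly for the
PSSM's modal sequence. The exponential-of-deficit form exists solely so
tests exercise a bounded, saturating objective like the real composite
score; it makes no biophysical claim.

## Multistate combination

States are merged translation-only (intra-state geometry preserved
exactly) along +x in state order, with centroid separations satisfying
r_ij ≥ 2·max(r_i,max, r_j,max) + r_min and r_min = 24 Å. r_i,max is
defined over CA atoms; because the separation guarantee is intended at the
atom level, the layout pads each state's effective radius to the all-atom
maximum distance from the CA centroid whenever that exceeds the CA radius.
Collinear placement is chosen for determinism; the constraint only binds
pairwise distances, and the collinear arrangement satisfies every pair.
Chain ids are kept where unique and otherwise renamed from an unused-letter
pool; the tie map (designable position → [(state, chain, residue)]) is
exported as JSON in a documented local convention, mirroring the
tied-position inputs of inverse-folding tools. PDB I/O is backed by
biotite; HETATM records are dropped on read, residue-numbering gaps
(unmodeled loops) are preserved, and duplicate (chain, residue, atom)
records or malformed ATOM lines (reported with their line number) are
rejected.

## Analysis metrics

* **Native recovery**: fraction of designable positions matching the
  reference; population mean reported separately.
* **Entropy**: per-position Shannon entropy in nats over the empirical
  residue distribution, with an eCDF helper.
* **Hypervolume**: exact 2-D sweep (sort contributing points by the first
  coordinate, accumulate rectangles to the reference point). Dominated,
  duplicated and out-of-box points contribute nothing. Reference-point
  conventions: (0, 0) for negated bounded composite scores, (4, 4) for
  negative log-likelihood objectives. Dimensions above 2 are rejected — a
  deliberate scope boundary, since only 2-D objective subspaces are
  measured here.
* **BLOSUM62 similarity**: per-position s(a,b)/√(s(a,a)·s(b,b)), averaged.
  This normalization guarantees unit self-similarity and symmetry; since
  "normalized" conventions vary between implementations, absolute values
  should only be compared within this package.
* **Spectral embedding**: affinities are min-max shifted to [0, 1]
  (BLOSUM similarities can be negative), the symmetric normalized graph
  Laplacian is decomposed with `scipy.linalg.eigh`, and the first
  nontrivial eigenvectors are returned with each eigenvector's sign fixed
  by making its largest-magnitude entry positive. Direct eigh is used
  rather than a higher-level wrapper because the deterministic sign
  convention and strict input validation are part of the contract.
* **Alignment trimming**: the alignment columns carrying the reference's
  designable positions are extracted for every row; rows with any gap in
  the region are dropped, with retained/dropped counts reported. The
  operation consumes an already-computed (and, where applicable,
  confidence-filtered) alignment; running an aligner is out of scope.
* **Percentile similarity**: the q-th percentile (default 95) of
  similarities to a reference set, with numpy's linear-interpolation
  percentile convention, documented because rank conventions differ.

## Synthetic data

The toy generator emulates the two-state design tension at an enumerable
scale: L = 6 positions, A = 4 letters (4096 sequences) by default, chosen
so exhaustive Pareto enumeration takes milliseconds while fronts remain
nontrivial. Per-position PSSMs come from a softmax over
sharpness-scaled standard-normal logits (sharpness 4.0 by default, which
makes modal probabilities peaked enough that conflicting positions create
genuine objective tension). A configurable fraction of positions is
conflicting: state B's modal logit is swapped with another residue's, so
the two states prefer different residues there; the remaining positions
share a mode. The toy wild type is the modal sequence of the averaged
PSSMs — the natural compromise sequence. Toy backbones are ideal-parameter
traces (helix-like: 2.3 Å radius, 100°/residue, 1.5 Å rise; strand-like:
3.3 Å rise with 0.95 Å zigzag; both give consecutive CA-CA ≈ 3.8 Å) with
N/C/O atoms placed at fixed offsets and a 0.02 Å deterministic jitter.
Reference sequence sets are generated by per-position mutation of the toy
wild type at low (0.1) and high (0.7) divergence, standing in for
annotated "similar" and "dissimilar" databases.

What the surrogates do not capture: positional couplings (PSSMs are
site-independent), realistic backbone geometry and sterics, and the
ruggedness of neural-network score landscapes. Passing tests therefore
demonstrate the correctness of the optimization, geometry and analysis
machinery under controlled conditions — not transferability of any design
outcome to real proteins.

## Problem sizes and numerical choices

Tests and the acceptance script run full-size optimizer settings (N = 100,
50 iterations) on the L = 6, A = 4 toys, 100 random sorting instances up
to n = 500 points in 2–4 objectives, 20 hypervolume fronts against
10⁶-sample Monte-Carlo estimates, 50 random structure pairs for the
geometry guarantee, and 20,000 draws for selector-distribution checks.
Elitism implies front-0 hypervolume is non-decreasing whenever front 0
fits within the population; the monotonicity check asserts that
implication directly. Floating-point tolerances: crowding/hypervolume
comparisons at 1e-12, rigid-invariance checks at 1e-6, oracle agreement
for superposition at 1e-8.

## Known limitations

* Hypervolume is 2-D only; many-objective (> 4) scalability and
  reference-direction methods (NSGA-III) are out of scope.
* One designable chain per problem; no insertions/deletions; sequences
  only (no backbone redesign).
* The exact offspring-pairing discipline is one of several reasonable
  readings of the standard scheme; trajectory-level reproduction of other
  NSGA-II implementations is not expected, only distributional behavior.
* The tie-map JSON dialect is a local convention; adapters may be needed
  for specific inverse-folding tools.
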