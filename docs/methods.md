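# Methods

## RLowPC: relevance low-order partial correlation

The refinement operates in two steps on an expression matrix (genes ×
samples):

1. **Search-space reduction.** A full-order partial-correlation network is
   inferred: the sample correlation matrix R is shrunk toward the identity,
   R\* = λI + (1−λ)R, with the analytic Schäfer–Strimmer intensity
   λ\* = Σ Var̂(r<sub>ij</sub>) / Σ r<sub>ij</sub>² (clamped to [0, 1]), and
   partial correlations are read off the inverse,
   ρ<sub>ij</sub> = −Ω<sub>ij</sub>/√(Ω<sub>ii</sub>Ω<sub>jj</sub>). The top
   N edges by |ρ| form the confined search space; the rest of the ranking is
   kept but never re-enters the head.
2. **Neighbour-conditioned re-estimation.** For each retained edge (i, j)
   the partial correlation is re-computed by inverting the submatrix of R\*
   over {i, j} ∪ Q, where Q is the set of the pair's immediate neighbours
   in the trimmed graph. By default Q is the **shared** neighbours
   (N(i) ∩ N(j)); a `union` mode (N(i) ∪ N(j)) is also provided. Q is
   capped at `max_q` (default: samples − 4) so the conditioned system stays
   over-determined; above the cap, neighbours are dropped weakest-first by
   the pre-inference |score| of their retained edges incident to the pair.

Retained edges carry |refined score| (the signed value is available);
non-retained edges carry ε·|original ρ| with ε chosen so every non-retained
edge ranks strictly below every retained one. The refinement therefore
re-orders the head of the ranking without discarding the tail — evaluation
at the standard top-1000 cutoff with N ≥ 1500 never reaches the tail
anyway.

**Search-space size.** The suggested N follows the published mapping
{100 → 1500, 500 → 2000, 1000 → 3000, 2000 → 5000, 3000 → 8000} with
linear interpolation in between. Below 100 genes the mapping is
extrapolated by holding the retained *fraction* of pairs at the 100-gene
ratio (1500/4950 ≈ 30%); clamping to 1500 instead would retain every pair
of any smaller network and silently degenerate the method to full-order
PC. In the benchmark pipeline N is keyed to the full network size even
when inference runs on an ANOVA-filtered subset, matching the published
usage where N is a property of the dataset, not of the filtered gene
count.

**Neighbour mode.** `shared` is the default: it is the conditioning set
the method is named for, and in development benchmarks it performed at
least as well as `union`. Both are exposed because the defining
illustration of the method (a 5-gene example where the pair's two
immediate neighbours are conditioned on) cannot distinguish them.

## Comparator methods

All methods share one contract: expression matrix in, symmetric
zero-diagonal weighted adjacency out. MI-based methods use the Gaussian
surrogate MI = −½ ln(1−r²) of the Pearson correlation, the standard choice
for continuous time-series input; |r| is clamped to 1−10⁻¹² first so
collinear genes map to a large finite value.

- **cor** — Pearson correlation, diagonal zeroed. Zero-variance genes get
  correlation 0 (with a warning) rather than NaN.
- **pc** — the shrinkage partial-correlation network of step 1 alone.
- **pcit** — for every gene triplet the three first-order partial
  correlations are computed by the recursion formula; the trio tolerance ε
  is the mean of the three ratios (partial / marginal), ratios with
  |denominator| < 10⁻¹² contributing 0; an edge is eliminated if for some
  third gene both |r<sub>xy</sub>| < |ε·r<sub>xz</sub>| and
  |r<sub>xy</sub>| < |ε·r<sub>yz</sub>|. Survivors carry |r|.
- **aracne** — data-processing inequality: edge (i, j) is zeroed when some
  k gives MI<sub>ij</sub> < min(MI<sub>ik</sub>, MI<sub>jk</sub>) − ε
  (strict, default ε = 0, so equal-MI triangles survive); all triplets are
  judged on the unpruned matrix simultaneously.
- **clr** — each MI value is z-scored against the background mean and
  sample (ddof = 1) standard deviation of both genes' off-diagonal MI
  values; negative z clips to 0; weight = √(z<sub>i</sub>² + z<sub>j</sub>²);
  a zero background SD yields z = 0.
- **mrnet** — per target, greedy forward minimum-redundancy
  maximum-relevance selection: add the gene maximising
  MI(t, j) − mean MI(j, selected) until the best score is ≤ 0; pair weight
  is the score at selection, symmetrised by max over the two passes.
- **mrnetb** — per target, backward elimination from the full candidate
  set under the objective mean-relevance − mean-pairwise-redundancy,
  removing while the objective improves by > 10⁻¹², followed by one
  sequential replacement sweep (single pass guarantees termination);
  weights are the final within-set MRMR scores, symmetrised by max and
  clipped at 0.
- **random** — i.i.d. uniform(0, 1) upper-triangle weights from a fixed
  seed.

**Ranking.** All pairs are ordered by descending |score| with a
lexicographic tie-break on the canonical (min, max) gene pair, making
every ranking bit-reproducible. Correlations are signed; ranking by
magnitude treats strong repression as informative as strong activation,
and the signed score is preserved in all outputs.

## Evaluation

Scoring is over undirected, self-loop-free pairs; directed gold standards
are collapsed at load. Confusion counts at rank k satisfy TP + FP = k and
TP + FN = |true edges| by construction. The partial AUPR over ranks 1..K
(default K = 1000, clipped to the pair universe) uses step integration —
each true positive at rank k contributes precision(k)·Δrecall — with no
anchor point at recall 0; the partial AUROC is trapezoidal with FPR
denominated by the total negatives of the full pair universe. At full
depth, precision equals the network density identically, which the tests
exploit as an algebraic oracle. Method comparison across repeated runs
uses a two-sided paired t-test; identical vectors return p = 1 exactly and
a constant non-zero difference (zero variance) is an error rather than a
spurious certainty.

**Module-wise evaluation.** Genes are partitioned by average-linkage
hierarchical clustering on the distance 1 − |r|, cutting the tree at the
height that maximises the number of modules of size ≥ `min_size`
(default 10), ties broken by maximal gene coverage and then minimal
height. Genes in smaller clusters are left unassigned ("grey"). This is a
deliberate, documented substitute for the full weighted co-expression
(WGCNA) pipeline — soft thresholding, topological overlap and dynamic tree
cutting are out of scope — and a user-supplied partition file can be used
instead. Inference and scoring then run independently inside each module
against the induced reference sub-network; modules without a true edge are
excluded from the average, as are grey genes.

## The synthetic-data generator

The generator emulates the statistical design of the benchmark rather than
any particular simulator's kinetics:

- **Networks.** A directed scale-free source graph (Barabási–Albert
  skeleton, attachment 2, random edge orientation; ~2 edges/gene, matching
  the published benchmark densities of 0.002–0.05) stands in for curated
  source networks. Sub-networks are extracted by greedy neighbourhood
  expansion from a random seed node (ties random, restart on exhaustion),
  which preserves local clustering the way neighbourhood-based extraction
  does.
- **Kinetics.** One state variable per gene:
  dx<sub>i</sub> = m<sub>i</sub> σ(Σ<sub>j</sub> W<sub>ij</sub> u<sub>j</sub> + b<sub>i</sub> + δ<sub>i</sub>) − d<sub>i</sub> x<sub>i</sub>,
  with production m<sub>i</sub> ~ U(0.8, 1.2), degradation
  d<sub>i</sub> ~ U(0.05, 0.2) per unit time, signed edge weights
  |w| ~ U(0.5, 1.5) with 70% activation, and σ the logistic function. The
  regulation input uses expression normalized by its characteristic scale,
  u<sub>j</sub> = x<sub>j</sub>d<sub>j</sub>/m<sub>j</sub> ∈ (0, 1) at
  steady state; without this, raw expression levels (up to m/d ≈ 24) would
  saturate the logistic and no signal would propagate. The basal input
  b<sub>i</sub> = −½ Σ<sub>j</sub> W<sub>ij</sub> + U(−0.5, 0.5) centres
  each gene's activation near the logistic midpoint at mid-range inputs.
- **Perturbation.** One experiment per time series: a random third of the
  genes receives a fixed activation shift δ ~ ±U(1, 3) from the first time
  point through time point 11 (of 21), then reverts — a sustained
  enhancement or inhibition followed by recovery.
- **Noise.** Euler–Maruyama dynamic noise c·√Δt·(production +
  degradation)·ε with c = 0.05, so active genes are noisier than inactive
  ones; independent technical noise N(0, 0.025) on every measurement.
- **Sampling.** 21 time points × 3 replicates = 63 profiles. Replicates
  are independent SDE trajectories sharing the perturbation. Each recorded
  time point is `steps_per_sample` = 15 integration steps (Δt = 1) apart,
  placing the per-sample relaxation d·Δt<sub>sample</sub> in [0.75, 3]: a
  gene traverses most of its response within one to a few sampling
  intervals, the regime of the benchmark time courses this emulates. With
  one step per sample instead, targets would lag their regulators by 5–20
  samples and correlation-based inference would be systematically
  mis-ranked.
- **Initialisation.** The deterministic steady state, found by 500
  noiseless burn-in steps (no initialisation recipe is prescribed by the
  design being emulated; the fixed point is unique in practice for these
  dissipative dynamics). States are clamped at 0; a non-finite state
  aborts with the offending step.
- **Prefilter.** Per-gene one-way fixed-effects ANOVA across the 21 time
  points (3 replicates each), keeping genes with p < 0.001. Constant genes
  are assigned p = 1 rather than NaN.

**What the emulator does not reproduce.** Thermodynamic transcription
kinetics (protein species, binding complexes, Hill activation) are
deliberately absent; so are knockout designs and the exact numerical
trajectories of any external simulator. Consequently, passing benchmarks
here show that the methods behave as expected under the stated statistical
design — sample layout, perturbation window, noise structure — not that
they would reach any particular accuracy on data from a richer kinetic
model or from real experiments. One known consequence: with a single
shared perturbation window, all responding genes carry a strong
common-mode profile, so plain correlation exceeds the random baseline only
modestly here, while redundancy-aware methods (ARACNE, MRNETB) and the
partial-correlation family separate more clearly.

## Benchmark protocol

A benchmark run (`rlowpc.benchmark.run_benchmark`, CLI `rlowpc benchmark`)
generates `n_structures` networks × `n_series` time series (defaults 5 × 5;
the tests and the acceptance script use the reduced 5 × 2 design at 100
genes to stay fast), prefilters each series by the ANOVA (p < 0.001),
runs every method on the filtered matrix, zero-pads the inferred adjacency
back to the full gene universe so filtered-out genes rank at the bottom,
and scores the top-1000 predictions against the full reference network.
All child seeds derive deterministically from the top-level seed via
`SeedSequence` and are recorded in the run manifest, so any run is exactly
reproducible.

## Numerical choices

- λ is clamped to [0, 1]; a singular matrix at λ = 0 raises with an
  instruction to shrink rather than returning garbage.
- Conditioning submatrices with condition number > 10⁸ are re-shrunk with
  λ = 0.01 and a warning.
- Zero-variance detection is relative (sd ≤ 10⁻¹² × scale), so a constant
  gene stored with rounding noise is still caught.
- DPI/PCIT use strict inequalities; exact ties never remove an edge.
- The RLowPC tail factor ε = min(retained)/(2·max(non-retained)), with the
  tail zeroed if either side is ~0.
- All evaluation cutoffs clip to the pair-universe size for small networks
  and modules.

## Known limitations

- The PCIT variant here weights the Boolean keep-flags by |r|; published
  PCIT implementations differ in minor details of the tolerance loop.
- MRNETB's backward search is a heuristic (best-improvement elimination
  plus one replacement sweep), not an exhaustive subset optimisation; the
  tests verify its objective is never below the forward-greedy solution's.
- The module partition is a clustering substitute, not WGCNA; module
  boundaries will differ from a WGCNA run on the same data.
- Timing benchmarks and multi-experiment designs (concatenating several
  perturbation experiments) are supported by composition but not studied
  here.
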