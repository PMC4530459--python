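# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `paraconv`.  It is the design record: everything here is
implemented and exercised by the test suite; no empirical claim is made
that the tests or `scripts/acceptance.py` do not themselves compute.

## Substitution models and site likelihoods

All models are time-reversible continuous-time Markov chains
`Q = S·diag(π)` with the diagonal set so rows sum to zero, normalized so
that `−Σ πᵢQᵢᵢ = 1` (one branch-length unit = one expected substitution
per site at stationarity).  Supported: the empirical amino-acid matrices
**LG** and **WAG** with their published exchangeabilities and stationary
frequencies (embedded as plain-text tables in the conventional PAML
lower-triangle layout; no "+F" frequency re-estimation — a deliberate
simplification, recorded in output metadata), nucleotide **GTR**
(exchangeabilities and frequencies supplied by the caller, defaults
equal), and the two-state **CF2** (Cavender–Felsenstein) model for
purine/pyrimidine-recoded data with frequencies fixed at (½, ½).

Among-site rate variation uses a discrete gamma with `k = 4`
equal-probability categories; category rates are within-bin conditional
means (computed from the shape-(α+1) incomplete-gamma identity) and are
renormalized to average exactly 1.  Transition matrices come from the
symmetric eigendecomposition of `diag(π)^½ Q diag(π)^(−½)`, which is
numerically stable for reversible chains; tiny negative entries from
round-off are clipped and rows renormalized.

Site likelihoods use Felsenstein pruning over unique site patterns with
per-node rescaling to avoid underflow.  Gap and unknown characters
contribute all-ones partial vectors, so a fully gapped column has site
lnL 0 by convention.  The engine also maintains *outward* partials
(likelihood of all data outside a subtree, conditional on the state at
the parent end of the edge, stationary frequencies folded in at the
root).  From the inward/outward pair at any edge it evaluates the total
lnL, its first and second derivatives with respect to that edge's length
(`dP/dt = rQP`, `d²P/dt² = (rQ)²P`), and the likelihood of attaching a
new leaf to the edge — the work-horses of branch-length optimization,
NNI scoring and stepwise addition.

## Branch-length and shape optimization

Branch lengths are bounded to `[1e-8, 10]` substitutions/site.  Joint
optimization proceeds in two phases: damped Newton sweeps (all edges
updated simultaneously from the current partials, steps clamped to a
5-fold length change) take the fit close to the optimum in a handful of
tree passes, and L-BFGS-B with the analytic gradient polishes from the
best point seen.  The polish is essential on flat ridges — e.g. an
internal branch collapsing to the lower bound — where sweep-to-sweep
improvements can fall below the tolerance long before the optimum; the
monotonicity contract (final lnL ≥ initial lnL) is enforced by restoring
the best visited lengths.  The default convergence target is a total-lnL
improvement below `1e-4`; per-window fits of the fixed global topology
use `1e-6` because the window statistic compares that single-topology fit
against a search optimum and its slack must stay negligible.  Coarse
screening fits (below) cap the Newton phase at 4 sweeps and skip the
polish.

The gamma shape α is estimated by bounded one-dimensional search over
log α ∈ [log 0.02, log 100] with branch lengths re-optimized at every
candidate (warm-started from the previous candidate's optimum), absolute
tolerance 0.02 on log α.  In the sliding-window pipeline α is estimated
**once** on the full alignment jointly with the global tree and then held
fixed for all windows and both test trees: 50-column windows cannot
support a stable shape estimate of their own.

## Tree search

*Exhaustive* mode enumerates all `(2n−5)!!` unrooted topologies (used up
to 6 leaves, 105 topologies), drops those violating the monophyly
constraint, branch-length-optimizes each with a coarse screen, refits the
three leaders at Newton precision and polishes every leader within 0.5
lnL of the best, so near-ties are decided at full precision.  *Heuristic* mode (larger trees)
runs stepwise addition in a seed-derived random leaf order — each
placement scored exactly from the current tree's edge partials, candidate
placements that would break the constraint rejected — followed by NNI
hill climbing.  Both NNI rearrangements of an internal edge are scored
locally (partials regrouped around the edge, central branch re-optimized
by Newton with all other lengths fixed); strictly improving moves are
accepted first-come in a deterministic traversal, and all lengths are
re-optimized jointly whenever a sweep finishes.  Ties everywhere break
toward the first candidate in traversal order, so results are
reproducible from the seed.  Multiple random-addition starts return the
best tree (windows default to 3 starts; full-alignment fits to 5).

## The sliding-window scan

Windows are 1-based inclusive, `start = (index−1)·step + 1`, trailing
partial windows dropped (defaults width 50, step 10: over 230 columns
this yields 19 windows, window 12 starting at column 111 and window 15
ending at column 190).  One global tree — the unconstrained
full-alignment ML tree — is imposed on every window with branch lengths
refit per window; the conversion tree is searched per window under the
constraint.  Windows are scored independently; the profile is invariant
to alignment row order and to the order windows are evaluated in.

## Parametric-bootstrap calibration

Replicates are simulated on the fitted no-conversion tree (which must
violate the constraint — a constraint-satisfying tree is a
misconfiguration, as the null would be degenerate).  Each replicate is
scanned exactly like real data, re-inferring its own global tree with a
single heuristic start (one search per replicate, as is standard for
bootstrap replicates).  Window deltas are pooled across windows and
replicates into a single null distribution; the critical value is the
nearest-rank (no interpolation) `⌈(1−α)·n⌉`-th order statistic, a
well-defined and conservative choice at small replicate counts.  A
window is significant iff its delta **strictly** exceeds the critical
value.  The simulation model defaults to WAG+Γ with parameters from the
original fit while the analysis model stays LG+Γ, mirroring a common
simulator limitation; both are configurable.  By default the analysis of
replicates keeps the gamma shape fixed at the simulation value
(re-estimation per replicate is available but roughly doubles the cost).

## Boundary estimation

Per-column lnL differences are computed under the two full-alignment
test trees (global unconstrained vs conversion-constrained, same fixed
α).  For every integer width in [30, 90] and every start, the statistic
is the Welch unequal-variance *t* comparing mean Δsite-lnL inside vs
outside the window (unbiased variances; if both variances vanish, t = 0
for equal means and ±1e12 otherwise).  All windows of one width are
scored in O(L) from prefix sums of the values and their squares — unit
tests pin this scanner to a naive per-window implementation.  The
permutation null for each width shuffles column order (independent
seed-derived stream per width, so observed maxima never depend on the
seed) and records the max t over that width's windows; the p-value is
the proportion of permuted maxima **strictly greater** than the observed
maximum, deliberately without the "+1" correction, so the smallest
attainable p is 0.  The reported region is the window with the largest t
among widths with p below the level; when no width is significant the
result carries the per-width records and no best window.  The
"corrected" aspect of the statistic is realized here as the Welch form
plus the max-statistic permutation adjustment across window positions
and widths; this is a reconstruction, not a restatement of any
particular published correction.

## Synthetic scenarios

The generator emulates the study design the pipeline targets: `n_pairs`
paralog pairs (default 6, i.e. 12 sequences — one candidate converted
pair plus five background pairs; 4/8/10-pair designs are assembled with
`make_npair_alignment`), 230 columns, a contiguous tract at columns
111–190 simulated on the conversion tree while all other columns follow
the no-conversion tree, LG+Γ with α = 0.7.  Template trees are two
mirrored ladder-shaped paralog clades joined by an inter-paralog branch
of length `2·depth_scale`, intra-clade branch lengths i.i.d. exponential
with mean `depth_scale = 0.3` substitutions/site — a deep duplication
with moderate within-clade divergence, the qualitative regime in which
the scan is meant to operate.  Real branch lengths for the motivating
system are not published, so `depth_scale` is an explicit parameter
rather than an asserted fact.  The tract is simulated on the conversion
tree rather than spliced from a second simulation, matching the
likelihood model the detector assumes and making recovery tests
interpretable.  Rate categories are drawn i.i.d. uniform per site,
mirroring the discrete-gamma likelihood.  Motif insertions are **not**
simulated by default (the scan alignments the design emulates exclude
the motif columns); the motif module is exercised on purpose-built
alignments instead.

What the generator does *not* emulate: indel evolution (alignments are
gap-free unless the user introduces gaps), compositional heterogeneity
across lineages, model misspecification (data are simulated under the
analysis model family), and alignment error.  Passing recovery tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to real-data artifacts.

## Determinism

Every stochastic stage draws from a named substream of one master seed
(`_rng.substream(seed, *tags)`), so any stage can be replayed in
isolation; thread count never affects results.  CLI runs write a
manifest (parameters, input checksums, version) sufficient to reproduce
their outputs.

## Problem sizes in the shipped checks

The test suite and acceptance script run entirely on synthetic data at
deliberately modest scales chosen to keep a full run on one CPU in the
tens of minutes: bootstrap calibration checks use 3 pairs × 230 columns
with 100 calibration + 40 evaluation replicates; end-to-end recovery uses
the default 6-pair scenario over 10 seeds with a 10-replicate null and
1,000 permutations; the family-wise-error check uses 50 runs × 500
permutations; `scripts/acceptance.py` uses one scenario, a 5-replicate
null and 1,000 permutations.  All scales are parameters, and larger
values only sharpen the estimates.

## Known limitations

- NNI-only rearrangement can in principle miss optima that SPR-style
  moves would find; multiple random-addition starts mitigate this at the
  tree sizes the pipeline targets (≤ ~12 sequences per scan).
- The Wald interval in the G+C screen is a normal approximation; at the
  intended n (thousands of columns) it is accurate, but it is not exact
  at small n.  The choice is recorded in the output, not asserted as
  canonical.
- GTR exchangeabilities are not ML-estimated internally; callers supply
  them (or accept equal rates).  Empirical state frequencies are
  available via `models.empirical_frequencies`.
- The scan tests a *given* candidate pair; it does not search over which
  sequences converted.
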