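# Methods

`dynflex` implements a complete dynamic brain-network reconfiguration
analysis: sliding-window functional connectivity, multilayer modularity
community detection, temporal reconfiguration metrics, temporal
core–periphery classification, and covariate-adjusted permutation group
statistics — together with a synthetic cohort generator that plants known
community dynamics so every stage can be validated against ground truth.

## The multilayer model

A subject's regional time series (T samples × N regions; the reference
geometry is N = 227 regions from a 264-node functional atlas with 37
unassigned regions removed, T = 230 samples at a 2 s sampling interval) is
decomposed into overlapping windows of `width` samples moved by `step`
(defaults 30 and 1, giving L = ⌊(T − width)/step⌋ + 1 = 201 windows).  Each
window yields a Pearson correlation matrix A_·,·,l with zeroed diagonal —
one *layer* of a multilayer network in which every region appears once per
layer as a state node.  Edge weights are raw correlations: no Fisher
transform and no thresholding by default, matching the convention of
passing windowed correlations directly into generalized-Louvain community
detection (a Fisher-z flag and `{keep | zero-negative | absolute}`
negative-edge policies exist for sensitivity analyses).

A partition g of the state nodes is scored by the multilayer modularity

    Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ_l P_ijl) δ_lr + δ_ij ω_jlr ] δ(g_il, g_jr)

with P_ijl = k_il k_jl / 2m_l the Newman–Girvan null (k_il the strength of
node i in layer l, 2m_l the layer's total weight), γ the resolution
(default 1), ω the inter-layer coupling (default 1) rewarding a node for
keeping its community across *adjacent* windows (ordinal coupling;
categorical all-pairs coupling is available), and 2μ the total weight over
layers plus couplings.  Negative correlations enter A and the null as-is by
default.  A layer whose total weight is non-positive makes the null model
undefined and raises an error.

## The optimiser

Q is maximised with an iterated Louvain procedure on the sparse
supra-modularity matrix (dense N×N blocks on the diagonal, diagonal
inter-layer couplings; at the reference geometry ≈ 45k state nodes and
10.4M non-zeros):

1. greedy phase: state nodes are visited in a seed-randomised order and
   moved between communities while the move improves Q by more than the
   tolerance 1e−10 (smaller gains are rejected to prevent float-noise label
   churn);
2. aggregation phase: communities collapse into supernodes and the phases
   repeat on the aggregated matrix;
3. the full cycle restarts from the obtained finest-level partition until
   Q stops improving.

Two move-selection policies are implemented.  The default,
`random-weighted`, samples among all strictly improving destinations with
probability proportional to the gain.  This choice matters: the
supra-modularity matrix of a correlation multilayer is nearly fully
connected, and maximal-gain moves funnel every seed into the same shallow
basin (on small test graphs, 100 of 100 seeds can converge to an identical
sub-optimal partition that single-node moves cannot leave).  Gain-weighted
sampling diversifies the agglomeration path at no measurable runtime cost
and restores exhaustive-search optimality on all sampled ≤ 8-node graphs.
The alternative `best` policy takes the maximal gain with seed-randomised
tie-breaking.  Two further details are easy to get wrong on signed
matrices: a node must always be allowed to *leave* for a fresh singleton
community (its attachment to every existing community can be negative),
and the B_ii diagonal entries travel with their node and therefore cancel
from every move gain while still counting in Q.

Because the optimiser is stochastic, it is run `n_reps` times (default
100) per subject and all metrics are averaged across repetitions;
partitions are never merged into a consensus.  Labels are canonicalised to
1..C by first appearance scanning layers then nodes, so community counting
is well defined.

## Reconfiguration metrics

From the community matrix S (N × L), per node i:

* **flexibility** F_i = m/(L−1), the number m of transitions l → l+1 at
  which g_il ≠ g_i,l+1, over the L−1 opportunities; 0 = never changes,
  1 = changes at every transition.
* **promiscuity** P_i = c_p/C, the fraction of all C communities in S the
  node ever joins.  Its floor is 1/C (a node always occupies at least one
  community of the C detected).
* **cohesion**: fraction of transitions at which i changes together with
  at least one other node sharing both its source and destination
  community; **disjointedness**: fraction of transitions at which it
  changes alone.  Both are normalised by L−1 change opportunities, so
  **flexibility = cohesion + disjointedness holds exactly node-wise** —
  every change is either coordinated or solo.  (The alternative toolbox
  convention counts pairwise co-moves, which breaks this identity; the
  per-change normalisation is used here precisely because the identity is
  the pipeline's strongest internal check.)

Nodal values are averaged into ten functional-network means and one global
mean (unweighted average over all N nodes).  Nodes in the lowest decile of
group-mean flexibility form the *temporal core*, the highest decile the
*temporal periphery* (k = round-half-away-from-zero of 0.10·N, i.e. 23 of
227; boundary ties resolve by stable input order with a warning), and each
class is summarised by its per-network composition.

## Group statistics

Each feature (metric × unit × level) is compared between groups by the t
statistic of the group coefficient in `value ~ group + age + gender +
mean_fd`; with no covariates this is exactly the pooled two-sample t.  The
group dummy codes group 1, so negative t means group 1 < group 2.
Significance comes from an empirical null: subjects are randomly
redistributed between the two groups (covariates stay attached to their
subjects) and the model is refit per permutation — 5000 permutations by
default, the same seeded sequence for all features, with +1 smoothing of
the two-sided p; when fewer distinct reassignments exist than requested,
the null is enumerated exactly.  A permuted design that happens to be
rank-deficient (e.g. the dummy aligning with a binary covariate in a small
cohort) is dropped from the null.  Benjamini–Hochberg FDR is applied
within each metric × level family (e.g. the ten network-level flexibility
tests), α = 0.05.

## The synthetic cohort generator

The generator emulates the study geometry (two groups of 13 and 14
subjects, 227 regions, 230 samples) with planted, countable dynamics.
Time is split into epochs of `epoch_length` samples (default 30, matching
the window width so that detection granularity and ground-truth
granularity coincide).  Within an epoch, signals follow a one-factor-per-
module Gaussian model: x_i = √r·f_{m(i)} + √(1−r)·e_i, whose population
correlation is exactly r = `within_module_corr` (default 0.6) inside
modules and 0 between, plus independent measurement noise of sd `noise_sd`
(default 0.1, which attenuates observed correlations by 1/(1+σ²) ≈ 1%).
At each epoch boundary every region switches modules independently with a
group-specific probability (defaults 0.05 vs 0.30 — the planted analogue
of a trained-vs-control contrast, with the low-switch group cast as group
1 so the expected group effect is a negative t for flexibility).  A
switching node joins a coordinated group (one shared destination per
source module) or moves solo to a destination no co-mover of its module
takes; the expected share of coordinated movers equals
`cohesive_fraction` (default 0.5, an uninformed midpoint) among modules
fielding ≥ 2 movers.  A lone mover cannot be coordinated, so at low switch
rates the realised coordinated share is necessarily below the nominal
fraction; the generator keeps the per-node switch probability exact and
accepts this floor effect, and the recovery test conditions on feasible
(≥ 2-mover) events.  Boundaries that would empty a module are redrawn.
Covariates are drawn independently of group (age uniform 17–28, gender
0/1, mean framewise displacement ≈ N(0.13, 0.05) clipped, near the
magnitudes reported for such cohorts); an optional `fd_group_gap` knob
injects covariate confounding for testing the adjustment.

What the generator does *not* emulate: hemodynamics, autocorrelated BOLD
spectra, motion artefacts, spatially heterogeneous module sizes, or any
relation between covariates and dynamics (by default).  Passing tests
therefore show that the pipeline recovers planted piecewise-stationary
Gaussian dynamics, not that it is robust to fMRI acquisition artefacts.

## Identifiability of planted modules at window scale

A finding worth recording: with equal-size equicorrelated modules, the
planted partition is *not* always the modularity optimum of a 30-sample
window.  Each module's signals share one latent factor, and the sample
correlation between two modules' factors over w window samples fluctuates
with sd ≈ 1/√w ≈ 0.18.  Merging modules a and b raises Q at γ = 1 whenever
that chance correlation exceeds ≈ (module size − 1)/N ≈ 1/n_modules.  With
5 equal modules the threshold (0.2) sits at about one sd, so roughly 14%
of module pairs merge per window and median per-layer agreement with the
planted labels plateaus near ARI 0.79 — the optimiser is not at fault (it
attains *higher* Q than the planted partition there).  With 3 or 4 modules
the threshold (0.33 / 0.25) is comfortably above the noise scale and
recovery is essentially perfect (median ARI 1.0).  This is an inherent
property of modularity on windowed equicorrelation data, not of the
implementation; it is why the recovery property test runs at 4 modules
while the 5-module condition is reported as measured.

## Problem sizes and numerical choices

The validation suite scales region counts down (cohort checks at N = 40 or
N = 30 regions, single-subject recovery at N = 60; full N = 227 geometry
is exercised once for shape and end-to-end behaviour) and uses 10
optimiser repetitions with 1000
permutations for power checks and 1 repetition with 400 permutations for
the 200-replicate type-I calibration — sizes chosen so the entire suite
runs on one CPU in minutes while keeping every statistical conclusion
sample-size-aware (binomial error bands are computed at the sizes used).
ΔQ tolerance is 1e−10; permutation p-values use a 1e−12 absolute guard
when comparing |t| values; correlations are clipped to [−1, 1] before the
diagonal is zeroed.  All randomness flows from explicit integer seeds:
cohort → per-subject seeds via one root generator, optimiser repetitions
use consecutive seeds, and the permutation sequence is drawn once per
statistical pass.

## Known limitations

* Single-node-move Louvain has no optimality guarantee; the randomised
  move policy empirically reaches exhaustive optima on tiny graphs, but
  large instances are only locally optimal (as with all Louvain variants).
* The permutation test assumes exchangeability of subjects under the null;
  covariates are refit per permutation rather than regressed out once
  (Freedman–Lane and similar schemes are out of scope).
* Sliding-window correlation with step 1 makes neighbouring layers highly
  dependent; flexibility values under ω = 1 are therefore small in
  absolute terms and meaningful chiefly in comparison across groups or
  conditions.
* The atlas table carries correct counts and network sizes, but region
  identities are synthetic placeholders; real analyses should supply their
  own region manifest.
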