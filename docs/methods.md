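# Methods

This note documents the models and procedures implemented in `fconn`,
the parameters that matter, the numerical conventions, and the design
choices made where the underlying methodology is genuinely open.

## Preprocessing model

The package operates on per-subject ROI-by-time signal matrices; all
image-space steps (slice timing, realignment estimation, spatial
normalisation, extraction of white-matter/CSF or component-based
nuisance signals) are out of scope, and any such nuisance signals are
accepted as externally supplied regressor columns.

**Framewise displacement.** FD_t = Σ over the six rigid-body
parameters of |p_t − p_{t−1}|, with each rotation difference converted
from degrees to millimetres of arc as |Δdeg|·(π/180)·r at head radius
r = 50 mm (approximately the mean distance from the centre of standard
space to the cortex). FD at the first frame has no predecessor and is
defined as 0 — a convention, made explicit because downstream mean-FD
covariates depend on it.

**Pipeline order.** drop initial volumes → linear detrend → ideal
bandpass → nuisance regression → scrubbing, with FD always computed
from the raw motion parameters. Filtering before scrubbing is a
deliberate trade-off: deleting frames first would break the uniform
sampling the DFT filter assumes, while filtering first lets spike
energy smear slightly before the offending frames are removed. Since
the scrubbed frames are deleted outright anyway (no interpolation, no
spike regressors), the smear affects only neighbouring frames'
passband content, and the exactness of frame-level scrubbing — which
the synthetic ground truth tests verify — is preserved.

**Scrubbing threshold.** The default is FD_t > 0.3 mm; the threshold
is a configuration field (`prep.fd_threshold_mm`), and 0.5 mm is a
commonly used alternative. Frames failing the criterion are removed;
the retained-frame mask over original acquisition frames is carried on
the series, so provenance of every surviving column is recoverable.

**Bandpass.** A rectangular frequency-domain filter: real-FFT bins
with frequency in [0.01, 0.10] Hz (inclusive) are retained, all others
— including DC — zeroed, and the inverse transform returned. The high
cutoff is validated against the Nyquist frequency 1/(2·TR); at
TR = 3 s Nyquist is 0.167 Hz. An ideal filter was chosen over an IIR
design because the downstream statistics operate on correlations, not
on waveform shape, and the ideal filter's passband is exactly
characterisable in tests.

**DVARS.** The root-mean-square frame-to-frame signal change is
computed as a QC statistic only; no exclusion rule is attached to it.

## Network model

Edges come from the Pearson correlation of ROI time series over
retained frames, Fisher-transformed (z = atanh r) for variance
stabilisation. Binarization is at fixed sparsity: the
K = round(s·N(N−1)/2) pairs with the largest |z| become edges, which
equates wiring cost across subjects and groups. Conventions:

* **|z| ranking** means strong negative correlations become edges.
  This is deliberate: the pipeline performs no global-signal
  regression (which manufactures spurious anticorrelations), so large
  negative z values are treated as real coupling.
* **Rounding and ties.** K rounds to nearest; ties at the K-th rank
  break by lexicographic (i, j) order. Both choices are arbitrary but
  deterministic, and they make edge sets nested across the grid (the
  graph at sparsity s is a subgraph of the one at s′ > s).
* **Degenerate inputs.** A zero-variance ROI or an off-diagonal
  |r| = 1 (duplicate series) raises a named error rather than
  propagating infinities.
* Partial-correlation edge definition is noted as a possible extension
  point; the implemented construction is Pearson.

**Threshold selection.** The grid default is 0.11–0.44 in steps of
0.01. The lower bound is the smallest grid sparsity with mean degree
s·(N−1) > 2·ln N (for N = 90: 0.11·89 = 9.79 > 2·ln 90 = 9.00, while
0.10·89 = 8.90 fails), which keeps the thresholded networks estimable.
The upper bound can be chosen by `maximum_sparsity`: the largest grid
point up to which every subject's small-worldness stays above 1.1.

## Graph statistics

All metrics operate on undirected, unweighted, simple graphs.

* **Clustering** C_i = E_i / (K_i(K_i−1)/2), the fraction of a node's
  neighbour pairs that are themselves connected; C_i = 0 for degree
  < 2 (kept defined rather than NaN so C_p is always computable at low
  sparsity). C_p is the unweighted mean over all N nodes.
* **Distances** are BFS hop counts; unreachable pairs are infinite.
* **Path length** L_i averages the finite distances from i; infinite
  distances are excluded with the exclusion count reported, and a node
  reaching nothing has undefined L_i, excluded from L_p with a
  warning. Fragmentation at low sparsity is thereby visible, not
  silently absorbed.
* **Efficiencies** use 1/∞ = 0 throughout: E_glo is the mean inverse
  distance over ordered pairs, E_nodal(i) the mean over partners of i
  (so mean_i E_nodal(i) = E_glo exactly), and E_loc the mean over
  nodes of the global efficiency of each node's neighbour-induced
  subgraph (node i excluded) — the fault-tolerance reading: how well
  i's neighbourhood communicates if i is removed. E_nodal(i) on the
  whole graph and E_glo(G_i) on the neighbourhood subgraph are
  distinct quantities and are deliberately exposed as distinct
  operations.
* **Betweenness** is the Brandes sum over unordered pairs of
  σ_st(i)/σ_st, unnormalized by default (normalization by
  (N−1)(N−2)/2 is an option).
* **Null networks** are degree-preserving Markov-chain randomizations:
  repeated double-edge swaps (a,b),(c,d) → (a,d),(c,b), rejecting
  self-loops and duplicate edges. The swap budget defaults to 10× the
  edge count — a standard mixing heuristic; if the budget cannot be
  met within 100× attempts (very constrained degree sequences), a
  warning is raised and the partially randomized graph returned.
* **Small-world indices**: γ = C_p/mean(C_rand), λ = L_p/mean(L_rand),
  σ = γ/λ over n_random = 100 nulls per graph (the Humphries–Gurney
  scalar; σ > 1, operationally > 1.1, marks small-world organisation).
  A null whose L_p comes out undefined is regenerated with a fresh
  sub-seed (at most 10 tries).
* **AUC**: the trapezoid Σ_k [Y(S_k)+Y(S_{k+1})]·ΔS/2 over a uniform
  grid — a threshold-free per-subject summary, and the quantity the
  nodal group comparisons and behavioral correlations run on.
* **Cost efficiency**: E_glo − s pointwise, with the argmax grid point
  reported (ties take the smallest sparsity and are flagged).

## Inference

* **Global metrics** (C_p, L_p, E_glo, E_loc, γ, λ, σ) are compared by
  pooled-variance two-sample t-tests (df = n_A + n_B − 2) at every
  grid sparsity and on each metric's AUC, uncorrected. The same pooled
  formula is exposed from summary statistics
  (`t_test_from_summary`) so published mean ± SD tables can be
  re-checked.
* **Nodal AUCs** use a residualize-then-permute scheme
  (Freedman–Lane on the reduced model): covariates — by default age
  and mean FD — are regressed out of each node's AUC across all
  subjects; the statistic is the absolute difference of residual group
  means; the null distribution comes from random relabelings
  preserving group sizes (default 5,000); and
  p = (1 + #{null ≥ observed})/(1 + n_perm), which can never be
  exactly 0 and counts exact ties conservatively (with a 1e-12
  relative tolerance absorbing summation-order float noise). The
  statistic and the covariate scheme are package choices — the
  permutation literature offers several defensible variants; this one
  is exact under exchangeability of residuals and is validated against
  exhaustive enumeration at tiny n and by type-I calibration over
  hundreds of null replicates.
* **Brain–behavior screening** computes the partial Pearson
  correlation (correlation of OLS residuals after removing intercept
  and covariates; p from the t transform with df = n − 2 − k) for
  every (node, nodal metric, behavioral score) triple, in an
  all-subjects scope and a single-group scope. Each row carries two
  flags: the per-node threshold 1/N (≈ 0.011 at N = 90) and
  uncorrected 0.05. Zero-variance residuals raise an explicit error
  rather than yielding NaN.

## Synthetic-data generator

The generator's defaults are the emulated study design: two groups of
18 subjects, 90 ROIs × 97 frames at TR = 3 s. Within that design:

* **True networks** are Watts–Strogatz graphs (k = 10, β = 0.1),
  independently drawn per subject — safely in the small-world regime
  (σ ≈ 4 against 100 nulls) while providing within-group topological
  variability.
* **Group-B degradation** deletes a fraction (default 0.5) of each
  affected node's edges and adds the same number of edges between
  random unconnected pairs elsewhere. Global edge count is preserved
  (groups stay cost-matched at every sparsity), while the affected
  node's degree and nodal efficiency drop in expectation — the planted
  effect the nodal inference must recover. A variant that rewires the
  affected node's edges to new partners while keeping its degree was
  considered and rejected: it leaves nodal degree untouched and the
  random shortcuts it creates tend to *raise* the node's efficiency,
  so it plants no recoverable deficit. The default affected nodes
  (1-based atlas indices 32, 35, 47, 67: anterior cingulate,
  posterior cingulate, lingual, precuneus territory) sit in the
  default-mode/visual territory where case–control nodal differences
  are typically reported.
* **Time series** are zero-mean Gaussian with covariance
  I + w·A (w = 0.25 by default), eigenvalue-clipped at 1e-6;
  the series is scaled by an amplitude parameter that leaves
  correlations unchanged. Adjacent pairs thus have population
  correlation w and non-adjacent pairs 0, so top-|z| binarization at
  the true sparsity recovers ≥ 95 % of true edges at a few hundred
  frames. The generator makes no attempt at hemodynamic realism (no
  BOLD forward model, no autocorrelation, no physiological noise);
  what passing recovery tests show is that the *analysis chain* is
  correct and calibrated, not that it is robust to every property of
  real fMRI noise.
* **Motion** is a uniform random-walk drift (±0.01 mm or deg per
  frame, keeping baseline FD ≈ 0.05 mm, comparable to a compliant
  subject) plus persistent steps of 0.6 mm at spike frames drawn with
  probability 0.03 per frame — so the set of frames exceeding the
  0.3 mm threshold equals the planted spike set exactly.
* **Behavioral scores** (a total and three subscales, generated
  independently) are intercept + slope·(reference-node degree) +
  Gaussian noise; the implied population correlation is
  slope·sd(value)/sqrt(slope²·var(value) + noise_sd²). Recovery tests
  set the noise for a target population r (0.6 in the headline test).
* **Seeding**: a single master `SeedSequence` spawns
  [subjects, behavior, ages]; each subject spawns
  [graph, time series, motion]. Generation is bit-reproducible given
  (spec, seed), and any stage can be regenerated in isolation.

## Replicate experiments and problem sizes

`fconn.experiments` runs the calibration and recovery studies on a
scaled-down design chosen once: 30 nodes, 12 + 12 subjects, 150
frames, k = 6, edge weight 0.3, an 8-point sparsity grid
(0.12–0.26, step 0.02), degree as the probed nodal metric, 200–500
permutations, and 500 replicates. These sizes keep hundreds of
full-chain replicates cheap while preserving every stage of the
mechanism; the type-I calibration uses the full 18 + 18 group size
since it skips the network stage. Observed behaviour: permutation
type-I error within the 95 % binomial band of 0.05; planted-degradation
and planted-correlation (population r = 0.6) recovery well above the
80 % design target.

## Known limitations

* Binary graphs only; weighted variants, modularity, rich-club and
  hub classification are out of scope.
* The generator's covariance model is direct (I + w·A), not a
  precision-matrix or dynamical model; indirect functional coupling
  through shared neighbours is absent by construction.
* The ideal bandpass assumes uniform sampling; heavily scrubbed data
  (many deleted frames) weaken that assumption for any filter applied
  beforehand.
* Nodal permutation p-values are uncorrected beyond the 1/N screening
  convention; no FDR/FWE machinery is included.
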