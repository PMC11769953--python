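# Methods

## The model

`dynstates` analyses parcellated multi-subject resting-state BOLD series as
a sequence of recurring whole-brain states.  The generative model is a
hidden Markov model with K latent states and Gaussian observations: at each
TR the brain occupies exactly one state `z_t ∈ {1..K}`, the state sequence
follows a first-order Markov chain with initial distribution π and
row-stochastic transition matrix A, and the observed N-region vector is
drawn from a state-specific full-covariance Gaussian,

    x_t | z_t = k  ~  N(μ_k, Σ_k).

All subjects share one set of states (one π, A, {μ_k, Σ_k}); per-subject
structure enters only through chain restarts — the forward recursion
restarts from π at each subject's first row, so state sequences are never
bridged across subjects.  The state mean μ_k, on standardized data, is the
state's *activation map* (positive = above the region's temporal mean while
the state is active); the state covariance Σ_k, rescaled to correlation, is
the state's *functional-connectivity matrix*.

Because the observation model is not stated in the kind of study this
pipeline reproduces, the full-covariance Gaussian was chosen as the variant
most consistent with reporting both per-state activation maps and per-state
FC matrices; a mean-only or autoregressive observation model would support
one but not both.

## Inference: variational Bayes and the free energy

Inference is conjugate variational Bayes with a mean-field factorisation
over (π, A, {μ_k, Λ_k = Σ_k⁻¹}, Z):

* Dirichlet priors on π and on each row of A.  The transition prior adds a
  "sticky" extra concentration (default 10) to the diagonal, which
  discourages degenerate fast-switching solutions; with thousands of
  timepoints its effect on the posterior mean is of order 10/count ≈ 0.01.
* Normal–Wishart priors on (μ_k, Λ_k): mean-precision scale β₀ = 0.01
  (weak), Wishart dof ν₀ = N + 2 (smallest integer dof with a finite
  mean covariance), Wishart scale = identity, appropriate for standardized
  (unit-variance) data.

The E-step runs scaled forward–backward under the sub-normalised quantities
exp E[log π], exp E[log A], exp E[log p(x|k)]; the M-step is the standard
conjugate update.  The variational free energy is

    F = − Σ_subjects log Z̃_s + KL(q(π)‖p(π)) + Σ_i KL(q(A_i·)‖p(A_i·))
        + Σ_k KL(q(μ_k, Λ_k)‖p(μ_k, Λ_k)),

where log Z̃_s is the E-step log-normaliser of subject s.  F is the negative
evidence lower bound: it is non-increasing over iterations (asserted in the
test suite for every fit) and, at K = 1, equals the negative closed-form
Normal–Wishart log evidence exactly — this identity is verified to 1e-6 and
pins down every term of the implementation.

**Model-order selection.**  The number of states is the arg-min of the
final free energy over K = 2..15 (ties toward smaller K, for parsimony and
determinism).  Unused states collapse onto their priors, so F(K) flattens
and then rises past the true K through the parameter-complexity terms.

**Initialisation and determinism.**  Each fit runs `n_init` (default 5)
k-means-style initialisations: timepoints are hard-assigned to states by
k-means, softened to responsibilities (0.9 one-hot + 0.1 uniform), and one
conjugate M-step produces the starting posterior.  K-means runs on a
lexicographically sorted copy of the rows, which makes the initialisation —
and therefore the entire fit — invariant to subject ordering.  Every
initialisation is burned in for 30 iterations; the one with the lowest free
energy is continued until the relative change |ΔF|/|F| < 1e-5 or 500
iterations (the usual short-run strategy).  A master seed spawns per-init
seeds, so fits are bit-reproducible.

**Numerical choices.**  Forward–backward runs in scaled space (stable for
T ≥ 10,000, verified); a ridge of 1e-6·I is added to posterior scale
matrices before inversion; state labels are matched across fits (label
switching) by maximising total Pearson correlation between state-mean
vectors with an exact linear assignment.  State indices are 0-based
internally and 1-based in all written reports.

## Temporal metrics

For each subject, from the fitted posterior:

* **Fractional occupancy (FO)** — column means of the soft responsibilities
  γ (the posterior-mean analogue of time-point counting).
* **Lifetime (LT)** — mean length of a state's maximal constant runs in the
  hard Viterbi path, reported in TRs and seconds (TR = 2 s by default).
  Runs presuppose discrete assignments, hence the hard path; a state never
  visited yields a missing value, and such subjects are dropped from that
  state's group comparison with a logged count.
* **Switching rate (SR)** — state changes per transition opportunity,
  `#{t: z_t ≠ z_{t−1}} / (T − 1)`.
* **Empirical transition matrix** — row-normalised successor counts of the
  hard path.  Group comparisons of transition probabilities use these
  per-subject matrices, not the shared model's A: a single shared A admits
  no between-group test.  Diagonal entries are excluded from testing
  (self-persistence is the lifetimes' domain and is nearly collinear
  with LT).

## Group statistics

Two-group comparisons use a nonparametric permutation test: statistic =
difference of group means (patients − controls), 5,000 label permutations
by default, two-sided p with the add-one correction
`p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1)`.  Permuted subsets are drawn
from the sorted pooled sample at the smaller group's size, which makes the
p-value invariant to within-group ordering and to label swapping.
Benjamini–Hochberg FDR is applied within each metric family — FO across
states, LT across states, transition entries — a correction scope chosen to
be conservative within families and documented because the convention is
often left unstated.  Spearman correlations between each state's FO/LT and
the clinical scores (IBS-SSS, PHQ-9, PASS) are computed over patients only
(controls carry no scale scores), with FDR within each clinical variable;
results report ρ, ρ², and the large-sample p.  IBS-SSS severity bands
(<75 none, 75–175 mild, 176–300 moderate, >300 severe) and PHQ-9 bands
(floors 5/10/15/20) are provided as classification helpers.

## The synthetic cohort generator

The generator emulates the study conditions end-to-end so that every stage
can be validated against ground truth: 35 patients and 31 controls, 190
timepoints at TR = 2 s, a 6-state sticky Gaussian HMM.  The default uses 20
regions rather than the full 116-region atlas; the HMM mathematics is
dimension-agnostic and the reduced dimensionality keeps a full selection
sweep at minutes on one CPU (116 regions remains available by
configuration).

Construction:

* **Dynamics.**  The control transition matrix is sticky-uniform (diagonal
  0.7, i.e. mean dwell 3.3 TR ≈ 6.7 s, in the range typically reported for
  fMRI HMM states; off-diagonals uniform).  Its stationary distribution
  weights states by dwell mass 1/(1−s_i), which makes occupancy effects
  nearly local to the state whose diagonal is changed.
* **Group effect.**  Patients differ in exactly three rows: the designated
  "down" state's dwell is shortened by 2 TR, one off-diagonal transition
  entry is raised by 0.055 at the expense of the *other* off-diagonal
  entries of its row (leaving that source state's leave-rate, hence its
  lifetime, unchanged), and the designated "up" state's dwell is then
  re-derived by an occupancy-balancing step that solves two dwell knobs so
  every non-designated state keeps stationary occupancy exactly 1/K.
  The result is a clean ±0.10 occupancy contrast confined to the two
  designated states, an elevated lifetime in the up state, a reduced one in
  the down state, and one elevated transition probability — with no
  systematic spillover that would smear group differences across null
  states.  These magnitudes were calibrated analytically (from the chains'
  stationary laws and dwell statistics) so that the designed effects are
  reliably detectable at n = 35/31 while non-designated states remain null;
  the generating parameters of the original study are unpublished, so the
  defaults target identifiability, not unknown values.
* **Emissions.**  State means sit on random orthogonal unit directions
  scaled by `mean_separation` (default 3.0, i.e. pairwise Mahalanobis
  separation ≈ 4.2 at unit noise — identifiable but far from trivial);
  covariances are unit-scale with one state-specific rank-one bump, so
  states differ in connectivity as well as activation.
* **Clinical scores.**  Patient IBS-SSS is a linear map on the ranks of the
  designated up state's true FO plus unit Gaussian noise (`clinical_effect`
  = 1.0, giving a rank correlation ≈ 0.7), rescaled to the published
  cohort's mean ± SD (223.71 ± 50.11) and clipped to 0–500.  PHQ-9
  (5.17 ± 3.97) and PASS (29.42 ± 16.22) share a separate latent distress
  factor — mutually correlated but independent of brain-state occupancy —
  and IBS-QOL (50.94 ± 11.44) declines with the severity latent.  Any
  monotone link reproduces a rank correlation, so the linear-on-ranks
  choice is the simplest adequate one.  Controls carry missing scores.

**What the generator does not emulate:** voxel-level 4D images,
physiological noise, head motion, scanner drift, spatial autocorrelation,
or hemodynamic smoothing.  Passing tests therefore demonstrate that the
inference, metrics and statistics behave correctly for data that truly
follow a Gaussian HMM at realistic size and noise — not that real BOLD data
follow one.

Because generated series are already at the HMM's observation scale, the
synthetic pipeline mode applies only standardization; volume discarding and
band-pass filtering (0.01–0.08 Hz, zero-phase 4th-order Butterworth, chosen
so that no phase shift biases state timing) apply to the real-data input
modes, in the fixed order extract → discard → band-pass → standardize.
Standardization uses the per-subject, per-region sample (n−1) SD after
filtering; this convention sets the units of the activation maps and is
therefore stated explicitly.  Whether to standardize before HMM fitting at
all is a documented convention (it is required for a shareable Gaussian
scale across subjects).

## Problem sizes used in the shipped checks

The packaged tests and the acceptance script run at desk scale, chosen so
the full suite completes in minutes on one CPU: the model-order sweep uses
the default 20-region, 66-subject, 190-timepoint cohort with 5
initialisations per K; parameter-recovery runs 20 seeds at 10 regions and
24 subjects; statistical calibration uses 1,000 null permutation runs and
50 null cohorts; designed-effect detection uses 20 seeded cohorts with
5,000 permutations per test.

## Known limitations

* The Gaussian-observation HMM assumes mutually exclusive states and
  short-range (first-order) temporal dependence; both are simplifications
  of cortical dynamics.
* A single model is fitted to both groups jointly; group differences are
  assessed post hoc on per-subject metrics, so systematically different
  state *shapes* between groups would be absorbed into shared states.
* Free-energy model selection compares point-converged runs; with few
  initialisations the F(K) curve can be locally rough (the selection test
  uses 5 initialisations per K for this reason).
* The clinical-score generator reproduces rank correlations only; it makes
  no claim about the scales' measurement models.
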