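# Methods

## Model

`conndiff` treats resting-state large-scale brain activity as linear
diffusion of noise over the anatomical network — a multivariate
Ornstein–Uhlenbeck (OU) process

    dx(t) = A x(t) dt + σ dξ(t),        A = −I + c W,

where `W` is the structural connectivity (SC) matrix with the diagonal
removed, `c ≥ 0` the global coupling, and `ξ` independent unit white
noise per region.  The unit self-decay makes each node relax towards
zero; the equilibrium is stable exactly while `c < c_critic = 1/max_i
λ_i(W)` (real parts for asymmetric `W`).  The single coupling parameter
has no direct biological identity — it absorbs everything between
neural activity and the measured signal.

For symmetric `W` and uniform noise the stationary covariance is

    C = −(σ²/2) A⁻¹,

and Pearson correlation of `C` is the analytically predicted functional
connectivity (aFC).  Inverting,

    W_{i≠j} = −(σ²/2c) (C⁻¹)_{i≠j},      diag = 0,

so structure is minus the off-diagonal inverse covariance up to a
positive scale: both `σ` and `c` cancel in any correlation-based
comparison, which is why the inverse operation (aSC) needs no parameter
fitting.  The same algebra shows the off-diagonal partial correlation
`Π_ij = −C⁻¹_ij/√(C⁻¹_ii C⁻¹_jj)` is proportional to the inferred
structure, and that `diag(C⁻¹) = 2/σ²`, which `estimate_sigma` uses.

Assumptions worth keeping in mind: stationarity of the signal,
symmetric SC (for asymmetric covariance input the inverse problem has
infinitely many solutions and is rejected unless explicitly
symmetrized), no transmission delays, and noise that is white at the
sampling scale.

### Asymmetric drift

For asymmetric `A` the forward problem is still well posed: the
stationary covariance solves the continuous Lyapunov equation
`A C + C Aᵀ = −Σ`, which `stationary_covariance_general` solves exactly
(`mode="lyapunov"`, the default).  A truncated Baker–Campbell–Hausdorff
combination of the two propagator exponentials (`mode="bch"`, up to two
nested commutator levels) is provided as the series counterpart; its
truncation error is uncontrolled for strongly non-normal `A`, so the
Lyapunov route is the reference.  Both reduce to the closed form for
symmetric `A`.  With per-node noise the closed form `−(1/2)A⁻¹Σ` is
used only when `A` and `Σ` commute; otherwise the Lyapunov solve is
used silently.

### Small coupling and perturbations

Taylor expansion around `c = 0` gives `C ≈ (σ²/2)(I + cW)`: at weak
coupling the covariance is the identity plus a matrix proportional to
structure, so the low-`c` end of a coupling sweep measures the direct
SC–covariance similarity.  The truncation error is O(c²).

A symmetric single-edge edit `W_{ij} → W_{ij} + ε` shifts the drift by
`dA = cε(e_i e_jᵀ + e_j e_iᵀ)`; the first-order covariance response is
the resolvent expansion

    C' ≈ C + (2/σ²) C dA C,

with O(ε²) error against exact recomputation (verified by the log–log
slope test).  The cofactor route to the same result needs determinant
normalization and alternating signs to define an inverse; the resolvent
form is the numerically meaningful equivalent and is what we implement.

## Numerical choices

- Inverses are computed as linear solves against the identity, never by
  adjugates; matrices with condition number above 1e12 are rejected as
  singular.  This matters near `c_critic`, where `A` degenerates, and
  for empirical covariances after global signal regression (which
  introduces zero eigenvalues — such input is explicitly refused with a
  diagnostic).
- Stability uses the strict inequality with a 1e-9 relative margin.
  Networks whose `W` has no positive eigenvalue have no finite boundary
  (`critical_coupling` raises) but are stable at every coupling, and
  the forward operator and simulators accept them.
- Eigen-decompositions sort eigenvalues descending (ties keep the
  original order) and fix eigenvector signs by making the
  largest-magnitude component positive, so projector bases are
  deterministic.
- Window covariances subtract the within-window mean and divide by the
  window length `w` (biased form), matching the covariance definition
  used in the projector decomposition; windows floor seconds to samples
  (140 s at TR 1.94 s → 72 samples) and incomplete trailing windows are
  dropped.
- Coupling sweeps use a 200-point grid, log-dense towards `c_critic`
  where the fit curve is steepest, spanning `[1e-3, 1−1e-3]·c_critic`;
  ties break towards smaller `c`.  During the grid search the diagonal
  is kept in the correlation (it stabilizes the scaling between
  variances and covariances); the reported best fit is recomputed
  without the diagonal to remove its positive bias, and the gain is the
  fit-curve difference between the optimum and the near-zero reference
  point.
- The goodness-of-fit of a k-dimensional reduction is variance
  accounted for: `1 − ‖X − X_proj‖²_F/‖X‖²_F` on the mean-centered
  series.  Subspace similarity is the mean cosine of the principal
  angles (singular values of `AᵀB`); a single-angle variant
  (`aggregate="first"`) is available since the aggregation convention
  is not unique.
- Bootstrap confidence intervals resample masked entry pairs with
  replacement (percentile method, default 10,000 resamples, α = 0.01).
  Entry-pair resampling is the only construction applicable to a single
  matrix pair; it ignores the spatial dependence between entries of a
  connectivity matrix, so intervals should be read as descriptive.

## Simulators

Both simulators use stochastic Euler (Euler–Maruyama) integration with
noise increments `σ√dt·N(0,1)` and a mandatory seed.

- OU: step `dt` in model-time units (node relaxation time 1); steps
  ≥ 0.5 are rejected for integrator stability, 0.05 is the default.  A
  burn-in (default 20 time units, several relaxation times) is
  discarded so retained samples come from the stationary state.
- Reduced Wong–Wang mean field: one synaptic gating equation per
  region, `dS_i = [−S_i/τ_S + (1−S_i) γ H(x_i)] dt + σ dν_i`, with the
  sigmoidal firing-rate transfer `H(x) = (ax−b)/(1−exp(−d(ax−b)))`
  (removable singularity at `ax = b`, where `H = 1/d`, handled by a
  series branch).  Defaults: `w = 0.9`, `a = 270`, `b = 108` Hz,
  `d = 0.154` s, `γ = 0.641/1000`, `τ_S = 100` ms, `J_N = 0.2609` nA,
  `I_0 = 0.3` nA, noise `σ = 5e-5`, integration step 0.1 ms with
  decimation 10 (1 ms samples; 20 minutes → 1.2 million points).  The
  gating variable is integrated exactly as written — no clipping to
  [0, 1]; noise-driven excursions remain in the trajectory.

## Synthetic data

The generator emulates the features of a tractography connectome that
the analytic operators are sensitive to, on a hemisphere-ordered
parcellation (default 66 regions, three modules per hemisphere):

- log-normal edge weights (heavy-tailed, like streamline counts),
  denser within modules (0.7) than between (0.15);
- sparse non-homotopic inter-hemispheric links (density 0.05, weight
  scale 0.3);
- strong homotopic links between mirror regions, on the antidiagonal of
  the hemisphere-ordered matrix (scale 0.8);
- cohorts by multiplicative log-normal jitter of each edge (SD 0.3 by
  default, tunable to hit a target between-subject correlation);
- BOLD-like series as OU trajectories (one model-time unit = one
  second) decimated to TR 1.94 s, with optional additive measurement
  noise.

What it does **not** emulate: hemodynamics (no Balloon–Windkessel
convolution), transmission delays, fiber-length biases, scanner drift,
motion, or physiological confounds.  Tests passing on these fixtures
demonstrate the correctness and self-consistency of the operators and
the recoverability of structure under the model's own assumptions —
not that empirical BOLD data satisfy those assumptions.

## Validation scales

The test suite validates the simulators against the analytic
predictions at sizes chosen to give comfortable statistical margins:
oracle equivalence uses 10-node networks, 1e5 model-time units and five
seeds (observed lower-triangle correlations ≥ 0.999 against the
analytic covariance); recovery-versus-duration uses cumulative prefixes
of one long run per model — 16,000 model units for OU and 240 s of
Wong–Wang dynamics at the higher noise amplitude 1e-3, where the
covariance of the gating variables is informative about structure over
a 4-point doubling schedule (observed correlations rising from ~0.65 to
~0.90).  Reproductions of the published group-level numbers require the
original 14-subject structural and BOLD matrices, which are distributed
with the source publication's data deposit; the corresponding test runs
only when those files are placed under `data/empirical/`.

## Known limitations

- The inverse operation requires covariance (not correlation) input for
  absolute scales, an invertible matrix, and symmetric input; it cannot
  disambiguate asymmetric structure.
- The BCH mode's truncation error for non-normal drift is not
  characterized; use the Lyapunov mode for anything quantitative.
- Clipping negative inferred weights (on by default only in the CLI)
  breaks exact round trips; library defaults leave it off.
- Windowed inverse structure needs windows longer than the region count
  and degrades gracefully only while window covariances stay
  well-conditioned.
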