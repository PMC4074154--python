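# Methods

This note documents the models, numerical methods and conventions behind
`voltdiff`, the defaults and why they were chosen, and what the synthetic
data used in the tests does and does not establish.

## Electrode-reaction model and simulator

The simulator solves one-dimensional semi-infinite diffusion for the
species of

    A  =  B + n e-          (electrode surface, x = 0)
    B  ->  C                (homogeneous, first order, rate k1 >= 0)

with one shared diffusion coefficient D (the package regresses a single D
per system, so unequal diffusivities are out of scope).  The applied
potential is a symmetric triangle from `e_start` to `e_reverse` and back
in uniform steps `e_step`; with m increments per sweep the waveform has
2m+1 samples, the switching sample counted once.  The current follows the
oxidation convention: anodic current on the forward sweep is positive.

**Spatial discretization.**  Exponentially expanding node spacing
h_j = h0 * g^j on a domain of width `domain_factor * sqrt(D * t_total)`,
with bulk (Dirichlet) conditions at the outer edge.  The expansion puts
the first node spacing orders of magnitude below the diffusion-layer
thickness (h0 ~ 1e-7 cm at the defaults), which makes the two-point
surface-gradient formula used for the flux accurate despite its low
order.

**Time stepping.**  Crank-Nicolson for diffusion with one step per
potential increment (optionally sub-stepped).  The homogeneous B -> C
term is treated fully implicitly inside the same linear system rather
than by operator splitting or Crank-Nicolson: implicit Euler is L-stable,
so the scheme stays monotone at k1 * dt ~ 5 (k1 = 1000 s^-1 at the
default 5 ms step), where Crank-Nicolson weighting would oscillate.  All
species and nodes form one banded system (bandwidth = number of species)
solved by LAPACK's banded solver each step.

**Electrode boundary.**  Reversible kinds impose the Nernst ratio
cB(0)/cA(0) = exp(nF(E - E0)/RT) together with flux balance
(cA + cB has zero surface flux); quasi-reversible kinds impose
Butler-Volmer kinetics

    flux = ks * [cA(0) e^(alpha*phi) - cB(0) e^(-(1-alpha)*phi)],
    phi = nF(E - E0)/RT,

with symmetry factor alpha = 0.5 by default.  The product C has zero
surface flux.  Overpotentials are clipped at |phi| = 60 (far outside any
physical window) purely to avoid overflow.

**Default resolution.**  `NumericsConfig(n_space_nodes=140,
grid_expansion=1.08, domain_factor=6, time_substeps=1)`.  These defaults
were calibrated once against refined grids: doubling both the spatial
resolution and the number of substeps moves the forward peak current by
less than 0.1% over the whole parameter range used in the study
(D from 1e-6 to 5.05e-5 cm^2/s, k1 up to 1000 s^-1, ks from 1e-3 to
10 cm/s), and the reversible-limit peak gives pi*chi_p = 0.44650 against
the theoretical 0.4463 (0.05% high).  A voltammogram at these defaults
takes on the order of 0.1 s, which is what makes the 700-9800-point
grids of the simulation study practical on one CPU.

The test suite additionally checks the simulator against an *independent*
solution route: for the reversible mechanism the surface flux satisfies
an Abel-type Volterra integral equation, solved by the classical
step-function method; the two solutions agree pointwise to better than
0.5% of the peak.  Mass balance (the spatial integral of A+B+C) is
conserved to well below 0.1%.

## Classical peak-current estimate

`estimate_D_nicholson_shain` inverts pi*chi = i/(nFAc0 sqrt(D a)) at the
forward peak assuming the reversible-limit value pi*chi_p = 0.4463, with
the peak current measured from the zero-current baseline (no tail
correction), F = 96485.339 C/mol and R = 8.314472 J/(mol K).  The
estimate is exact (to simulator accuracy) for reversible transfers and
biased otherwise; the bias grows with the dimensionless follow-up rate
kappa1 = k1/a and becomes severe (tens of percent) for kappa1 >> 1.
This bias — and its absence in the trained regressors — is the central
comparison of the study.

## Preprocessing routes

* **Manual peak features** (7): forward-peak potential and current, the
  half-peak potential (rising flank, linearly interpolated at ip/2), the
  half-peak current (ip/2 by definition), reverse-peak potential, the
  peak separation Ep_for - Ep_rev, and the zero-baseline peak-current
  ratio ip_for/ip_rev.  Note that without the classical tail correction
  this ratio is about -1.35 for a reversible couple (the reverse peak
  rides on the forward diffusion tail), not 1; the uncorrected convention
  is deliberate.  A flag marks traces whose reverse extremum sits at a
  branch endpoint (e.g. fast follow-up kinetics, where the return peak
  vanishes).
* **Downsampling** keeps every 20th sample by default (1401 -> 71).
* **PCA** is mean-centered, computed by SVD, with no per-column scaling
  (all inputs share one unit, and variance scaling would distort peak
  shape); 5 components are retained.  PCA is always fitted on training
  rows only; test rows are centered with the training mean.

Inside the experiment pipeline the reduced inputs are rescaled to O(1)
using training statistics only — one global amplitude scale for PCA and
downsampling, per-column standardization for the mixed-unit manual
features — so that the regressors' default hyperparameter grids (e.g.
RBF widths ~ 1/dimension) are meaningful regardless of the raw current
magnitude (~1e-5 A).  Regression targets are D in units of 1e-5 cm^2/s
for the same conditioning reason; predictions are mapped back.

## Support vector regression

The primal objective is beta^T K beta + C * sum_i max(0, |r_i| - eps)^2
with r_i = K_i beta + b - y_i.  The dead zone is expressed on the
residual (|r| <= eps costs nothing, quadratic growth outside), which
keeps the objective continuously differentiable — the property the
Newton solver relies on.  Training is a damped Newton iteration on
(beta, b): the Hessian uses the active set (points outside the dead
zone), a Levenberg shift handles rank deficiency, and a backtracking
line search makes the objective provably nonincreasing.  With eps = 0
the problem is exactly kernel ridge regression with penalty 1/C and the
solver reproduces its closed-form solution to 1e-6; this equivalence is
asserted in the tests on random toy problems.

Hyperparameters (C, eps, and the RBF width gamma) minimize 5-fold
cross-validated mean squared error over a log-spaced grid — defaults
C in 10^-2..10^4, eps in {0} union 10^-4..10^-1 times std(y), gamma in
10^-4..10^2 divided by the input dimension — followed by a short
Nelder-Mead refinement of (C, gamma) around the grid optimum.  Folds are
seeded, so selection is deterministic.  Cross-validation was chosen as
the generalization surrogate because it is fully specifiable and
deterministic; inside the large experiment battery a coarsened grid
(5 x 3 x 5) is used to keep a full mechanism-by-estimator matrix
affordable on one CPU, without changing the protocol.

## Gaussian process regression

Covariances: linear sigma^2 (1 + <x, x'>) and squared-exponential
sigma^2 exp(-||x - x'||^2 / (2 l^2)), each plus a noise term sigma_n^2 I.
The empirical target mean is subtracted; hyperparameters maximize the
log marginal likelihood in log-parameter space by L-BFGS-B with analytic
gradients and 5 seeded multistarts (signal variance initialized near
var(y), length scale near the median pairwise distance, noise over a
wide low range).  The noise variance is optimized jointly with the other
hyperparameters.  Quasi-Newton ascent was preferred over nonlinear
conjugate gradients as the stationary points are identical and the
implementation better conditioned.  All solves go through a Cholesky
factor; if a candidate covariance is numerically indefinite, a relative
jitter escalates 1e-10 -> 1e-8 -> 1e-6 before the candidate is rejected.
Posterior mean and variance follow the standard Gaussian conditioning
formulas; variances are clipped at zero against roundoff.

## Parameter fitting

`fit_parameters` recovers (E0, ks, D) or (E0, ks, k1, D) by minimizing,
over all target voltammograms, the squared current difference after both
traces of a pair are mapped with the affine transformation that sends
the *target* trace to [-1, 1].  Scaling per curve gives small-amplitude
voltammograms the same weight as large ones; deriving the map from the
target alone (rather than scaling each trace by its own extrema) is an
identifiability requirement, not a detail: a voltammogram's *shape*
depends only on dimensionless groups such as ks/sqrt(aD) and k1/a, so a
fully amplitude-invariant objective has an exact flat ridge
(ks, D) -> (lambda ks, lambda^2 D) and cannot determine D, whereas the
peak amplitude scales with sqrt(D).  This was confirmed numerically: an
own-extrema variant of the objective drifted along that ridge to
lambda ~ 2 with near-zero objective.

Rate constants and D are searched on a log10 scale with bound
constraints; multistart uses a seeded Latin hypercube, plus an optional
explicit start.  The optimizer is L-BFGS-B with numerical gradients —
any bounded local method would do, the contract is objective quality.
Self-fit studies (targets simulated at known parameters over four
concentration/scan-rate combinations) recover D to 0.01% noiseless and
within 5% under 1%-of-peak Gaussian current noise.

## The simulation study

`build_grid` enumerates the parameter grids: for the follow-up (EC)
mechanism 7 rate constants k1 (1e-3..1e3 s^-1, decades) crossed with 100
diffusion coefficients (1e-6 to 5e-5 cm^2/s in 5e-7 steps, plus
5.05e-5), E0 = 0.3 V, window 0 -> 0.7 V; for the quasi-reversible (Eqr)
mechanism 14 ks values (0.001, 0.005, 0.01..0.1, 0.5, 1 cm/s) crossed
with the same D series, E0 = 0.2108 V, window 0 -> 0.5 V; their
combination (EqrC) crosses all three lists (9800 points; a ks subset
option scales it down), E0 = 0.2775 V, window 0 -> 0.6 V.  Common
conditions: 0.2 V/s, 293.15 K, 0.064 cm^2, 0.4 mmol/L, one electron,
1 mV steps.

`run_mechanism_experiment` simulates the grid (cached on disk and in
memory, keyed by a hash of every parameter), splits it 50/50 at random,
fits the preprocessing and the estimator on the training half only, and
reports per-test-item absolute errors |D_est - D| in cm^2/s, grouped by
rate constant, with 95% percentile-bootstrap confidence intervals of the
mean (1000 resamples by default).  Every stochastic step — split, CV
folds, GP multistarts, bootstrap — draws its seed hierarchically from
one experiment seed (default 1400), so runs are reproducible end to end.

On this synthetic study the nonlinear regressors (SVR-RBF, GP with
squared-exponential covariance, both on 5 PCA components) beat the
classical inversion by orders of magnitude on average, their error is
nearly flat across k1 while the classical error climbs above the D-grid
spacing (5e-7 cm^2/s) for k1 > 1 s^-1, nonlinear kernels/covariances
beat their linear counterparts, and the manual peak features lose
accuracy relative to PCA.

## What the synthetic data does not show

The training and test voltammograms are noiseless, share one set of
experimental conditions, and come from the same simulator that defines
the truth.  Consequently the regression errors reported here (down to
~1e-12 cm^2/s for GP interpolation) reflect smooth-manifold
interpolation at float64 precision, not measurement accuracy; with
instrument noise, baseline drift, uncompensated resistance or
capacitive charging current — none of which are modelled — absolute
errors would be far larger, even though the *orderings* among methods
are the quantity of interest.  A related caveat: on half-size grids the
GP errors for PCA and manual features both sit at the numerical floor
and their ordering is sign-noise; the preprocessing comparison is
therefore made on the full 700-point grid, where it is clean.

Other known limitations: no migration, convection, double-layer
capacitance or ohmic drop; planar macroelectrode geometry only; equal
diffusion coefficients; first-order irreversible follow-up kinetics
only.  The `estimate` CLI applies the classical inversion to voltammogram
files directly, while model-based estimation on files goes through a
`TrainedPipeline` (training-grid reducer state plus regressor), which can
normalize currents by (c0 v) to place voltammograms recorded at other
concentrations and scan rates on the training scale.
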