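# Methods

## Model and assumptions

The signal model is the two-compartment "standard model" of white matter
restricted to a single fiber population: intra-neurite water in sticks
(zero transverse diffusivity, longitudinal diffusivity Da) and
extra-neurite water in an axially symmetric Gaussian tensor
(De_par, De_perp) locally aligned with each stick; a voxel is the
ODF-average of the per-segment kernel. Assumed throughout: no
inter-compartment exchange, Gaussian compartments (long-diffusion-time
regime), no compartmental T2 difference, identical scalar parameters for
all segments in a voxel. Consequently the fractions are T2-weighted signal
fractions, not volume fractions. Diffusion-time dependence, exchange,
stationary-water and myelin-water compartments are out of scope.

Units: diffusivities in um^2/ms, b-values in ms/um^2 (1 ms/um^2 = 1000
s/mm^2), so every fitted quantity is order one.

## DKI estimation

The log signal truncated at b^2 is linear in (ln S0, D, V) with
V = MD^2 W; estimation is two-pass weighted linear least squares (OLS
predictions -> squared-signal weights -> WLLS). Directional constraints
D_app > 0, 0 < K_app < b_max/(3 D_app) are linear in the same parameters;
they are checked on the unique acquisition directions plus a 60-point
frame-attached Fibonacci sphere and, when violated, enforced by
least-distance programming reduced to a single non-negative least-squares
solve (Lawson-Hanson). The auxiliary sphere is attached to the gradient
frame — rotating the acquisition rotates it — because a fixed lab-frame
evaluation set would make the clamped estimator frame dependent.

Mean kurtosis is a numerical spherical mean of directional apparent
kurtosis over a 1152-direction Gauss-Legendre x uniform-azimuth product
quadrature (spectrally convergent for the smooth integrand; rotation
invariant to ~1e-10). Radial kurtosis and the perpendicular kurtosis
component are 64-point ring averages about the principal axis. The
principal axis is the largest-eigenvalue eigenvector with its
largest-magnitude component made positive.

The axisymmetric component set used by the inversion is
D0 = (D_par + 2 D_perp)/3, D2 = (2/3)(D_par - D_perp), W0 = Tr(W)/5
(full trace sum_ij W_iijj / 5), W2 = (3 W_par + 5 W0 - 8 W_perp)/7,
W4 = (4/7)(W_par - 3 W0 + 2 W_perp), with W_par/W_perp directional
contractions so that AK = W_par MD^2/D_par^2 and RK = W_perp MD^2/D_perp^2
hold exactly for axisymmetric tensors.

### b^2 truncation

The forward signal is not a finite cumulant series, so DKI components at
b_max = 2 carry a truncation error that vanishes as the shells shrink;
the consistency test freezes the measured envelope at the study protocol
(about 0.01 in D0, up to 0.2 in W2). This propagates into Method 1: even
noise-free, the analytic inversion of fitted (rather than exact)
components carries a nonzero f error floor at low dispersion (frozen in
the test suite as RMSD(f) < 0.12 on exactly-Watson voxels at the study
protocol) — estimation bias intrinsic to inverting a b^2-truncated
representation.

## Watson ODF mathematics

p2 and p4 use the Dawson-function closed forms with a 4-term Taylor
series below kappa = 0.02 (the p4 closed form loses ~19 digits to
cancellation by kappa = 1e-4) and asymptotic expansions above kappa =
1e4; branches agree to ~1e-12 at the switch points and match quadrature
oracles to ~1e-13 in between. kappa(p2) is inverted by bracketed Brent
iteration. Watson sampling is batch rejection against the uniform sphere
(acceptance ~ 1/sqrt(kappa); exact, deterministic under a seeded
generator).

The representative dispersion angle is theta_disp =
arccos sqrt((2 p2 + 1)/3); p2 = 0.91 and 0.79 correspond to 14 and 22
degrees, the callosal histology range.

## Method 1 (analytic inversion)

Given the five components and a trial p2, the first four moment equations
reduce to a quadratic whose two roots are the +/- branches (closed form
derived by symbolic elimination; correctness enforced by round-trip
tests, not transcribed algebra). The fifth equation, with p4 tied to p2
through the Watson kappa, is a scalar root problem on p2 in [0, 1]:
a 1000-point sign-change scan plus Brent refinement to 1e-10, including
probes at the edges of the discriminant-positive region where a root can
sit flush against the branch-merge boundary. Scan grid resolution and
tolerance were chosen so round-trip error is floating-point dominated
(~1e-9 relative).

The +1 algebraic sign is the branch that recovers tissue with
beta = (Da - De_par)/De_perp inside 4 +/- sqrt(40/3), a correspondence
enforced by the randomized round-trip tests. Plausibility filter: 0 <= f, p2 <= 1 and all
diffusivities in [0, 4] um^2/ms (upper bound deliberately above the
free-water 3 to absorb noise overshoot).

**Within-branch degeneracy.** The minus branch frequently admits *two*
exact, plausible, Watson-consistent parameter sets (the round-trip suite
exercises such cases routinely); the plus branch has not produced one. No data-driven rule can pick the true one, so the solver returns
the complete root set per branch (`BranchSolution.roots`) and selects
the largest-kappa root by default (closest to the low-dispersion
histology prior); `multiplicity` flags affected voxels. Practical
analyses on coherent white matter use the plus branch, where the issue
did not arise.

## Method 2 (rotational-invariant fit)

Shell signals (b=0-normalized) are decomposed into real, orthonormal,
even-degree spherical harmonics up to lmax = 4 (30 directions support
it; only l = 0, 2 enter the objective). The invariant convention is
S_l = sqrt((2l+1)/(4 pi) * sum_m c_lm^2), which makes S_0(0) = 1 and
factorizes the model as S_l(b) = p_l K_l(b) with kernel projections
K_l(b) = (2l+1) * int_0^1 K(b, x) P_l(x) dx (64-point Gauss-Legendre on
the half interval; validated against doubled order). The l = 2 model
invariant uses |K_2| since measured invariants are nonnegative
magnitudes while K_2 < 0 for stick-like kernels.

The objective is unweighted least squares over shells and l in {0, 2}
(trust-region reflective, box 0 <= f, p2 <= 1, 0 <= D <= 4, ftol/xtol
1e-12); the default single start is drawn uniformly with D in [0, 3].
With three shells the problem has 6 data values for 5 parameters
(1 degree of freedom, reported on every fit), so single-start fits can
and do stop in spurious minima or the wrong implicit branch; this is
reported (objective, convergence flag, optional multi-start), not
suppressed. A flat-objective probe flags p2 as unidentifiable when the
voxel has no anisotropic signal content.

## Synthetic data

The protocol generator emulates the study acquisition: shells at b = 1.0,
1.5, 2.0 ms/um^2 with one 30-direction electrostatic-repulsion table
reused on all shells (configurable), 5 b=0 volumes, delta/Delta = 35.1/
44.7 ms as metadata. Rician noise takes sigma = S(b=0)/SNR with SNR 25.
Voxels contain 30 equal-weight fiber segments drawn from a Watson
distribution without imposing axisymmetry; the *realized* stick-set
invariant p2 (addition-theorem evaluation) is the ground truth for error
scoring, not the nominal Watson value. An exact axisymmetric
Legendre-series simulator (`simulate_watson_voxel`) provides the
infinite-segment limit for truncation studies.

The cohort generator draws 26 patients and 42 controls (study
demographics for age, sex ratio, symptom score, disease duration,
medication dose), five abstract callosal regions (I-V), 20 voxels per
region by default, subject- and voxel-level variation of f and
theta_disp, and subject-level diffusivities around (2.2, 1.8, 0.5).
Group effects are synthetic calibration values — patients: f lower by
0.05 in Regions II-III, dispersion up 3 degrees in Region I — chosen to
be detectable at the study's sample size; the source literature reports
these differences only graphically, so the magnitudes are this package's
choice, not published values. What passing recovery tests show is that
the *pipeline* detects effects of this size under Rician noise and
estimator bias; they say nothing about anatomical realism (no geometry,
no partial volume beyond what the FA filter emulates, no registration
error, no crossing fibers).

## Group analysis

Voxels with FA >= 0.5 (inclusive) enter subject x region means; Welch's
unequal-variance two-sided t-test compares groups per region and
parameter; Spearman rank correlations (midrank ties; exact two-sided p
by full permutation enumeration for n <= 9 without ties, large-sample
approximation otherwise) relate patient parameters to clinical
covariates. No multiple-comparison correction is applied at the ROI
level — flags are raw p < 0.05, stated in the output schema.

## Reduced problem sizes

Shipped presets reproduce the full-scale studies at reduced n chosen for
interactive turnaround: recovery sweep 500 voxels per p2_min (full scale
10,000), fixed-truth study 200 noise realizations (full scale 1000),
null-calibration 40 seeded cohorts of 6+6 subjects x 5 regions x 3
voxels. The qualitative orderings asserted in the acceptance tests
(Method 1 beating Method 2 on f and p2 at tight dispersion with the
advantage — RMSD ratio — shrinking as dispersion grows; Method 1 more
precise but more biased than Method 2; ~5% null flag rate) were measured
at exactly these sizes and seeds. The advantage is compared as the
Method1/Method2 RMSD *ratio* because both absolute RMSDs grow at low
p2_min.

## Known limitations

* At the fixed reference truth the directional-kurtosis clamp is active
  in essentially all noisy fits (the true radial kurtosis ~7 exceeds the
  b_max/(3 D_app) bound ~2.9); the resulting Method-1 f estimates are
  strongly biased low with spread comparable to or exceeding the
  diffusivities' — so the "diffusivities scatter most" rule of thumb
  holds for Method 2 but not for Method 1's f under these conditions.
* Branch selection is a prior, not an inference; per-voxel or per-subject
  branch variation cannot be excluded by the data.
* The 6-data/5-parameter invariant fit is fundamentally
  under-determined at this acquisition; multi-start mitigates but cannot
  cure it.
* Rician noise is treated at the magnitude level only; no noise-floor
  correction is applied before fitting.
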