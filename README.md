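# dkimicro

Two-compartment white-matter microstructure modeling from diffusion
kurtosis imaging (DKI), for researchers who want to go beyond empirical
DKI metrics (FA, MK, ...) toward biophysical tissue parameters — the
intra-neurite signal fraction *f*, compartmental diffusivities
*D*<sub>a</sub>, *D*<sub>e∥</sub>, *D*<sub>e⊥</sub>, and fiber orientation
dispersion *p*<sub>2</sub> — from a clinically practical three-shell
acquisition, and who need to understand (and simulate) how reliable those
estimates are.

## The model

Intra-neurite water is a collection of zero-radius "sticks"; extra-neurite
water is an axially symmetric Gaussian ("zeppelin") aligned with each
stick. For a gradient direction **ĝ** and fiber orientation **n̂** the
per-segment signal kernel is

    K(b, ĝ·n̂) = f·exp(−b·Da·(ĝ·n̂)²) + (1−f)·exp(−b·De⊥ − b·(De∥−De⊥)·(ĝ·n̂)²)

and the voxel signal is the kernel averaged over the fiber orientation
distribution function (ODF). Two estimation routes are implemented:

* **Method 1 — analytic Watson inversion.** A constrained weighted-linear
  DKI fit supplies the axisymmetric tensor components
  {D₀, D₂, W₀, W₂, W₄}; under a Watson ODF these determine the model
  parameters in closed form up to a two-fold **branch** ambiguity (±),
  resolved by whether β = (Da−De∥)/De⊥ lies inside 4 ± √(40/3). Both
  branch solutions are returned, with plausibility filtering
  (0 ≤ f, p₂ ≤ 1; diffusivities ≤ 4 μm²/ms) and the complete root set
  when the fifth-equation root is not unique.
* **Method 2 — rotational-invariant fitting.** Per-shell spherical-harmonic
  invariants S₀(b), S₂(b) are fitted directly by S_l = p_l·K_l(b; x)
  with bounded nonlinear least squares — free of the Watson assumption,
  but with 6 invariants against 5 parameters at this acquisition, hence
  deliberately fragile from a single random start.

A synthetic-data layer simulates the study conditions end to end: the
3-shell protocol (b = 1.0/1.5/2.0 ms/μm² × 30 directions + 5 b=0, Rician
noise at SNR 25), random stick ensembles at controlled dispersion,
parameter-recovery studies (RMSD sweeps; fixed-truth accuracy/precision),
and a two-group cohort with region-wise effects feeding Welch tests and
Spearman correlations over FA-filtered callosal ROIs.

## Worked example

```python
from dkimicro import TissueParams, forward_components, solve_watson_inversion

truth = TissueParams(f=0.7, Da=2.2, De_par=1.8, De_perp=0.5)
comps = solve_watson_inversion(forward_components(truth, p2=0.7))
for sol in comps:
    print(f"{sol.branch:>5}: f={sol.f:.4f} Da={sol.Da:.4f} "
          f"De_par={sol.De_par:.4f} De_perp={sol.De_perp:.4f} "
          f"p2={sol.p2:.4f} theta={sol.theta_disp:.1f} deg")
```

prints

```
 plus: f=0.7000 Da=2.2000 De_par=1.8000 De_perp=0.5000 p2=0.7000 theta=26.6 deg
minus: f=0.6340 Da=1.7616 De_par=2.3545 De_perp=0.5484 p2=0.7599 theta=23.6 deg
```

Both parameter sets reproduce the same DKI components exactly — the
bimodality at the heart of the branch-selection problem. The plus branch
recovers the truth because β = 0.8 lies inside 4 ± √(40/3); on real data
the choice rests on prior knowledge (callosal histology: θ_disp 14–22°,
f ≈ 0.6–0.8 favors the plus branch). θ_disp is the representative
dispersion angle arccos√((2p₂+1)/3) in degrees.

The `examples/` scripts walk through each capability — forward
simulation, noisy DKI fitting, both inversions, recovery studies, cohort
statistics — with a line on what every printed number means. A thin
`dkimicro` command-line tool exposes the same stages (`simulate`,
`fit-dki`, `fit-method1`, `fit-method2`, `sweep`, `fixed-gt`, `cohort`,
`group-stats`).

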