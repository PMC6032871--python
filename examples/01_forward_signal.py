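"""Simulate a multi-shell diffusion signal from a dispersed fiber voxel.

Builds the three-shell protocol (b = 1, 1.5, 2 ms/um^2 x 30 directions,
5 b=0 volumes), draws 30 fiber segments from a Watson distribution at a
target dispersion, and prints noise-free and Rician-noisy signals.
"""

import numpy as np

from dkimicro import (
    FiberConfiguration,
    TissueParams,
    add_rician_noise,
    kappa_from_p2,
    odf_invariant_p_l,
    simulate_voxel,
    study_protocol,
)

rng = np.random.default_rng(0)
scheme = study_protocol()
params = TissueParams(f=0.7, Da=2.2, De_par=1.8, De_perp=0.5)

kappa = kappa_from_p2(0.85)
fibers = FiberConfiguration.from_watson(kappa, 30, rng)
print(f"target p2 = 0.85 (kappa = {kappa:.2f}); "
      f"realized stick-set p2 = {odf_invariant_p_l(fibers, 2):.4f}")

clean = simulate_voxel(scheme, fibers, params)
noisy = add_rician_noise(clean, snr=25.0, rng=rng)

for b in scheme.shells:
    m = scheme.shell_mask(b)
    print(f"b = {b:.1f}: mean signal {clean[m].mean():.4f} "
          f"(range {clean[m].min():.4f}-{clean[m].max():.4f}), "
          f"noisy mean {noisy[m].mean():.4f}")
# The spread within a shell reflects anisotropy: gradients along the fiber
# see fast intra-neurite diffusion, perpendicular ones almost none.
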