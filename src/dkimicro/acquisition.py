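"""Multi-shell acquisition schemes and deterministic direction sets.

Units: b-values are in ms/um^2 (1 ms/um^2 == 1000 s/mm^2) so that
diffusivities in um^2/ms keep all fitted quantities order one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "electrostatic_directions",
    "fibonacci_sphere",
    "study_protocol",
]

B0_THRESHOLD = 0.05  # ms/um^2, i.e. 50 s/mm^2; also the shell-grouping tolerance


@lru_cache(maxsize=None)
def electrostatic_directions(n: int, seed: int = 1234, n_iter: int = 2000) -> np.ndarray:
    """Deterministic electrostatic-repulsion point set of n directions.

    Minimizes antipodal Coulomb energy sum 1/|x_i - x_j|^2 + 1/|x_i + x_j|^2
    by projected gradient descent from a fixed-seed random start, mimicking
    the optimized gradient tables scanners use. Cached; the same table is
    returned on every call with the same arguments.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    lr = 0.01
    eye = np.eye(n)
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        anti = x[:, None, :] + x[None, :, :]
        d2 = np.sum(diff**2, axis=-1) + eye + 1e-12
        a2 = np.sum(anti**2, axis=-1) + eye + 1e-12
        # descent direction of the 1/r^2 repulsion for each point and its antipode
        g = np.sum(4 * diff / d2[..., None] ** 2 + 4 * anti / a2[..., None] ** 2, axis=1)
        gn = np.linalg.norm(g, axis=1, keepdims=True)
        g = g / np.maximum(gn, 1.0) * np.minimum(gn, 20.0)  # cap blow-ups from near pairs
        x += lr * g
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    x.setflags(write=False)
    return x


@lru_cache(maxsize=None)
def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform set of n unit vectors (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts.setflags(write=False)
    return pts


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values (ms/um^2) and gradient directions.

    ``bvals[i]`` and ``bvecs[i]`` describe volume i; b=0 volumes carry a
    zero direction vector by convention. ``metadata`` may hold gradient
    timing (delta, Delta, in ms) and the nominal b=0 SNR.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError("bvals must be (N,), bvecs (N, 3)")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        dw = bvals > B0_THRESHOLD
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("diffusion-weighted directions must have unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b0_mask))

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values (grouped within the b0 tolerance)."""
        b = self.bvals[~self.b0_mask]
        out: list[float] = []
        for v in np.sort(b):
            if not out or v - out[-1] > B0_THRESHOLD:
                out.append(float(v))
        return np.array(out)

    def shell_mask(self, b: float) -> np.ndarray:
        return (~self.b0_mask) & (np.abs(self.bvals - b) <= B0_THRESHOLD)

    def rotated(self, R: np.ndarray) -> "AcquisitionScheme":
        """Scheme with all gradient directions rotated by the 3x3 matrix R.

        The accumulated rotation is recorded so frame-attached auxiliary
        direction sets (e.g. the constraint evaluation sphere) rotate with
        the gradients, keeping estimators rotation covariant.
        """
        meta = dict(self.metadata)
        prev = np.asarray(meta.get("frame_rotation", np.eye(3)))
        meta["frame_rotation"] = np.asarray(R) @ prev
        return AcquisitionScheme(self.bvals.copy(), self.bvecs @ R.T, meta)

    @property
    def frame_rotation(self) -> np.ndarray:
        return np.asarray(self.metadata.get("frame_rotation", np.eye(3)))


def study_protocol(
    shells=(1.0, 1.5, 2.0),
    n_directions: int = 30,
    n_b0: int = 5,
    snr: float = 25.0,
    reuse_directions: bool = True,
    seed: int = 1234,
) -> AcquisitionScheme:
    """The emulated clinical protocol: 3 shells x 30 directions + 5 b=0.

    One electrostatically optimized direction table is reused on every
    shell by default (common scanner practice); set ``reuse_directions``
    False to generate an independent table per shell.
    """
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for i, b in enumerate(sorted(shells)):
        dirs = electrostatic_directions(n_directions, seed=seed if reuse_directions else seed + i)
        bvals.extend([b] * n_directions)
        bvecs.extend(list(dirs))
    return AcquisitionScheme(
        np.array(bvals),
        np.vstack(bvecs),
        metadata={"delta_ms": 35.1, "Delta_ms": 44.7, "snr": snr},
    )
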