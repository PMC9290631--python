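"""Multi-shell q-space acquisition schemes.

The default scheme mirrors a clinical two-shell protocol: 7 interleaved
b=0 volumes plus 32 directions at b = 700 s/mm^2 and 64 directions at
b = 2000 s/mm^2 (103 measurements in total).  Gradient directions are
spread quasi-uniformly on the sphere by electrostatic repulsion of
antipodally symmetric point sets, so the construction is deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "default_scheme",
    "sphere_points",
    "B0_THRESHOLD",
]

#: b-values at or below this (s/mm^2) are treated as b=0 volumes.
B0_THRESHOLD = 10.0


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the upper hemisphere."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # z in (0, 1]: hemisphere only, since directions are antipodally symmetric
    z = 1.0 - i / n
    phi = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sphere_points(n: int, iterations: int = 200, step: float = 0.005) -> np.ndarray:
    """Quasi-uniform unit directions by antipodal electrostatic repulsion.

    Starts from a Fibonacci hemisphere and relaxes the points under a
    Coulomb-like repulsion that treats each direction and its antipode as
    one charge pair.  Fully deterministic.

    Parameters
    ----------
    n : number of directions.
    iterations : relaxation sweeps.
    step : gradient step size on the sphere.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    x = _fibonacci_hemisphere(n)
    for _ in range(iterations):
        diff_m = x[:, None, :] - x[None, :, :]   # x_i - x_j
        diff_p = x[:, None, :] + x[None, :, :]   # x_i + x_j (antipode of j)
        dm = np.linalg.norm(diff_m, axis=-1)
        dp = np.linalg.norm(diff_p, axis=-1)
        np.fill_diagonal(dm, np.inf)
        dp[dp < 1e-12] = np.inf
        force = (diff_m / dm[..., None] ** 3).sum(axis=1)
        force += (diff_p / dp[..., None] ** 3).sum(axis=1)
        # project onto the tangent plane and step
        force -= (force * x).sum(axis=1, keepdims=True) * x
        x = x + step * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical hemisphere orientation (z >= 0, ties resolved on y then x)
    flip = (x[:, 2] < 0) | ((x[:, 2] == 0) & (x[:, 1] < 0))
    x[flip] *= -1.0
    return x


class AcquisitionScheme:
    """A diffusion sampling scheme: b-values and unit gradient directions.

    Invariants are checked at construction: matching lengths, unit-norm
    directions wherever b exceeds the b=0 threshold.
    """

    def __init__(self, bvals, bvecs):
        bvals = np.asarray(bvals, dtype=float).ravel()
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvals length {bvals.size} does not match bvecs shape {bvecs.shape}"
            )
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > B0_THRESHOLD
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values."""
        return np.unique(self.bvals[~self.b0_mask])

    def subset(self, mask: np.ndarray) -> "AcquisitionScheme":
        mask = np.asarray(mask, dtype=bool)
        return AcquisitionScheme(self.bvals[mask], self.bvecs[mask])

    def qvals(self, tau: float) -> np.ndarray:
        """q-space radii (mm^-1) under the narrow-pulse convention
        q = sqrt(b / (4 pi^2 tau))."""
        return np.sqrt(self.bvals / (4.0 * np.pi**2 * tau))


def default_scheme() -> AcquisitionScheme:
    """The default two-shell scheme: 7 b0 + 32 @ b=700 + 64 @ b=2000."""
    d700 = sphere_points(32)
    d2000 = sphere_points(64)
    bvals = np.concatenate([np.zeros(7), np.full(32, 700.0), np.full(64, 2000.0)])
    bvecs = np.vstack([np.zeros((7, 3)), d700, d2000])
    return AcquisitionScheme(bvals, bvecs)
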