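"""Per-voxel microstructural index maps (the eight indices).

Combines the DTI fit (FA, MD, and the principal eigenvector that orients
the RTAP/RTPP axis) with the 3D-SHORE fit (GFA, PA, MSD, RTOP, RTAP,
RTPP) over a block of voxels sharing one acquisition scheme.  The basis
scale zeta is estimated once per block from the median DTI mean
diffusivity.  Voxels that fail either fit carry NaN in every index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionScheme
from .dti import fa_from_eigenvalues, fit_dti_block
from .shore import (
    DEFAULT_LAMBDA,
    DEFAULT_RADIAL_ORDER,
    DEFAULT_TAU,
    ShoreIndexEngine,
    fit_shore_block,
)

__all__ = ["INDEX_NAMES", "ShoreSettings", "IndexMaps", "compute_index_maps"]

log = logging.getLogger(__name__)

#: Canonical index order used everywhere downstream.
INDEX_NAMES = ("fa", "md", "gfa", "pa", "msd", "rtop", "rtap", "rtpp")


@dataclass(frozen=True)
class ShoreSettings:
    """Hyperparameters of the SHORE stage, recorded in every output."""

    radial_order: int = DEFAULT_RADIAL_ORDER
    tau: float = DEFAULT_TAU
    lambda_n: float = DEFAULT_LAMBDA
    lambda_l: float = DEFAULT_LAMBDA


@dataclass
class IndexMaps:
    """Eight per-voxel scalar fields plus the fit metadata."""

    values: dict[str, np.ndarray]  # index name -> (voxels,)
    zeta: float
    settings: ShoreSettings = field(default_factory=ShoreSettings)

    def __post_init__(self):
        missing = set(INDEX_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing index maps: {sorted(missing)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    @property
    def n_voxels(self) -> int:
        return next(iter(self.values.values())).shape[0]


def compute_index_maps(signals: np.ndarray, scheme: AcquisitionScheme,
                       settings: ShoreSettings | None = None) -> IndexMaps:
    """All eight indices for a (voxels, measurements) signal block.

    The RTAP/RTPP reference axis of each voxel is its DTI principal
    eigenvector.  Failed voxels (non-positive or non-finite signals) are
    NaN in every index; their count is logged.
    """
    settings = settings or ShoreSettings()
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != len(scheme):
        raise ValueError(
            f"signal block has {signals.shape[1]} measurements, scheme has {len(scheme)}"
        )
    evals, e1, _ = fit_dti_block(signals, scheme)
    coeffs, zeta = fit_shore_block(
        signals, scheme,
        radial_order=settings.radial_order, tau=settings.tau,
        lambda_n=settings.lambda_n, lambda_l=settings.lambda_l,
    )
    engine = ShoreIndexEngine(settings.radial_order, zeta, settings.tau)
    shore_vals = engine.all_indices(coeffs, e1)

    values = {
        "fa": fa_from_eigenvalues(evals),
        "md": evals.mean(axis=1),
        **{k: shore_vals[k] for k in ("gfa", "pa", "msd", "rtop", "rtap", "rtpp")},
    }
    # a voxel failing any fit is invalid everywhere
    invalid = np.zeros(signals.shape[0], dtype=bool)
    for v in values.values():
        invalid |= ~np.isfinite(v)
    if invalid.any():
        log.warning("%d of %d voxels failed index computation (set to NaN)",
                    int(invalid.sum()), signals.shape[0])
        for v in values.values():
            v[invalid] = np.nan
    # FA on a valid voxel is clipped to [0, 1] against rounding excursions
    np.clip(values["fa"], 0.0, 1.0, out=values["fa"])
    return IndexMaps(values=values, zeta=zeta, settings=settings)
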