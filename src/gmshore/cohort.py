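"""Synthetic two-group gray-matter cohorts.

Generates per-subject, per-ROI multi-shell diffusion signal blocks,
regional morphometry, and clinical covariates for a PPMS vs. RRMS style
two-group study (default 45 + 45 subjects, 11 gray-matter ROIs).

The voxel signal model is a two-compartment Gaussian mixture — a mildly
anisotropic "tissue" tensor plus a faster quasi-isotropic compartment —
with per-voxel fraction and orientation jitter and per-subject diffusivity
variation.  Group differences are injected through an ``effect_map`` of
per-ROI multiplicative shifts on diffusivities, compartment fractions,
volumes, or thicknesses; by default the progressive group carries a
hippocampal restriction deficit (higher diffusivity) and a smaller
thalamus, which downstream analyses should recover.  Magnitude noise is
Rician, built from two Gaussian channels with sigma = s0 / SNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import AcquisitionScheme, default_scheme

__all__ = [
    "ROIS",
    "SUBCORTICAL_ROIS",
    "CORTICAL_ROIS",
    "GROUPS",
    "TissueCompartment",
    "CovariateParams",
    "CohortConfig",
    "SubjectRecord",
    "simulate_signal",
    "simulate_covariates",
    "build_cohort",
    "default_covariate_params",
    "default_effect_map",
]

log = logging.getLogger(__name__)

#: The 11 study ROIs (hemisphere-merged), subcortical first.
SUBCORTICAL_ROIS = ("thalamus", "caudate", "putamen", "hippocampus")
CORTICAL_ROIS = (
    "insula",
    "precuneus",
    "superior_frontal",
    "posterior_cingulate",
    "lateral_occipital",
    "lingual",
    "pericalcarine",
)
ROIS = SUBCORTICAL_ROIS + CORTICAL_ROIS

GROUPS = ("PPMS", "RRMS")


# --------------------------------------------------------------------------
# compartments and the forward signal model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueCompartment:
    """One Gaussian diffusion compartment: a 3x3 tensor and a volume fraction."""

    tensor: np.ndarray  # mm^2/s, symmetric positive semi-definite
    fraction: float

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.allclose(t, t.T, atol=1e-12):
            raise ValueError("tensor must be symmetric")
        if np.linalg.eigvalsh(t).min() < -1e-15:
            raise ValueError("tensor eigenvalues must be non-negative")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        object.__setattr__(self, "tensor", t)


def _axisymmetric_tensor(axial: float, radial: float, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return radial * np.eye(3) + (axial - radial) * np.outer(axis, axis)


def simulate_signal(compartments, scheme: AcquisitionScheme, s0: float,
                    snr: float | None = None, seed: int | None = None) -> np.ndarray:
    """Multi-tensor forward signal S(b, g) = s0 * sum_i f_i exp(-b g'D_i g).

    With ``snr`` set, Rician magnitude noise is applied per measurement:
    two independent Gaussian channels with sigma = s0 / snr.
    """
    if len(compartments) == 0:
        raise ValueError("compartment list must not be empty")
    fractions = np.array([c.fraction for c in compartments], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"compartment fractions sum to {fractions.sum():.12g}, not 1")
    if not s0 > 0:
        raise ValueError("s0 must be positive")
    b = scheme.bvals
    g = scheme.bvecs
    signal = np.zeros(len(scheme))
    for comp in compartments:
        # quadratic form g' D g per measurement
        adc = np.einsum("mi,ij,mj->m", g, comp.tensor, g)
        signal += comp.fraction * np.exp(-b * adc)
    signal *= s0
    if snr is not None:
        if not snr > 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1, n2 = rng.normal(0.0, sigma, (2, len(scheme)))
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return signal


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateParams:
    """Per-group demographic distributions (mean, SD, printed range)."""

    age: tuple[float, float, float, float]        # mean, sd, lo, hi (years)
    duration: tuple[float, float, float, float]   # years
    edss: tuple[float, float, float, float]       # EDSS score
    n_female: int
    n_male: int


def default_covariate_params() -> dict[str, CovariateParams]:
    """Published group demographics of the 45+45 cohort."""
    return {
        "RRMS": CovariateParams(
            age=(42.8, 9.9, 21.0, 61.0),
            duration=(7.3, 6.2, 1.0, 26.0),
            edss=(2.8, 1.2, 0.0, 5.0),
            n_female=32, n_male=13,
        ),
        "PPMS": CovariateParams(
            age=(47.4, 10.9, 23.0, 69.0),
            duration=(12.1, 7.8, 1.0, 32.0),
            edss=(4.7, 1.3, 2.0, 7.0),
            n_female=26, n_male=21,
        ),
    }


def _truncated_normal(rng, mean, sd, lo, hi, n):
    """Rejection sampling: exact range compliance."""
    if sd == 0:
        return np.full(n, float(mean))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, 2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def simulate_covariates(group: str, n: int, params=None, seed: int | None = None):
    """Draw ``n`` covariate records for one group.

    Ages and disease durations come from truncated normals at the group's
    published mean/SD clipped to the printed range; EDSS is rounded to the
    nearest 0.5 step; sex matches the group's published female/male split
    as closely as ``n`` allows.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    params = (params or default_covariate_params())[group] if not isinstance(params, CovariateParams) else params
    rng = np.random.default_rng(seed)
    age = _truncated_normal(rng, *params.age, n)
    duration = _truncated_normal(rng, *params.duration, n)
    edss = _truncated_normal(rng, *params.edss, n)
    edss = np.clip(np.round(edss * 2.0) / 2.0, params.edss[2], params.edss[3])
    frac_female = params.n_female / (params.n_female + params.n_male)
    n_female = int(round(n * frac_female))
    sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sex)
    return [
        {"age": float(age[i]), "disease_duration": float(duration[i]),
         "edss": float(edss[i]), "sex": str(sex[i])}
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# cohort configuration
# --------------------------------------------------------------------------

#: Baseline morphometry: hemisphere-averaged volumes (mm^3) for subcortical
#: ROIs and cortical thicknesses (mm), with generic adult SDs.
MORPHOMETRY_BASELINE = {
    "thalamus": (7700.0, 600.0),
    "caudate": (3600.0, 350.0),
    "putamen": (5000.0, 450.0),
    "hippocampus": (4000.0, 350.0),
    "insula": (3.00, 0.12),
    "precuneus": (2.40, 0.12),
    "superior_frontal": (2.70, 0.12),
    "posterior_cingulate": (2.50, 0.12),
    "lateral_occipital": (2.20, 0.12),
    "lingual": (2.00, 0.12),
    "pericalcarine": (1.60, 0.12),
}

ETIV_BASELINE = (1.5e6, 1.5e5)  # mm^3

#: Baseline gray-matter voxel mixture: a mildly anisotropic tissue tensor
#: (axial 1.0e-3, radial 0.5e-3 mm^2/s) plus a faster quasi-isotropic
#: compartment (1.8e-3 mm^2/s), 80/20 by volume.
BASELINE_TISSUE = {
    "tissue_axial": 1.0e-3,
    "tissue_radial": 0.5e-3,
    "fast_diffusivity": 1.8e-3,
    "tissue_fraction": 0.8,
}


@dataclass(frozen=True)
class ROIEffect:
    """Multiplicative group-specific shifts for one ROI."""

    diffusivity: float = 1.0       # scales both compartments' tensors
    tissue_fraction: float = 1.0   # scales the tissue compartment fraction
    volume: float = 1.0
    thickness: float = 1.0


def default_effect_map() -> dict[str, dict[str, ROIEffect]]:
    """Ground-truth group differences injected by default.

    The progressive group gets a 10% hippocampal diffusivity increase
    (lower restriction, hence lower RTOP/RTAP/RTPP) and a 15% thalamic
    volume reduction — the qualitative pattern downstream selection and
    statistics should recover.
    """
    return {
        "hippocampus": {"PPMS": ROIEffect(diffusivity=1.10)},
        "thalamus": {"PPMS": ROIEffect(volume=0.85)},
    }


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to regenerate a cohort bit-identically."""

    n_per_group: int = 45
    rois: tuple[str, ...] = ROIS
    voxels_per_roi: int = 200
    effect_map: dict = field(default_factory=default_effect_map)
    snr: float | None = 30.0
    seed: int = 0
    covariate_params: dict = field(default_factory=default_covariate_params)
    s0: float = 100.0
    subject_sd: float = 0.03        # per-subject diffusivity variation (fraction)
    voxel_fraction_sd: float = 0.05  # per-voxel tissue-fraction jitter (absolute)

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        bad = set(self.effect_map) - set(self.rois)
        if bad:
            raise ValueError(f"effect_map keys not in ROI list: {sorted(bad)}")
        for roi, per_group in self.effect_map.items():
            unknown = set(per_group) - set(GROUPS)
            if unknown:
                raise ValueError(f"effect_map[{roi!r}] has unknown groups {sorted(unknown)}")


@dataclass
class SubjectRecord:
    """One synthetic subject: label, covariates, signals, morphometry."""

    subject_id: str
    group: str
    covariates: dict
    signals: dict[str, np.ndarray]       # roi -> (voxels, measurements)
    morphometry: dict[str, float]        # vol_<roi> (mm^3) / thick_<roi> (mm)
    etiv: float                          # mm^3


def _roi_effect(config: CohortConfig, roi: str, group: str) -> ROIEffect:
    return config.effect_map.get(roi, {}).get(group, ROIEffect())


def build_cohort(config: CohortConfig | None = None,
                 scheme: AcquisitionScheme | None = None) -> list[SubjectRecord]:
    """Generate the full two-group cohort, deterministic under config.seed."""
    config = config or CohortConfig()
    scheme = scheme or default_scheme()
    root = np.random.SeedSequence(config.seed)
    cov_seeds = root.spawn(2)
    subj_seeds = root.spawn(2 * config.n_per_group)

    base = BASELINE_TISSUE
    # per-ROI orientation fields are a fixed property of the (synthetic)
    # anatomy: identical across subjects, varied across voxels
    roi_axes = {}
    for ri, roi in enumerate(config.rois):
        axis_rng = np.random.default_rng([config.seed, ri, 914])
        axes = axis_rng.standard_normal((config.voxels_per_roi, 3))
        roi_axes[roi] = axes / np.linalg.norm(axes, axis=1, keepdims=True)

    subjects: list[SubjectRecord] = []
    idx = 0
    for gi, group in enumerate(GROUPS):
        covs = simulate_covariates(
            group, config.n_per_group,
            config.covariate_params[group],
            seed=cov_seeds[gi],
        )
        for k in range(config.n_per_group):
            rng = np.random.default_rng(subj_seeds[idx])
            subj_scale = 1.0 + config.subject_sd * rng.standard_normal()
            subj_scale = max(subj_scale, 0.5)
            signals = {}
            for roi in config.rois:
                eff = _roi_effect(config, roi, group)
                dscale = subj_scale * eff.diffusivity
                f_tissue = np.clip(
                    base["tissue_fraction"] * eff.tissue_fraction
                    + config.voxel_fraction_sd * rng.standard_normal(config.voxels_per_roi),
                    0.05, 0.95,
                )
                axes = roi_axes[roi]
                # vectorized two-compartment forward model (voxels x measurements)
                cos2 = (axes @ scheme.bvecs.T) ** 2
                adc_tissue = dscale * (
                    base["tissue_radial"]
                    + (base["tissue_axial"] - base["tissue_radial"]) * cos2
                )
                att_tissue = np.exp(-scheme.bvals[None, :] * adc_tissue)
                att_fast = np.exp(-scheme.bvals * base["fast_diffusivity"] * dscale)
                block = config.s0 * (
                    f_tissue[:, None] * att_tissue
                    + (1.0 - f_tissue)[:, None] * att_fast[None, :]
                )
                if config.snr is not None:
                    sigma = config.s0 / config.snr
                    n1, n2 = rng.normal(0.0, sigma, (2,) + block.shape)
                    block = np.sqrt((block + n1) ** 2 + n2**2)
                signals[roi] = block

            morpho = {}
            for roi in config.rois:
                eff = _roi_effect(config, roi, group)
                mean, sd = MORPHOMETRY_BASELINE[roi]
                if roi in SUBCORTICAL_ROIS:
                    val = max(rng.normal(mean * eff.volume, sd), 1.0)
                    morpho[f"vol_{roi}"] = float(val)
                else:
                    val = max(rng.normal(mean * eff.thickness, sd), 0.1)
                    morpho[f"thick_{roi}"] = float(val)
            etiv = max(rng.normal(*ETIV_BASELINE), 1e5)

            subjects.append(SubjectRecord(
                subject_id=f"{group.lower()}_{k:03d}",
                group=group,
                covariates=covs[k],
                signals=signals,
                morphometry=morpho,
                etiv=float(etiv),
            ))
            idx += 1
    return subjects
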