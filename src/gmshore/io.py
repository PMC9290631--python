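"""File formats: NIfTI + FSL gradient tables, TSV outputs, YAML config.

Conventions: FSL-dialect ``bvals``/``bvecs`` text files (space-separated,
one row of b-values, three rows of direction components); integer NIfTI
label maps with a two-column ``roi_labels.tsv`` mapping; all tables are
tab-separated with ``.`` decimals; the pipeline configuration is a
strict ``key: value`` YAML document that round-trips losslessly and
rejects unknown keys.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .acquisition import AcquisitionScheme, B0_THRESHOLD
from .cohort import CohortConfig, CovariateParams, ROIEffect, SubjectRecord
from .maps import ShoreSettings
from .selection import DEFAULT_COST

__all__ = [
    "read_dwi",
    "write_dwi",
    "write_scheme",
    "write_cohort",
    "PipelineConfig",
    "load_config",
    "save_config",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# DWI + gradient tables
# --------------------------------------------------------------------------

def write_scheme(scheme: AcquisitionScheme, bvals_path, bvecs_path) -> None:
    """FSL dialect: one space-separated row of b-values, three rows of bvecs."""
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.bvecs.T, fmt="%.17g")


def write_dwi(data: np.ndarray, scheme: AcquisitionScheme, nifti_path,
              bvals_path=None, bvecs_path=None, affine=None) -> None:
    """4D NIfTI volume plus its gradient table."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 4 or data.shape[3] != len(scheme):
        raise ValueError(
            f"data must be 4D with {len(scheme)} volumes, got shape {data.shape}"
        )
    nifti_path = Path(nifti_path)
    img = nib.Nifti1Image(data, affine if affine is not None else np.eye(4))
    nib.save(img, nifti_path)
    base = nifti_path.name.split(".")[0]
    if bvals_path is None:
        bvals_path = nifti_path.parent / f"{base}.bval"
    if bvecs_path is None:
        bvecs_path = nifti_path.parent / f"{base}.bvec"
    write_scheme(scheme, bvals_path, bvecs_path)


def read_dwi(nifti_path, bvals_path, bvecs_path):
    """Load a 4D NIfTI and its FSL gradient table.

    Returns ``(data, scheme)``.  The scheme length must equal the 4th
    NIfTI dimension; non-unit directions at b > 0 are renormalized with a
    warning.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D NIfTI, got {data.ndim}D")
    bvals = np.loadtxt(bvals_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvecs_path, dtype=float)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvecs must have 3 rows, got shape {bvecs.shape}")
    bvecs = bvecs.T
    if bvals.size != bvecs.shape[0]:
        raise ValueError(
            f"bvals has {bvals.size} entries but bvecs has {bvecs.shape[0]} columns"
        )
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"gradient table has {bvals.size} entries but NIfTI has {data.shape[3]} volumes"
        )
    dwi = bvals > B0_THRESHOLD
    norms = np.linalg.norm(bvecs, axis=1)
    off = dwi & (np.abs(norms - 1.0) > 1e-6)
    if off.any():
        warnings.warn(f"renormalized {int(off.sum())} non-unit gradient direction(s)")
        bvecs[off] /= norms[off, None]
    return data, AcquisitionScheme(bvals, bvecs)


def write_cohort(cohort: list[SubjectRecord], scheme: AcquisitionScheme,
                 out_dir, rois=None) -> None:
    """Write a synthetic cohort to disk.

    Per subject: a 4D NIfTI block of shape (voxels, n_rois, 1, n_meas)
    with an integer ROI label map (1-based, mapping in roi_labels.tsv),
    one shared gradient table, and a cohort manifest TSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rois is None:
        rois = list(cohort[0].signals)
    write_scheme(scheme, out / "bvals", out / "bvecs")
    with open(out / "roi_labels.tsv", "w") as fh:
        fh.write("label\troi\n")
        for i, roi in enumerate(rois, start=1):
            fh.write(f"{i}\t{roi}\n")
    label_written = False
    rows = []
    for subj in cohort:
        block = np.stack([subj.signals[roi] for roi in rois], axis=1)
        data = block[:, :, None, :]  # voxels x rois x 1 x measurements
        nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)),
                 out / f"{subj.subject_id}_dwi.nii")
        if not label_written:
            labels = np.tile(np.arange(1, len(rois) + 1, dtype=np.int16)[None, :, None],
                             (block.shape[0], 1, 1))
            nib.save(nib.Nifti1Image(labels, np.eye(4)), out / "roi_labels.nii")
            label_written = True
        rows.append({
            "subject_id": subj.subject_id, "group": subj.group,
            **subj.covariates, "etiv": subj.etiv, **subj.morphometry,
        })
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    out_dir: str = "gmshore_out"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    shore: ShoreSettings = field(default_factory=ShoreSettings)
    cost: float = DEFAULT_COST
    n_max: int | None = None
    alpha: float = 0.05


def _cohort_to_dict(c: CohortConfig) -> dict:
    return {
        "n_per_group": c.n_per_group,
        "rois": list(c.rois),
        "voxels_per_roi": c.voxels_per_roi,
        "effect_map": {
            roi: {grp: dataclasses.asdict(eff) for grp, eff in per_group.items()}
            for roi, per_group in c.effect_map.items()
        },
        "snr": c.snr,
        "seed": c.seed,
        "covariate_params": {
            grp: {
                "age": list(p.age), "duration": list(p.duration),
                "edss": list(p.edss), "n_female": p.n_female, "n_male": p.n_male,
            }
            for grp, p in c.covariate_params.items()
        },
        "s0": c.s0,
        "subject_sd": c.subject_sd,
        "voxel_fraction_sd": c.voxel_fraction_sd,
    }


def _check_keys(d: dict, allowed, context: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")


def _cohort_from_dict(d: dict) -> CohortConfig:
    defaults = CohortConfig()
    allowed = {f.name for f in dataclasses.fields(CohortConfig)}
    _check_keys(d, allowed, "cohort")
    kwargs = dict(d)
    if "rois" in kwargs:
        kwargs["rois"] = tuple(kwargs["rois"])
    if "effect_map" in kwargs:
        kwargs["effect_map"] = {
            roi: {grp: ROIEffect(**(eff or {})) for grp, eff in per_group.items()}
            for roi, per_group in kwargs["effect_map"].items()
        }
    if "covariate_params" in kwargs:
        kwargs["covariate_params"] = {
            grp: CovariateParams(**{
                **p,
                "age": tuple(p["age"]),
                "duration": tuple(p["duration"]),
                "edss": tuple(p["edss"]),
            })
            for grp, p in kwargs["covariate_params"].items()
        }
    return dataclasses.replace(defaults, **kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    return {
        "out_dir": config.out_dir,
        "seed": config.seed,
        "cohort": _cohort_to_dict(config.cohort),
        "shore": dataclasses.asdict(config.shore),
        "cost": config.cost,
        "n_max": config.n_max,
        "alpha": config.alpha,
    }


def config_from_dict(d: dict) -> PipelineConfig:
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    _check_keys(d, allowed, "pipeline config")
    kwargs = dict(d)
    if "cohort" in kwargs:
        kwargs["cohort"] = _cohort_from_dict(kwargs["cohort"] or {})
    if "shore" in kwargs:
        shore = kwargs["shore"] or {}
        _check_keys(shore, {f.name for f in dataclasses.fields(ShoreSettings)}, "shore")
        kwargs["shore"] = ShoreSettings(**shore)
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d or {})
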