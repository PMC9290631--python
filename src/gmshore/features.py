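"""Regional moment features and the 539-column feature table.

Each of the 8 microstructural indices is reduced, per ROI, to six
distribution moments (mean, median, mode, skewness, SD, kurtosis), giving
8 x 6 x 11 = 528 diffusion features per subject; 4 eTIV-normalized
subcortical volumes and 7 cortical thicknesses complete the 539 columns.

Conventions: SD uses the n-1 denominator; skewness is the bias-uncorrected
g1; kurtosis is excess g2 (0 for a normal distribution); the mode of a
continuous sample is the center of the most populated histogram bin with
Freedman-Diaconis bin width (Sturges when the IQR is zero), ties broken
toward the lowest bin.  On a constant sample SD, skewness, and kurtosis
are all defined as 0.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CORTICAL_ROIS, GROUPS, ROIS, SUBCORTICAL_ROIS, SubjectRecord
from .maps import INDEX_NAMES, IndexMaps

__all__ = [
    "MOMENT_NAMES",
    "MomentSet",
    "roi_values",
    "robust_mode",
    "moment_set",
    "feature_columns",
    "FeatureTable",
    "assemble_feature_table",
    "write_feature_table",
    "read_feature_table",
]

log = logging.getLogger(__name__)

MOMENT_NAMES = ("mean", "median", "mode", "skewness", "sd", "kurtosis")
COVARIATE_COLUMNS = ("age", "disease_duration", "edss")


@dataclass(frozen=True)
class MomentSet:
    """Six scalars summarizing one ROI's voxel distribution for one index."""

    mean: float
    median: float
    mode: float
    skewness: float
    sd: float
    kurtosis: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MOMENT_NAMES}


def roi_values(scalar_map: np.ndarray, labels: np.ndarray, roi_id: int) -> np.ndarray:
    """Finite map values at voxels labeled ``roi_id``, in C scan order.

    NaNs are dropped with a logged count; an absent label is an error.
    """
    scalar_map = np.asarray(scalar_map, dtype=float)
    labels = np.asarray(labels)
    if scalar_map.shape != labels.shape:
        raise ValueError(
            f"map shape {scalar_map.shape} does not match labels {labels.shape}"
        )
    mask = labels == roi_id
    if not mask.any():
        raise ValueError(f"ROI id {roi_id} absent from label field")
    vals = scalar_map[mask]  # boolean indexing preserves C order
    finite = np.isfinite(vals)
    dropped = int((~finite).sum())
    if dropped:
        log.warning("ROI %s: dropped %d non-finite voxel(s)", roi_id, dropped)
    return vals[finite]


def robust_mode(values: np.ndarray) -> float:
    """Histogram mode of a continuous sample.

    Freedman-Diaconis bin width; Sturges bin count when the IQR is zero;
    the mode is the center of the most populated bin and ties break toward
    the lowest bin.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("robust_mode requires at least one finite value")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    span = hi - lo
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr > 0:
        width = 2.0 * iqr / values.size ** (1.0 / 3.0)
        n_bins = int(np.ceil(span / width)) if span / width < 65536 else 65536
        n_bins = max(1, n_bins)
    else:
        n_bins = int(np.ceil(np.log2(values.size))) + 1
    # guard against spans too small to split into finite-width bins
    while n_bins > 1 and lo + span / n_bins == lo:
        n_bins //= 2
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    best = int(np.argmax(counts))  # argmax takes the first (lowest) bin on ties
    return float(0.5 * (edges[best] + edges[best + 1]))


def moment_set(values: np.ndarray) -> MomentSet:
    """The six distribution moments of a voxel-value sample."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("moment_set requires at least one finite value")
    mean = float(values.mean())
    median = float(np.median(values))
    mode = robust_mode(values)
    if values.size < 2:
        log.warning("moment_set: n < 2, sd/skewness/kurtosis set to NaN")
        return MomentSet(mean, median, mode, float("nan"), float("nan"), float("nan"))
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        skew = kurt = 0.0  # constant-sample convention
    else:
        skew = float(sps.skew(values, bias=True))
        kurt = float(sps.kurtosis(values, fisher=True, bias=True))
    return MomentSet(mean, median, mode, skew, sd, kurt)


def feature_columns(rois=ROIS) -> list[str]:
    """Deterministic order of the 539 feature columns."""
    cols = [
        f"{index}_{moment}_{roi}"
        for index in INDEX_NAMES
        for moment in MOMENT_NAMES
        for roi in rois
    ]
    cols += [f"vol_{roi}" for roi in SUBCORTICAL_ROIS]
    cols += [f"thick_{roi}" for roi in CORTICAL_ROIS]
    return cols


N_FEATURES = len(feature_columns())  # 8*6*11 + 4 + 7 = 539
assert N_FEATURES == 8 * 6 * 11 + 4 + 7 == 539


@dataclass
class FeatureTable:
    """Subjects x 539 named features, plus group label and covariates.

    ``data`` holds one row per subject with columns: ``subject_id``,
    ``group``, the covariates, then the 539 feature columns.
    """

    data: pd.DataFrame
    metadata: dict = None

    def __post_init__(self):
        cols = self.feature_names
        if len(cols) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} feature columns, got {len(cols)}")
        if len(set(cols)) != len(cols):
            raise ValueError("duplicated feature column names")
        unknown = set(self.data["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}")
        if self.metadata is None:
            self.metadata = {}

    @property
    def feature_names(self) -> list[str]:
        reserved = {"subject_id", "group", *COVARIATE_COLUMNS}
        return [c for c in self.data.columns if c not in reserved]

    @property
    def x(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


def assemble_feature_table(cohort: list[SubjectRecord],
                           index_maps: dict[str, dict[str, IndexMaps]],
                           metadata: dict | None = None) -> FeatureTable:
    """Build the 539-column table from a cohort and its per-ROI index maps.

    ``index_maps[subject_id][roi]`` holds the voxelwise indices of that
    subject's (hemisphere-merged) ROI block.  Volumes are normalized by
    the subject's eTIV.  Any NaN feature aborts assembly (complete-case
    design, no imputation).
    """
    rows = []
    for subj in cohort:
        row = {
            "subject_id": subj.subject_id,
            "group": subj.group,
            "age": subj.covariates["age"],
            "disease_duration": subj.covariates["disease_duration"],
            "edss": subj.covariates["edss"],
        }
        try:
            maps_by_roi = index_maps[subj.subject_id]
        except KeyError:
            raise ValueError(f"no index maps for subject {subj.subject_id}") from None
        for roi in ROIS:
            if roi not in maps_by_roi:
                raise ValueError(f"subject {subj.subject_id} is missing ROI {roi!r}")
            imap = maps_by_roi[roi]
            for index in INDEX_NAMES:
                vals = imap[index]
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    raise ValueError(
                        f"subject {subj.subject_id}, ROI {roi!r}, index {index!r}: "
                        "no finite voxels"
                    )
                for moment, value in moment_set(vals).as_dict().items():
                    row[f"{index}_{moment}_{roi}"] = value
        for roi in SUBCORTICAL_ROIS:
            row[f"vol_{roi}"] = subj.morphometry[f"vol_{roi}"] / subj.etiv
        for roi in CORTICAL_ROIS:
            row[f"thick_{roi}"] = subj.morphometry[f"thick_{roi}"]
        rows.append(row)
    ordered = ["subject_id", "group", *COVARIATE_COLUMNS, *feature_columns()]
    data = pd.DataFrame(rows)[ordered]
    feats = data[feature_columns()]
    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()
        raise ValueError(f"NaN features after assembly (no imputation): {bad[:5]}")
    return FeatureTable(data=data, metadata=dict(metadata or {}))


# --------------------------------------------------------------------------
# TSV round-trip
# --------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    """Tab-separated table with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, value in sorted(table.metadata.items()):
            fh.write(f"# {key}: {value}\n")
        table.data.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    metadata = {}
    with open(path) as fh:
        text = fh.read()
    body = []
    for line in text.splitlines(keepends=True):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            metadata[key.strip()] = value.strip()
        else:
            body.append(line)
    data = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    return FeatureTable(data=data, metadata=metadata)
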