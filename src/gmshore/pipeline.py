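"""End-to-end pipeline: simulate -> fit -> extract -> stats -> select -> classify.

Each stage writes its artifacts (TSV throughout) under the configured
output directory, and a manifest records the seed and every parameter
needed to regenerate the run.  Stage failures propagate with the stage
name attached.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acquisition import default_scheme
from .cohort import build_cohort
from .features import (
    FeatureTable,
    assemble_feature_table,
    write_feature_table,
)
from .io import PipelineConfig, config_to_dict, save_config
from .maps import compute_index_maps, INDEX_NAMES
from .selection import run_selection
from .stats import (
    ancova,
    long_table,
    morphometry_long_table,
    posthoc_disease_within,
)

__all__ = ["run_pipeline", "extract_features", "run_stats", "run_classification"]

log = logging.getLogger("gmshore.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("[%s] starting", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("[%s] done", name)
            return out
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig):
    cohort_config = dataclasses.replace(config.cohort, seed=config.seed)
    scheme = default_scheme()
    return build_cohort(cohort_config, scheme), scheme, cohort_config


@_stage("extract")
def extract_features(cohort, scheme, config: PipelineConfig) -> FeatureTable:
    """Fit DTI + SHORE per voxel and reduce to the 539-column table."""
    maps = {}
    for subj in cohort:
        maps[subj.subject_id] = {
            roi: compute_index_maps(block, scheme, config.shore)
            for roi, block in subj.signals.items()
        }
    metadata = {
        "pipeline_version": __version__,
        "seed": config.seed,
        "tau": config.shore.tau,
        "radial_order": config.shore.radial_order,
        "lambda_n": config.shore.lambda_n,
        "lambda_l": config.shore.lambda_l,
    }
    return assemble_feature_table(cohort, maps, metadata=metadata)


@_stage("stats")
def run_stats(table: FeatureTable, out_dir: Path, alpha: float = 0.05):
    """Three-way ANCOVA per index, two-way for morphometry, with post-hocs."""
    effects = []
    posthocs = []
    for index in INDEX_NAMES:
        res = ancova(long_table(table, index), design="three_way")
        eff = res.effects.copy()
        eff.insert(0, "analysis", index)
        effects.append(eff)
        three_way_p = eff.loc[eff["term"] == "disease:roi:feat", "p"].iloc[0]
        if three_way_p < alpha:
            ph = posthoc_disease_within(res)
            ph.insert(0, "analysis", index)
            posthocs.append(ph)
    for kind in ("volume", "thickness"):
        res = ancova(morphometry_long_table(table, kind), design="two_way")
        eff = res.effects.copy()
        eff.insert(0, "analysis", kind)
        effects.append(eff)
        two_way_p = eff.loc[eff["term"] == "disease:roi", "p"].iloc[0]
        if two_way_p < alpha:
            ph = posthoc_disease_within(res)
            ph.insert(0, "analysis", kind)
            posthocs.append(ph)
    effects_df = pd.concat(effects, ignore_index=True)
    effects_df.to_csv(out_dir / "ancova_effects.tsv", sep="\t", index=False)
    if posthocs:
        pd.concat(posthocs, ignore_index=True).to_csv(
            out_dir / "ancova_posthoc.tsv", sep="\t", index=False)
    return effects_df


@_stage("select")
def run_classification(table: FeatureTable, config: PipelineConfig, out_dir: Path):
    """Three-step selection plus the final LOOCV classifier report."""
    result, report = run_selection(table, cost=config.cost, n_max=config.n_max)
    pd.DataFrame({
        "n": np.arange(1, result.accuracy.size + 1),
        "accuracy": result.accuracy,
        "variance": result.variance,
    }).to_csv(out_dir / "accuracy_curve.tsv", sep="\t", index=False)
    pd.DataFrame({
        "feature": result.feature_names,
        "count": [result.occurrence_counts[f] for f in result.feature_names],
        "selected": [f in result.selected for f in result.feature_names],
    }).sort_values(["count", "feature"], ascending=[False, True]).to_csv(
        out_dir / "selection.tsv", sep="\t", index=False)
    conf = report.confusion
    with open(out_dir / "classifier_report.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_opt\t{result.n_opt}\n")
        fh.write(f"tn_ppms\t{conf[0, 0]}\nfp\t{conf[0, 1]}\n")
        fh.write(f"fn\t{conf[1, 0]}\ntp_rrms\t{conf[1, 1]}\n")
        for m in ("accuracy", "sensitivity", "specificity", "precision", "auc"):
            fh.write(f"{m}\t{getattr(report, m):.6f}\n")
    pd.DataFrame(report.roc, columns=["fpr", "tpr"]).to_csv(
        out_dir / "roc_curve.tsv", sep="\t", index=False)
    return result, report


def run_pipeline(config: PipelineConfig):
    """Run every stage and write all artifacts under ``config.out_dir``.

    Returns (feature table, ancova effects, selection result, report).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.yaml")

    cohort, scheme, cohort_config = _simulate(config)
    pd.DataFrame([{
        "subject_id": s.subject_id, "group": s.group, **s.covariates,
        "etiv": s.etiv, **s.morphometry,
    } for s in cohort]).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)

    table = extract_features(cohort, scheme, config)
    write_feature_table(table, out_dir / "feature_table.tsv")
    effects = run_stats(table, out_dir, alpha=config.alpha)
    result, report = run_classification(table, config, out_dir)

    with open(out_dir / "run_manifest.yaml", "w") as fh:
        import yaml

        yaml.safe_dump({
            "pipeline_version": __version__,
            "config": config_to_dict(config),
            "n_subjects": len(table),
            "n_features": len(table.feature_names),
            "n_opt": result.n_opt,
            "selected": list(result.selected),
            "accuracy": float(report.accuracy),
            "auc": float(report.auc),
        }, fh, sort_keys=False)
    return table, effects, result, report
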