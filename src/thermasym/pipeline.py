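"""End-to-end orchestration: image -> ROIs -> symmetry vector -> study.

:func:`process_subject` turns one thermogram into its 170-dimensional
feature-symmetry vector (segmentation can be bypassed with a manual ROI
JSON).  :func:`run_study` runs a whole labeled cohort through feature
extraction, cohort-level t-test selection, and the repeated leave-30-out
evaluation of the standard feature-set combinations (all/selected
temperature, texture per Minkowski order, and their unions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify_eval import CVConfig, EvaluationReport, run_experiment
from .errors import ThermasymError
from .segmentation import FacialROISet, PAIR_LABELS, SegmentationConfig, segment
from .stats_select import SelectionResult, select_features
from .symmetry import (
    FeatureSymmetryVector,
    assemble_vector,
    names_delta_t,
    names_texture,
    pair_symmetry,
)
from .synthgen import SubjectRecord, cohort_metadata
from .thermal_io import ThermalImage, read_thermal

log = logging.getLogger("thermasym")


@dataclass
class PipelineConfig:
    """Layered configuration of the whole pipeline; defaults reproduce the
    standard protocol (Δ∈{2,5}, four directions, G∈{16,32}, P∈{1,2},
    alpha = 0.05, leave-30-out × 10)."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    mirror_mode: bool = True
    alpha: float = 0.05
    selection_mode: str = "paper_faithful"  # or 'leak_free'
    classifier: str = "svm"


def process_subject(image: ThermalImage | str, config: PipelineConfig | None = None,
                    subject_id: str = "", rois: FacialROISet | None = None
                    ) -> FeatureSymmetryVector:
    """Segment one thermogram (unless ``rois`` overrides) and assemble its
    full bilateral symmetry vector.  Deterministic."""
    cfg = config or PipelineConfig()
    if not isinstance(image, ThermalImage):
        image = read_thermal(image)
    try:
        roi_set = rois if rois is not None else segment(image, cfg.segmentation)
        pairs = []
        for pair in PAIR_LABELS:
            left = roi_set.rois[f"{pair}.L"].extract(image.values)
            right = roi_set.rois[f"{pair}.R"].extract(image.values)
            pairs.append(pair_symmetry(left, right, pair, cfg.mirror_mode))
        return assemble_vector(pairs, subject_id=subject_id)
    except ThermasymError as exc:
        log.error("subject %s failed: %s", subject_id or "<anon>", exc)
        raise


def cohort_feature_table(records: list[SubjectRecord],
                         config: PipelineConfig | None = None,
                         use_truth_rois: bool = False) -> pd.DataFrame:
    """Symmetry vectors for every cohort subject (subjects x 170)."""
    cfg = config or PipelineConfig()
    rows = {}
    for rec in records:
        rois = rec.truth.rois if use_truth_rois else None
        vec = process_subject(rec.image, cfg, subject_id=rec.subject_id, rois=rois)
        rows[rec.subject_id] = vec.to_series()
    return pd.DataFrame(rows).T


#: the standard feature-set protocol evaluated by a study run
def standard_feature_sets(selected: list[str]) -> dict[str, list[str]]:
    sel = set(selected)
    dt_all = names_delta_t()
    f1 = names_texture(p=1)
    f2 = names_texture(p=2)
    dt2 = [n for n in dt_all if n in sel]
    f3 = [n for n in f1 if n in sel]
    f4 = [n for n in f2 if n in sel]
    sets = {
        "all_dTmean": names_delta_t("mean"),
        "all_dTmax": names_delta_t("max"),
        "dT1_all_temperature": dt_all,
        "dT2_selected_temperature": dt2,
        "F1_manhattan_texture": f1,
        "F2_euclidean_texture": f2,
        "F3_selected_manhattan": f3,
        "F4_selected_euclidean": f4,
        "F1+F2_all_texture": f1 + f2,
        "F3+F4_selected_texture": f3 + f4,
        "dT1+F1+F2_all_features": dt_all + f1 + f2,
        "dT2+F3+F4_selected_features": dt2 + f3 + f4,
    }
    return {k: v for k, v in sets.items() if v}


@dataclass
class StudyResult:
    features: pd.DataFrame
    metadata: pd.DataFrame
    selection: SelectionResult
    reports: dict[str, EvaluationReport]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary_row() for r in self.reports.values()])


def run_study(records: list[SubjectRecord], config: PipelineConfig | None = None,
              feature_sets: dict[str, list[str]] | None = None,
              classifiers: tuple[str, ...] | None = None,
              out_dir: str | None = None,
              use_truth_rois: bool = False) -> StudyResult:
    """Full study: vectors -> selection -> repeated leave-k-out evaluation.

    In ``paper_faithful`` mode the t-test selection is done once on the full
    cohort before cross-validation (which leaks label information into the
    feature choice); ``leak_free`` re-selects within every training fold.
    """
    cfg = config or PipelineConfig()
    features = cohort_feature_table(records, cfg, use_truth_rois=use_truth_rois)
    metadata = cohort_metadata(records)
    selection = select_features(features, metadata.set_index("subject_id")
                                .loc[features.index, "group"],
                                alpha=cfg.alpha, mode=cfg.selection_mode)
    sets = feature_sets if feature_sets is not None \
        else standard_feature_sets(selection.selected)
    leak_free_alpha = cfg.alpha if cfg.selection_mode == "leak_free" else None
    reports: dict[str, EvaluationReport] = {}
    for kind in classifiers or (cfg.classifier,):
        for name, cols in sets.items():
            key = name if kind == cfg.classifier else f"{name}[{kind}]"
            reports[key] = run_experiment(
                features, metadata, feature_subset=cols, cv=cfg.cv, kind=kind,
                selection_alpha=leak_free_alpha, feature_set_name=name)
            log.info("%s (%s): %s", name, kind, reports[key].mean_metrics)
    result = StudyResult(features, metadata, selection, reports)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "symmetry_vectors.tsv", sep="\t")
        metadata.to_csv(out / "manifest.tsv", sep="\t", index=False)
        selection.table.to_csv(out / "selection.tsv", sep="\t")
        result.summary().to_csv(out / "performance_summary.tsv", sep="\t", index=False)
        for key, rep in reports.items():
            rep.to_json(out / f"report_{key.replace('+', '_').replace('[', '.').rstrip(']')}.json")
    return result
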