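"""End-to-end orchestration: cohort -> consensus -> patches/QIF -> models.

``run_design`` reproduces the full comparison on one cohort and design:
a CNN alone (softmax score), the CNN's 200 penultimate features fused
with the 50 radiomic features into a 1000-tree Random Forest, and the
logistic size baseline, all evaluated on a patient-level held-out
validation set with equal class counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from .cnn import ArchitectureConfig, TrainConfig, TrainedModel
from .consensus import ConsensusNodule, build_consensus
from .fusion import (
    CNN_FEATURE_NAMES,
    EvalResult,
    combine_feature_tables,
    evaluate,
    size_baseline,
    size_feature_mm,
    train_random_forest,
)
from .patches import PatchSize, records_for_selection
from .phantoms import SyntheticCohort
from .qif import QIF_FEATURE_NAMES, SegmentedNodule, auto_segment, extract_qif
from .selection import (
    CohortDesign,
    SelectedNodule,
    select_cohort,
    split_train_validation,
)

__all__ = ["DesignReport", "cohort_consensus", "qif_table", "run_design"]


def cohort_consensus(cohort: SyntheticCohort) -> list[ConsensusNodule]:
    """Consensus nodule lists for every patient of a cohort."""
    out: list[ConsensusNodule] = []
    for pid in cohort.patients:
        out.extend(build_consensus(pid, cohort.annotations[pid]))
    return out


def _nodule_mask(nodule: ConsensusNodule, cohort: SyntheticCohort) -> np.ndarray:
    """Consensus mask, or an automated segmentation for point-only regions."""
    if nodule.mask is not None:
        return nodule.mask
    return auto_segment(cohort.volumes[nodule.patient_id], nodule.centroid)


def qif_table(
    selection: list[SelectedNodule], cohort: SyntheticCohort
) -> pd.DataFrame:
    """50-column radiomic feature table, one keyed row per selected nodule."""
    rows, keys = [], []
    for sel in selection:
        volume = cohort.volumes[sel.patient_id]
        mask = _nodule_mask(sel.nodule, cohort)
        rows.append(
            extract_qif(SegmentedNodule(volume.hu, mask, volume.spacing))
        )
        keys.append(sel.key)
    return pd.DataFrame(rows, index=keys, columns=list(QIF_FEATURE_NAMES))


@dataclass
class DesignReport:
    """Results of one design run: one EvalResult per model row."""

    design: CohortDesign
    results: dict[str, EvalResult]
    n_train: int
    n_validation: int
    train_patients: set[str]
    validation_patients: set[str]
    trained_cnn: TrainedModel
    # keyed artefacts retained for downstream analyses
    train_labels: np.ndarray = field(repr=False, default=None)
    validation_labels: np.ndarray = field(repr=False, default=None)
    qif_train: pd.DataFrame = field(repr=False, default=None)
    qif_validation: pd.DataFrame = field(repr=False, default=None)
    fused_train: pd.DataFrame = field(repr=False, default=None)
    fused_validation: pd.DataFrame = field(repr=False, default=None)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: dict(auc=r.auc, acc=r.accuracy, sens=r.sensitivity,
                           spc=r.specificity)
                for name, r in self.results.items()
            }
        ).T


def run_design(
    cohort: SyntheticCohort,
    design: CohortDesign,
    arch: ArchitectureConfig = cnn_mod.CNN21,
    train_cfg: TrainConfig | None = None,
    rf_trees: int = 1000,
    seed: int = 0,
) -> DesignReport:
    """Run the full pipeline for one design on one cohort."""
    if train_cfg is None:
        train_cfg = TrainConfig(epochs=30, seed=seed)
    design = replace(design, seed=seed)

    nodules = cohort_consensus(cohort)
    selection = select_cohort(nodules, design)
    train_sel, val_sel = split_train_validation(selection, design)
    train_patients = {s.patient_id for s in train_sel}
    val_patients = {s.patient_id for s in val_sel}

    size = arch.input_size
    train_recs = records_for_selection(train_sel, cohort.volumes, size)
    val_recs = records_for_selection(val_sel, cohort.volumes, size)
    x_train, y_train, keys_train = cnn_mod.records_to_arrays(train_recs)
    x_val, y_val, keys_val = cnn_mod.records_to_arrays(val_recs)

    trained = cnn_mod.train(x_train, y_train, arch, train_cfg)
    cnn_scores = cnn_mod.predict(trained, x_val)

    feats_train = pd.DataFrame(
        cnn_mod.extract_features(trained, x_train),
        index=keys_train, columns=list(CNN_FEATURE_NAMES),
    )
    feats_val = pd.DataFrame(
        cnn_mod.extract_features(trained, x_val),
        index=keys_val, columns=list(CNN_FEATURE_NAMES),
    )
    qif_train = qif_table(train_sel, cohort)
    qif_val = qif_table(val_sel, cohort)
    fused_train = combine_feature_tables(qif_train, feats_train)
    fused_val = combine_feature_tables(qif_val, feats_val)

    rf = train_random_forest(
        fused_train.to_numpy(), y_train, n_trees=rf_trees, seed=seed
    )
    rf_scores = rf.predict_proba(fused_val.loc[keys_val].to_numpy())[:, 1]

    sizes_train = [
        size_feature_mm(_nodule_mask(s.nodule, cohort),
                        cohort.volumes[s.patient_id].spacing)
        for s in train_sel
    ]
    sizes_val = [
        size_feature_mm(_nodule_mask(s.nodule, cohort),
                        cohort.volumes[s.patient_id].spacing)
        for s in val_sel
    ]
    lm = size_baseline(sizes_train, y_train, seed=seed)
    lm_scores = lm.predict_proba(np.asarray(sizes_val).reshape(-1, 1))[:, 1]

    results = {
        "CNN": evaluate(cnn_scores, y_val),
        "CNN+RF": evaluate(rf_scores, y_val),
        "LM": evaluate(lm_scores, y_val),
    }
    return DesignReport(
        design=design,
        results=results,
        n_train=len(train_sel),
        n_validation=len(val_sel),
        train_patients=train_patients,
        validation_patients=val_patients,
        trained_cnn=trained,
        train_labels=y_train,
        validation_labels=y_val,
        qif_train=qif_train,
        qif_validation=qif_val,
        fused_train=fused_train,
        fused_validation=fused_val,
    )
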