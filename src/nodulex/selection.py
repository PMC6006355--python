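"""Study-design cohort selection and patient-level train/validation split.

Three binary designs are supported, named by the malignancy-rating classes
they oppose: S1vS45 (rating 1 vs ratings 4-5), S12vS45 (ratings 1-2 vs
4-5) and S0vS1-5 (non-nodule regions vs any rated nodule).

Selection follows a two-stage policy: one eligible nodule is drawn
uniformly per patient, then the minority class is topped up with all
eligible minority-class nodules from patients whose stage-1 draw was not a
majority-class nodule, equalising by random discard if that overshoots.
The train/validation split is patient-level (no patient contributes to
both sides) and each side is balanced to equal class counts by random
discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusNodule

__all__ = ["CohortDesign", "SelectedNodule", "DESIGNS", "select_cohort",
           "split_train_validation"]

NON_NODULE_CLASS = 0  # rating code for point-only non-nodule regions


@dataclass(frozen=True)
class CohortDesign:
    """A binary classification design over consensus malignancy classes."""

    name: str
    negative_classes: frozenset[int]
    positive_classes: frozenset[int]
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "negative_classes", frozenset(self.negative_classes))
        object.__setattr__(self, "positive_classes", frozenset(self.positive_classes))
        if self.negative_classes & self.positive_classes:
            raise ValueError("negative and positive classes must be disjoint")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def label_of(self, nodule: ConsensusNodule) -> int | None:
        """1 for positive, 0 for negative, None if ineligible."""
        if nodule.rating in self.positive_classes:
            return 1
        if nodule.rating in self.negative_classes:
            return 0
        return None


DESIGNS = {
    "S1vS45": CohortDesign("S1vS45", frozenset({1}), frozenset({4, 5})),
    "S12vS45": CohortDesign("S12vS45", frozenset({1, 2}), frozenset({4, 5})),
    "S0vS1-5": CohortDesign(
        "S0vS1-5", frozenset({NON_NODULE_CLASS}), frozenset({1, 2, 3, 4, 5})
    ),
}


@dataclass(frozen=True)
class SelectedNodule:
    nodule: ConsensusNodule
    label: int  # 0 negative, 1 positive

    @property
    def key(self) -> str:
        return self.nodule.key

    @property
    def patient_id(self) -> str:
        return self.nodule.patient_id


def select_cohort(
    nodules: list[ConsensusNodule], design: CohortDesign
) -> list[SelectedNodule]:
    """Two-stage nodule selection under a design.

    Stage 1 draws one eligible nodule uniformly at random per patient.
    Stage 2 balances classes: all eligible minority-class nodules from
    patients whose stage-1 draw was not majority-class are added, then the
    larger class is trimmed back by random discard until counts are as
    balanced as the data allows.  Deterministic under ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    eligible: dict[str, list[tuple[ConsensusNodule, int]]] = {}
    class_totals = {0: 0, 1: 0}
    for nod in nodules:
        label = design.label_of(nod)
        if label is None:
            continue
        eligible.setdefault(nod.patient_id, []).append((nod, label))
        class_totals[label] += 1
    for label in (0, 1):
        if class_totals[label] == 0:
            side = "negative" if label == 0 else "positive"
            raise ValueError(
                f"design {design.name}: no eligible nodules in the {side} "
                f"class"
            )

    # stage 1: one nodule per patient, uniform over that patient's eligibles
    selected: list[SelectedNodule] = []
    stage1_label: dict[str, int] = {}
    for pid in sorted(eligible):
        nod, label = eligible[pid][rng.integers(len(eligible[pid]))]
        selected.append(SelectedNodule(nod, label))
        stage1_label[pid] = label

    counts = [sum(1 for s in selected if s.label == lab) for lab in (0, 1)]
    if counts[0] == counts[1]:
        return selected

    minority = int(counts[1] < counts[0])
    majority = 1 - minority
    chosen_keys = {s.key for s in selected}
    # stage 2: top up with every eligible minority nodule from patients
    # whose stage-1 draw was not a majority-class nodule
    for pid in sorted(eligible):
        if stage1_label[pid] == majority:
            continue
        for nod, label in eligible[pid]:
            if label == minority and nod.key not in chosen_keys:
                selected.append(SelectedNodule(nod, label))
                chosen_keys.add(nod.key)

    counts = [sum(1 for s in selected if s.label == lab) for lab in (0, 1)]
    if counts[minority] > counts[majority]:
        # overshoot: discard topped-up minority nodules at random
        extras = [
            i for i, s in enumerate(selected)
            if s.label == minority and i >= len(stage1_label)
        ]
        n_drop = counts[minority] - counts[majority]
        drop = set(rng.choice(extras, size=min(n_drop, len(extras)),
                              replace=False).tolist())
        selected = [s for i, s in enumerate(selected) if i not in drop]
    return selected


def _balance_by_discard(records: list[SelectedNodule], rng) -> list[SelectedNodule]:
    by_label = {0: [], 1: []}
    for rec in records:
        by_label[rec.label].append(rec)
    n = min(len(by_label[0]), len(by_label[1]))
    kept: list[SelectedNodule] = []
    for label in (0, 1):
        idx = rng.permutation(len(by_label[label]))[:n]
        kept.extend(by_label[label][i] for i in sorted(idx))
    return kept


def split_train_validation(
    selection: list[SelectedNodule],
    design: CohortDesign,
    max_retries: int = 50,
) -> tuple[list[SelectedNodule], list[SelectedNodule]]:
    """Patient-level split with equal class counts on each side.

    Patients are partitioned so that no patient's nodules appear on both
    sides, with the train side holding ~``train_fraction`` of the
    patients; each side is then balanced to equal class counts by random
    discard.  Raises when a class cannot appear on both sides (e.g. all
    its nodules come from a single patient).
    """
    patients = sorted({s.patient_id for s in selection})
    for label in (0, 1):
        holders = {s.patient_id for s in selection if s.label == label}
        if len(holders) < 2:
            side = "negative" if label == 0 else "positive"
            raise ValueError(
                f"cannot balance the split: {side} class comes from "
                f"{len(holders)} patient(s)"
            )
    rng = np.random.default_rng(design.seed + 1)
    n_train = int(round(design.train_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)

    for _ in range(max_retries):
        perm = rng.permutation(len(patients))
        train_patients = {patients[i] for i in perm[:n_train]}
        train = [s for s in selection if s.patient_id in train_patients]
        val = [s for s in selection if s.patient_id not in train_patients]
        labels_ok = all(
            any(s.label == lab for s in part)
            for part in (train, val)
            for lab in (0, 1)
        )
        if labels_ok:
            return _balance_by_discard(train, rng), _balance_by_discard(val, rng)
    raise ValueError(
        "could not find a patient partition with both classes on both sides"
    )
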