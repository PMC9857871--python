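"""Patient-wise cross-validation of the annotation-QC procedure.

Both protocols split by patient so no patient's spectra appear on both
sides of a fold: leave-one-patient-out (LOPOCV) and patient-grouped k-fold
with greedy class balancing. Accuracy is the proportion of correct final
labels (true positives + true negatives over all evaluated predictions):
a prediction is correct iff the final label — the claimed label when
confirmed, the suggested label when flagged — equals the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import LabelDecision, qc_library
from .core import ConfigurationError, SpectralLibrary
from .measures import patient_mean_spectra

__all__ = [
    "FoldPlan",
    "lopocv_plan",
    "grouped_kfold_plan",
    "EvaluationReport",
    "evaluate_annotation_qc",
]


@dataclass
class FoldPlan:
    """Patient-disjoint folds: (train patients, test patients) per fold."""

    folds: list[tuple[frozenset[str], frozenset[str]]]

    def __post_init__(self) -> None:
        tested: set[str] = set()
        for train, test in self.folds:
            if train & test:
                raise ConfigurationError("a patient appears in both train and test")
            if tested & test:
                raise ConfigurationError("a patient appears in two test sets")
            tested |= test


def lopocv_plan(lib: SpectralLibrary) -> FoldPlan:
    """Leave-one-patient-out: N folds for N patients, fold i tests
    patient i against references from the other N-1."""
    patients = sorted({str(p) for p in lib.patients})
    if len(patients) < 2:
        raise ConfigurationError("LOPOCV needs at least 2 patients")
    all_p = frozenset(patients)
    return FoldPlan([(all_p - {p}, frozenset({p})) for p in patients])


def grouped_kfold_plan(lib: SpectralLibrary, k: int, seed: int = 0) -> FoldPlan:
    """Patient-disjoint k folds with approximately balanced class proportions.

    Exact stratification is impossible with patient-level atoms; patients
    (seed-shuffled, then sorted by spectra count descending) are assigned
    greedily: the first k seed the folds, each remaining patient goes to the
    fold with the largest weighted deficit of the classes it carries.
    """
    patients = sorted({str(p) for p in lib.patients})
    if len(patients) < k:
        raise ConfigurationError(f"{len(patients)} patients < k={k} folds")
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    classes = sorted({str(t) for t in lib.tissues})
    counts = {
        p: np.array(
            [
                int(
                    np.sum(
                        [str(pt) == p and str(t) == c for pt, t in zip(lib.patients, lib.tissues)]
                    )
                )
                for c in classes
            ]
        )
        for p in patients
    }
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    order.sort(key=lambda p: -counts[p].sum())  # stable: keeps shuffled tie order
    total = sum(counts[p] for p in patients)
    share = total / total.sum()
    fold_counts = [np.zeros(len(classes)) for _ in range(k)]
    assignment: list[list[str]] = [[] for _ in range(k)]
    for i, p in enumerate(order):
        if i < k:
            f = i
        else:
            # fold with the largest deficit of the classes this patient
            # carries; ties go to the emptiest fold so sizes stay even
            scores = []
            for fc in fold_counts:
                tot = fc.sum()
                fold_share = fc / tot if tot > 0 else np.zeros_like(fc)
                deficit = round(float(counts[p] @ (share - fold_share)), 12)
                scores.append((deficit, -tot))
            f = max(range(k), key=lambda i: scores[i])
        assignment[f].append(p)
        fold_counts[f] += counts[p]
    all_p = frozenset(patients)
    return FoldPlan(
        [(all_p - frozenset(a), frozenset(a)) for a in assignment]
    )


@dataclass
class EvaluationReport:
    """Aggregated QC decisions over all folds."""

    fold_decisions: list[list[LabelDecision]]
    accuracy: float
    per_tissue_accuracy: dict[str, float]
    n_total: int
    n_correct: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_tissue_accuracy": self.per_tissue_accuracy,
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "n_folds": len(self.fold_decisions),
        }


def _patient_mask(lib: SpectralLibrary, patients: frozenset[str]) -> np.ndarray:
    return np.array([str(p) in patients for p in lib.patients])


def evaluate_annotation_qc(
    lib: SpectralLibrary,
    plan: FoldPlan,
    name: str = "SID-JM-TAN(SCA)",
    k_clusters: int = 2,
    seed: int = 0,
    true_labels=None,
    per_spectrum: bool = False,
) -> EvaluationReport:
    """Run annotation QC under a fold plan and score it.

    Per fold, the references are the training patients' spectra and the
    targets the test patients'. By default decisions are made on
    per-(tissue, patient) mean spectra; ``per_spectrum=True`` checks every
    individual spectrum instead. ``true_labels`` (length K, aligned with
    ``lib``) supplies ground truth; when omitted the claimed labels are
    assumed correct.
    """
    truth = (
        np.asarray(true_labels, dtype=object)
        if true_labels is not None
        else lib.tissues.copy()
    )
    if truth.shape != lib.tissues.shape:
        raise ConfigurationError("true_labels must align with the library entries")
    fold_decisions: list[list[LabelDecision]] = []
    correct_by_tissue: dict[str, int] = {}
    total_by_tissue: dict[str, int] = {}
    n_correct = 0
    n_total = 0
    for train, test in plan.folds:
        refs = lib.subset(_patient_mask(lib, train))
        target_mask = _patient_mask(lib, test)
        if not target_mask.any():
            fold_decisions.append([])
            continue
        targets_lib = lib.subset(target_mask)
        target_truth = truth[target_mask]
        if not per_spectrum:
            refs = patient_mean_spectra(refs)
            grouped = patient_mean_spectra(targets_lib)
            # truth of a (tissue, patient) mean: majority truth of its members
            group_truth = []
            for tissue, patient in grouped.keys():
                member = [
                    str(tr)
                    for tr, t, p in zip(
                        target_truth, targets_lib.tissues, targets_lib.patients
                    )
                    if str(t) == tissue and str(p) == patient
                ]
                vals, counts = np.unique(member, return_counts=True)
                group_truth.append(str(vals[np.argmax(counts)]))
            targets_lib = grouped
            target_truth = np.asarray(group_truth, dtype=object)
        decisions = qc_library(targets_lib, refs, name=name, k=k_clusters, seed=seed)
        fold_decisions.append(decisions)
        for d, tr in zip(decisions, target_truth):
            ok = d.final_label() == str(tr)
            n_total += 1
            n_correct += ok
            total_by_tissue[str(tr)] = total_by_tissue.get(str(tr), 0) + 1
            correct_by_tissue[str(tr)] = correct_by_tissue.get(str(tr), 0) + ok
    if n_total == 0:
        raise ConfigurationError("fold plan tested no spectra from this library")
    return EvaluationReport(
        fold_decisions=fold_decisions,
        accuracy=n_correct / n_total,
        per_tissue_accuracy={
            t: correct_by_tissue.get(t, 0) / n for t, n in sorted(total_by_tissue.items())
        },
        n_total=n_total,
        n_correct=n_correct,
    )
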