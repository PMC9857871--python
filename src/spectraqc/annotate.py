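"""Annotation quality control: cluster-reference label checking and
label suggestion.

Two-step procedure against a labeled reference library:

1. **Check.** Per tissue, the reference spectra are partitioned by K-means
   (k = 2 by default) and each cluster gets a threshold — the mean measure
   value between its center and its members. A target spectrum claiming
   tissue A is *confirmed* iff its measure value to **every** cluster center
   of tissue A is strictly below that center's threshold, else *flagged*.
2. **Suggest.** A flagged spectrum is assigned the tissue of the globally
   nearest cluster center under the measure (ties broken by lexicographic
   tissue order and recorded on the decision).

Clustering runs in Euclidean space on the (preprocessed) spectra — K-means
is Euclidean by definition — while thresholds and decisions use the chosen
spectral measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core import ConfigurationError, SpectralLibrary
from .measures import get_measure, normalize_measure_name

__all__ = [
    "TissueClusters",
    "ClusterModel",
    "compute_thresholds",
    "build_reference_clusters",
    "LabelDecision",
    "check_label",
    "suggest_label",
    "qc_library",
]


@dataclass
class TissueClusters:
    """Cluster centers (bandwise member means) and member indices into the
    reference library, for one tissue."""

    centers: np.ndarray  # (k, L)
    members: list[np.ndarray]  # member row indices per cluster


@dataclass
class ClusterModel:
    measure: str
    k: int
    wavelengths: np.ndarray
    tissues: dict[str, TissueClusters] = field(default_factory=dict)


def build_reference_clusters(
    refs: SpectralLibrary, k: int = 2, name: str = "SID-JM-TAN(SCA)", seed: int = 0
) -> ClusterModel:
    """Per-tissue K-means partition of the reference spectra.

    A tissue with fewer than ``k`` spectra falls back to a single cluster
    (with a warning). Centers are recomputed as bandwise means of the
    members so they are exact regardless of K-means convergence tolerance.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    name = normalize_measure_name(name)
    model = ClusterModel(measure=name, k=k, wavelengths=refs.wavelengths)
    for tissue in sorted({str(t) for t in refs.tissues}):
        idx = np.flatnonzero(np.array([str(t) == tissue for t in refs.tissues]))
        X = refs.reflectance[idx]
        k_t = k
        if idx.size < k:
            warnings.warn(
                f"tissue {tissue!r} has {idx.size} spectra < k={k}; using k=1",
                stacklevel=2,
            )
            k_t = 1
        if k_t == 1 or np.allclose(X, X[0]):
            assignment = np.zeros(idx.size, dtype=int)
            k_t = 1
        else:
            km = KMeans(n_clusters=k_t, n_init=10, random_state=seed)
            assignment = km.fit_predict(X)
        centers = np.vstack([X[assignment == c].mean(axis=0) for c in range(k_t)])
        # stable cluster order: sort by center mean reflectance, then first band
        order = np.lexsort((centers[:, 0], centers.mean(axis=1)))
        centers = centers[order]
        members = [idx[assignment == c] for c in order]
        model.tissues[tissue] = TissueClusters(centers, members)
    return model


def compute_thresholds(
    model: ClusterModel, refs: SpectralLibrary
) -> dict[tuple[str, int], float]:
    """Threshold per (tissue, cluster): mean measure value between the
    cluster center and its member spectra.

    A singleton cluster yields T = 0, which makes confirmation against that
    cluster impossible under the strict rule; warned, consider smaller k.
    """
    f = get_measure(model.measure)
    thresholds: dict[tuple[str, int], float] = {}
    for tissue, tc in model.tissues.items():
        for c, (center, idx) in enumerate(zip(tc.centers, tc.members)):
            if idx.size <= 1:
                t_val = 0.0
                warnings.warn(
                    f"singleton cluster for tissue {tissue!r}: threshold 0 makes "
                    "confirmation impossible; consider smaller k",
                    stacklevel=2,
                )
            else:
                t_val = float(np.mean([f(center, refs.reflectance[i]) for i in idx]))
            thresholds[(tissue, c)] = t_val
    return thresholds


@dataclass
class LabelDecision:
    """Outcome of checking one target spectrum against the cluster model."""

    index: int
    claimed: str
    verdict: str  # "confirmed" | "flagged"
    suggested: str | None = None
    cluster_values: dict[tuple[str, int], float] = field(default_factory=dict)
    min_value: float = float("nan")
    tie: bool = False

    def final_label(self) -> str:
        return self.claimed if self.verdict == "confirmed" else str(self.suggested)


def check_label(
    t,
    claimed: str,
    model: ClusterModel,
    thresholds: dict[tuple[str, int], float],
    index: int = -1,
    rule: str = "all",
) -> LabelDecision:
    """Confirm the claimed tissue iff m(t, r) < T(claimed, r) for ALL
    cluster centers r of the claimed tissue (strict inequality).

    ``rule="any"`` relaxes this to a single center beating its threshold —
    a lenient check for well-separated clusters where the literal rule is
    strict by construction.
    """
    if claimed not in model.tissues:
        raise LookupError(f"claimed tissue {claimed!r} unknown to the cluster model")
    if rule not in ("all", "any"):
        raise ConfigurationError("rule must be 'all' or 'any'")
    f = get_measure(model.measure)
    tc = model.tissues[claimed]
    values = {
        (claimed, c): f(t, center) for c, center in enumerate(tc.centers)
    }
    quantifier = all if rule == "all" else any
    ok = quantifier(v < thresholds[key] for key, v in values.items())
    return LabelDecision(
        index=index,
        claimed=claimed,
        verdict="confirmed" if ok else "flagged",
        cluster_values=values,
    )


def suggest_label(t, model: ClusterModel) -> str:
    """Tissue of the globally nearest cluster center under the measure."""
    label, _, _ = _nearest_tissue(t, model)
    return label


def _nearest_tissue(t, model: ClusterModel) -> tuple[str, float, bool]:
    f = get_measure(model.measure)
    best_label, best_value = None, np.inf
    tie = False
    for tissue in sorted(model.tissues):  # lexicographic tie-break
        for center in model.tissues[tissue].centers:
            v = f(t, center)
            if v < best_value:
                best_label, best_value, tie = tissue, v, False
            elif v == best_value and tissue != best_label:
                tie = True
    return str(best_label), float(best_value), tie


def qc_library(
    targets: SpectralLibrary,
    refs: SpectralLibrary,
    name: str = "SID-JM-TAN(SCA)",
    k: int = 2,
    seed: int = 0,
    rule: str = "all",
) -> list[LabelDecision]:
    """End-to-end QC: build clusters and thresholds from the references,
    check every target's claimed tissue, and suggest a label for flagged
    targets. Fully deterministic for a fixed seed."""
    if targets.wavelengths.shape != refs.wavelengths.shape or not np.allclose(
        targets.wavelengths, refs.wavelengths
    ):
        raise ConfigurationError("targets and references use different wavelength grids")
    model = build_reference_clusters(refs, k=k, name=name, seed=seed)
    thresholds = compute_thresholds(model, refs)
    decisions = []
    for i in range(targets.n_spectra):
        t = targets.reflectance[i]
        claimed = str(targets.tissues[i])
        decision = check_label(t, claimed, model, thresholds, index=i, rule=rule)
        if decision.verdict == "flagged":
            label, value, tie = _nearest_tissue(t, model)
            decision.suggested = label
            decision.min_value = value
            decision.tie = tie
        decisions.append(decision)
    return decisions
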