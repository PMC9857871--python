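"""Comparative discrimination statistics: RSDPW, RSDPB, RSDE.

The eight measures return values in different units (radians, nats,
dimensionless products), so their raw magnitudes cannot be compared across
measures. These relative statistics normalize the unit away:

* RSDPW(s_i, s_j; t) = max{ m(s_i,t)/m(s_j,t), m(s_j,t)/m(s_i,t) } >= 1 —
  how differently two references sit relative to a common target; larger
  means better discriminatory power.
* RSDPB — the target's measure values against a K-reference library
  normalized to a probability vector, entry k proportional to m(t, s_k).
* RSDE — the Shannon entropy of that vector in bits; smaller means the
  target is matched by few references, i.e. sharper identification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .core import DegenerateInputError, SpectralLibrary
from .measures import get_measure, normalize_measure_name, patient_mean_spectra

__all__ = ["rsdpw", "rsdpb", "rsde", "DiscriminationReport", "discrimination_report"]


def rsdpw(name: str, s_i, s_j, t) -> float:
    """Relative spectral discriminatory power of measure ``name`` for
    references ``s_i``, ``s_j`` against target ``t``; symmetric, >= 1."""
    f = get_measure(name)
    m_i, m_j = f(s_i, t), f(s_j, t)
    if m_i == 0 or m_j == 0:
        raise DegenerateInputError(
            "RSDPW undefined: a reference is identical to the target under this measure"
        )
    return max(m_i / m_j, m_j / m_i)


def rsdpb(name: str, t, refs: SpectralLibrary) -> np.ndarray:
    """Relative spectral discriminatory probability vector over the K
    references: entry k is m(t, s_k) / sum_i m(t, s_i)."""
    f = get_measure(name)
    values = np.array([f(t, refs.reflectance[k]) for k in range(refs.n_spectra)])
    total = values.sum()
    if total <= 0:
        raise DegenerateInputError(
            "RSDPB undefined: target is identical to every reference under this measure"
        )
    return values / total


def rsde(name: str, t, refs: SpectralLibrary) -> float:
    """Relative spectral discriminatory entropy in bits: Shannon entropy
    (base 2, 0 log 0 = 0) of the RSDPB vector; in [0, log2 K]."""
    return float(_shannon_entropy(rsdpb(name, t, refs), base=2))


@dataclass
class DiscriminationReport:
    """RSDPW/RSDPB/RSDE of one measure for one target tissue."""

    measure: str
    target_tissue: str
    rsdpw: dict[tuple[str, str], float]
    rsdpb_keys: list[tuple[str, str]] = field(default_factory=list)
    rsdpb: np.ndarray = field(default_factory=lambda: np.empty(0))
    rsde: float = 0.0

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "target_tissue": self.target_tissue,
            "rsdpw": {f"{a}|{b}": v for (a, b), v in self.rsdpw.items()},
            "rsdpb": {
                f"{t}|{p}": float(v) for (t, p), v in zip(self.rsdpb_keys, self.rsdpb)
            },
            "rsde": self.rsde,
        }


def _tissue_means(lib: SpectralLibrary) -> dict[str, np.ndarray]:
    means = patient_mean_spectra(lib)
    out: dict[str, np.ndarray] = {}
    for tissue in sorted({str(t) for t in means.tissues}):
        mask = np.array([str(t) == tissue for t in means.tissues])
        out[tissue] = means.reflectance[mask].mean(axis=0)
    return out


def discrimination_report(
    lib: SpectralLibrary, target_tissue: str, measures: list[str]
) -> list[DiscriminationReport]:
    """Per measure: RSDPW over all unordered pairs of non-target tissues
    (tissue mean spectra vs the target tissue mean), plus RSDPB/RSDE of the
    target mean against the per-patient mean references."""
    tissues_present = {str(t) for t in lib.tissues}
    if target_tissue not in tissues_present:
        raise LookupError(f"tissue {target_tissue!r} not present in the library")
    tissue_means = _tissue_means(lib)
    target = tissue_means[target_tissue]
    others = sorted(t for t in tissue_means if t != target_tissue)
    refs = patient_mean_spectra(lib)
    reports = []
    for name in measures:
        name = normalize_measure_name(name)
        pw = {
            (a, b): rsdpw(name, tissue_means[a], tissue_means[b], target)
            for a, b in itertools.combinations(others, 2)
        }
        pb = rsdpb(name, target, refs)
        reports.append(
            DiscriminationReport(
                measure=name,
                target_tissue=target_tissue,
                rsdpw=pw,
                rsdpb_keys=refs.keys(),
                rsdpb=pb,
                rsde=float(_shannon_entropy(pb, base=2)),
            )
        )
    return reports
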