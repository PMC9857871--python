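"""The eight spectral similarity measures and their registry.

Classical measures
------------------
* SAM — spectral angle mapper, the angle ``arccos(<s_i, s_j> / (|s_i||s_j|))``
  between two spectra seen as vectors; radians in [0, pi/2]; invariant to
  positive scaling of either spectrum.
* SID — spectral information divergence, the symmetrized Kullback–Leibler
  divergence of the probability-normalized spectra, in nats.
* SCA — spectral correlation angle, ``arccos((sigma + 1) / 2)`` with sigma
  the Pearson correlation coefficient; unlike SAM it separates positive from
  negative correlation and is invariant to positive affine transforms.
* JM — Jeffries–Matusita distance, ``2 (1 - e^{-B})`` with B the
  Bhattacharyya distance ``-ln BC``; equivalently ``2 (1 - BC)``, in [0, 2].

Hybrid measures multiply a stochastic factor (SID, JM) with the tangent of a
deterministic angle (SAM, SCA); the product amplifies the contrast between
similar pairs (every factor small) and dissimilar pairs (every factor large):

* SID-TAN(SAM) = SID * tan(SAM) and SID-TAN(SCA) = SID * tan(SCA)
* SID-JM-TAN(SAM) = SID * JM * tan(SAM) and SID-JM-TAN(SCA) = SID * JM * tan(SCA)

All eight are nonnegative, symmetric, zero on identical inputs, and smaller
means more similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, DegenerateInputError, SpectralLibrary
from .preprocess import to_probability

__all__ = [
    "MEASURE_NAMES",
    "get_measure",
    "normalize_measure_name",
    "sam",
    "sid",
    "sca",
    "bhattacharyya_coefficient",
    "jm",
    "sid_tan_sam",
    "sid_tan_sca",
    "sid_jm_tan_sam",
    "sid_jm_tan_sca",
    "patient_mean_spectra",
    "SimilarityMatrix",
    "pairwise_matrix",
]

# KL zero-handling: probabilities floored here, then renormalized, so SID is
# total even on raw inputs with empty bands.
_PROB_FLOOR = 1e-12
# tan saturates just below pi/2 so hybrids stay finite for exactly
# orthogonal / anticorrelated spectra while preserving order.
_ANGLE_CAP = np.pi / 2 - 1e-9


def _pair(s_i, s_j) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(s_i, dtype=float)
    b = np.asarray(s_j, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("spectra must be 1-D and share one wavelength grid")
    return a, b


def sam(s_i, s_j) -> float:
    """Spectral angle mapper, radians in [0, pi/2] (nonnegative inputs)."""
    a, b = _pair(s_i, s_j)
    if np.any(a < 0) or np.any(b < 0):
        raise DegenerateInputError("SAM requires nonnegative spectra")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateInputError("SAM undefined for a zero spectrum")
    # 2 arcsin(|a^ - b^| / 2) — numerically exact near 0, so identical
    # spectra give exactly 0 (arccos of a rounded cosine would not)
    chord = np.linalg.norm(a / na - b / nb)
    return float(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))


def _floored_probability(s) -> np.ndarray:
    p = np.maximum(to_probability(s), _PROB_FLOOR)
    return p / p.sum()


def sid(s_i, s_j) -> float:
    """Spectral information divergence, KL(p||q) + KL(q||p), in nats."""
    a, b = _pair(s_i, s_j)
    p = _floored_probability(a)
    q = _floored_probability(b)
    log_ratio = np.log(p) - np.log(q)
    return float((p - q) @ log_ratio)


def _one_minus_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """1 - sigma computed stably (exactly 0 for identical inputs)."""
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        raise DegenerateInputError("correlation undefined for a constant spectrum")
    num = float(ac @ bc)
    return float(np.clip((denom - num) / denom, 0.0, 2.0))


def sca(s_i, s_j, *, sqrt_variant: bool = False) -> float:
    """Spectral correlation angle, arccos((sigma+1)/2), radians in [0, pi/2].

    ``sqrt_variant`` applies arccos(sqrt((sigma+1)/2)), a form also found in
    the SCA literature; the plain form is the default.
    """
    a, b = _pair(s_i, s_j)
    om = _one_minus_pearson(a, b)  # 1 - sigma in [0, 2]
    if sqrt_variant:
        return float(np.arccos(np.clip(np.sqrt((2.0 - om) / 2.0), 0.0, 1.0)))
    # arccos((sigma+1)/2) = 2 arcsin(sqrt((1-sigma)/4)), exact near 0
    return float(2.0 * np.arcsin(np.clip(np.sqrt(om) / 2.0, 0.0, 1.0)))


def bhattacharyya_coefficient(s_i, s_j) -> float:
    """Overlap sum ``sum sqrt(p_l q_l)`` of the normalized spectra, in [0, 1]."""
    a, b = _pair(s_i, s_j)
    bc = float(np.sqrt(to_probability(a) * to_probability(b)).sum())
    return min(bc, 1.0)


def jm(s_i, s_j, *, literal_exponent: bool = False) -> float:
    """Jeffries–Matusita distance in [0, 2].

    Default uses the Bhattacharyya *distance* B = -ln(BC) in the exponent,
    so JM = 2 (1 - e^{-B}) = 2 (1 - BC), which attains the full [0, 2] range
    (2 exactly on disjoint support). ``literal_exponent`` instead puts the
    *coefficient* in the exponent, JM = 2 (1 - e^{-BC}), capped at
    2 (1 - 1/e).
    """
    bc = bhattacharyya_coefficient(s_i, s_j)
    if literal_exponent:
        return float(2.0 * (1.0 - np.exp(-bc)))
    return float(2.0 * (1.0 - bc))


def _tan(angle: float) -> float:
    return float(np.tan(min(angle, _ANGLE_CAP)))


def sid_tan_sam(s_i, s_j) -> float:
    """SID * tan(SAM)."""
    return sid(s_i, s_j) * _tan(sam(s_i, s_j))


def sid_tan_sca(s_i, s_j) -> float:
    """SID * tan(SCA)."""
    return sid(s_i, s_j) * _tan(sca(s_i, s_j))


def sid_jm_tan_sam(s_i, s_j) -> float:
    """SID * JM * tan(SAM) — hybrid of two stochastic and one angle factor."""
    return sid(s_i, s_j) * jm(s_i, s_j) * _tan(sam(s_i, s_j))


def sid_jm_tan_sca(s_i, s_j) -> float:
    """SID * JM * tan(SCA) — hybrid of two stochastic and one angle factor."""
    return sid(s_i, s_j) * jm(s_i, s_j) * _tan(sca(s_i, s_j))


_REGISTRY = {
    "SAM": sam,
    "SID": sid,
    "SCA": sca,
    "JM": jm,
    "SID-TAN(SAM)": sid_tan_sam,
    "SID-TAN(SCA)": sid_tan_sca,
    "SID-JM-TAN(SAM)": sid_jm_tan_sam,
    "SID-JM-TAN(SCA)": sid_jm_tan_sca,
}

#: Closed enumeration of measure names, registry lookup is total over it.
MEASURE_NAMES: tuple[str, ...] = tuple(_REGISTRY)

_ALIASES = {name.replace("(", "-").replace(")", "").upper(): name for name in _REGISTRY}


def normalize_measure_name(name: str) -> str:
    """Canonical measure name from either form (``SID-JM-TAN(SCA)`` or the
    shell-friendly alias ``sid-jm-tan-sca``)."""
    key = name.strip().replace("(", "-").replace(")", "").upper()
    try:
        return _ALIASES[key]
    except KeyError:
        raise ConfigurationError(
            f"unknown measure {name!r}; valid names: {', '.join(MEASURE_NAMES)}"
        )


def get_measure(name: str):
    """Measure function for a (possibly aliased) measure name."""
    return _REGISTRY[normalize_measure_name(name)]


def patient_mean_spectra(lib: SpectralLibrary) -> SpectralLibrary:
    """One bandwise-mean spectrum per (tissue, patient) group.

    The evaluation protocols compare mean spectra of a given tissue for each
    patient rather than individual pixels.
    """
    keys: list[tuple[str, str]] = []
    means: list[np.ndarray] = []
    seen: dict[tuple[str, str], int] = {}
    for i, key in enumerate(lib.keys()):
        if key not in seen:
            seen[key] = len(keys)
            keys.append(key)
            means.append(np.zeros(lib.n_bands))
    counts = np.zeros(len(keys))
    for i, key in enumerate(lib.keys()):
        j = seen[key]
        means[j] += lib.reflectance[i]
        counts[j] += 1
    reflectance = np.vstack(means) / counts[:, None]
    tissues = [t for t, _ in keys]
    patients = [p for _, p in keys]
    return SpectralLibrary(lib.wavelengths, reflectance, tissues, patients)


@dataclass
class SimilarityMatrix:
    """Measure values between every target (row) and reference (column)."""

    row_keys: list[tuple[str, str]]
    col_keys: list[tuple[str, str]]
    values: np.ndarray
    measure: str

    def to_dataframe(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.row_keys, names=["tissue", "patient"])
        cols = pd.MultiIndex.from_tuples(self.col_keys, names=["tissue", "patient"])
        return pd.DataFrame(self.values, index=idx, columns=cols)


def pairwise_matrix(
    targets: SpectralLibrary, references: SpectralLibrary, name: str
) -> SimilarityMatrix:
    """|targets| x |references| matrix of measure values."""
    if targets.wavelengths.shape != references.wavelengths.shape or not np.allclose(
        targets.wavelengths, references.wavelengths
    ):
        raise ConfigurationError("targets and references use different wavelength grids")
    name = normalize_measure_name(name)
    f = _REGISTRY[name]
    values = np.empty((targets.n_spectra, references.n_spectra))
    for i in range(targets.n_spectra):
        for j in range(references.n_spectra):
            values[i, j] = f(targets.reflectance[i], references.reflectance[j])
    return SimilarityMatrix(targets.keys(), references.keys(), values, name)
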