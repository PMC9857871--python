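"""Spectral preprocessing: Savitzky–Golay smoothing, SNV, Min-Max rescale.

The chain runs in the fixed order SG → SNV → Min-Max. SG removes
high-frequency noise by local polynomial fits; SNV centres each spectrum to
mean 0 / sd 1, removing per-spectrum affine (illumination) effects; the
Min-Max step then maps each spectrum to ``[epsilon, 1]`` so that the
divergence-based measures never see zero or negative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core import ConfigurationError, DegenerateInputError, SpectralLibrary

__all__ = [
    "PreprocessConfig",
    "savgol_smooth",
    "snv_normalize",
    "minmax_rescale",
    "to_probability",
    "preprocess_spectrum",
    "preprocess_library",
]

_STEPS = ("sg", "snv", "minmax")


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    sg_window : odd window length in bands (default 9 = 45 nm at 5 nm
    resolution — wide enough to smooth sensor noise, narrow enough to keep
    the 540–580 nm hemoglobin features). sg_order : polynomial order
    (default 3). minmax_epsilon : lower bound of the rescaled range; kept
    strictly positive so log terms stay finite. enabled_steps : ordered
    subset of ``("sg", "snv", "minmax")``.
    """

    sg_window: int = 9
    sg_order: int = 3
    minmax_epsilon: float = 1e-6
    enabled_steps: tuple[str, ...] = field(default=_STEPS)

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window < 5:
            raise ConfigurationError("sg_window must be an odd integer >= 5")
        if not 0 <= self.sg_order < self.sg_window:
            raise ConfigurationError("sg_order must satisfy 0 <= order < window")
        if not self.minmax_epsilon > 0:
            raise ConfigurationError("minmax_epsilon must be positive")
        self.enabled_steps = tuple(self.enabled_steps)
        unknown = set(self.enabled_steps) - set(_STEPS)
        if unknown:
            raise ConfigurationError(f"unknown preprocessing steps: {sorted(unknown)}")


def savgol_smooth(s: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Savitzky–Golay smoothing; edges use the polynomial fitted to the
    last full window (no reflectance is fabricated outside the grid)."""
    cfg = cfg or PreprocessConfig()
    s = np.asarray(s, dtype=float)
    if s.size < cfg.sg_window:
        raise ConfigurationError(
            f"spectrum has {s.size} bands, fewer than sg_window={cfg.sg_window}"
        )
    return savgol_filter(s, cfg.sg_window, cfg.sg_order, mode="interp")


def snv_normalize(s: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum mean 0, sample sd 1 (ddof=1)."""
    s = np.asarray(s, dtype=float)
    if s.max() == s.min():  # exact range check; a float sd of a constant
        raise DegenerateInputError("SNV undefined for a constant spectrum")
    return (s - s.mean()) / s.std(ddof=1)


def minmax_rescale(s: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Affine map of [min, max] onto [epsilon, 1]; strictly positive output."""
    if not epsilon > 0:
        raise ConfigurationError("epsilon must be positive")
    s = np.asarray(s, dtype=float)
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise DegenerateInputError("Min-Max undefined for a constant spectrum")
    return epsilon + (1.0 - epsilon) * (s - lo) / (hi - lo)


def to_probability(s: np.ndarray) -> np.ndarray:
    """Normalize a nonnegative spectrum to a probability distribution."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise DegenerateInputError(
            "negative reflectance; apply minmax_rescale before probability "
            "normalization"
        )
    total = s.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero spectrum has no probability distribution")
    return s / total


def preprocess_spectrum(s: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    cfg = cfg or PreprocessConfig()
    out = np.asarray(s, dtype=float)
    for step in cfg.enabled_steps:
        if step == "sg":
            out = savgol_smooth(out, cfg)
        elif step == "snv":
            out = snv_normalize(out)
        elif step == "minmax":
            out = minmax_rescale(out, cfg.minmax_epsilon)
    return out


def preprocess_library(
    lib: SpectralLibrary, cfg: PreprocessConfig | None = None
) -> SpectralLibrary:
    """Apply the enabled steps to every spectrum; labels untouched.

    Errors from individual spectra are re-raised annotated with the entry's
    index, tissue and patient so the offending annotation can be found.
    """
    cfg = cfg or PreprocessConfig()
    out = np.empty_like(lib.reflectance)
    for i in range(lib.n_spectra):
        try:
            out[i] = preprocess_spectrum(lib.reflectance[i], cfg)
        except (ConfigurationError, DegenerateInputError) as exc:
            raise type(exc)(
                f"entry {i} (tissue={lib.tissues[i]!r}, patient={lib.patients[i]!r}): {exc}"
            ) from exc
    return SpectralLibrary(lib.wavelengths, out, lib.tissues.copy(), lib.patients.copy())
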