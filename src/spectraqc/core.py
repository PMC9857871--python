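"""Core containers for labeled hyperspectral spectra.

A *spectrum* is a reflectance vector over a wavelength grid; the clinical
acquisition this package targets records 100 bands between 500 and 995 nm at
5 nm steps. Spectra are plain 1-D :class:`numpy.ndarray`\\ s; the containers
below add the labels (tissue type, patient ID) and validation that the
similarity measures and the patient-wise evaluation protocols rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectraQCError",
    "FormatError",
    "ConfigurationError",
    "DegenerateInputError",
    "LayoutError",
    "DEFAULT_GRID",
    "validate_grid",
    "SpectralLibrary",
    "Hypercube",
]


class SpectraQCError(Exception):
    """Base class for all domain errors raised by this package."""


class FormatError(SpectraQCError, ValueError):
    """A file does not conform to the spectral-library or cube dialect."""


class ConfigurationError(SpectraQCError, ValueError):
    """Invalid parameter combination (window sizes, fold counts, grids...)."""


class DegenerateInputError(SpectraQCError, ValueError):
    """Input is degenerate for the requested operation (constant spectrum,
    zero norm, all-zero measure vector...)."""


class LayoutError(SpectraQCError, ValueError):
    """Synthetic cube regions overlap or fall outside the image."""


#: 500–995 nm at 5 nm resolution — the 100-band grid of the push-broom
#: clinical camera the synthetic data emulates.
DEFAULT_GRID: np.ndarray = np.arange(500.0, 1000.0, 5.0)


def validate_grid(wavelengths) -> np.ndarray:
    """Validate a wavelength grid: finite, strictly increasing, length >= 2."""
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise FormatError("wavelength grid must be a 1-D array of length >= 2")
    if not np.all(np.isfinite(w)):
        raise FormatError("wavelength grid contains non-finite values")
    if not np.all(np.diff(w) > 0):
        raise FormatError("wavelength grid must be strictly increasing")
    return w


@dataclass
class SpectralLibrary:
    """A set of K labeled spectral signatures sharing one wavelength grid.

    Parameters
    ----------
    wavelengths
        Shape ``(L,)``, strictly increasing, in nm.
    reflectance
        Shape ``(K, L)``, one spectrum per row, all values finite.
    tissues, patients
        Length-K label arrays; every entry non-empty. Patient IDs are
        mandatory because every evaluation protocol splits by patient.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    tissues: np.ndarray
    patients: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = validate_grid(self.wavelengths)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.tissues = np.asarray(self.tissues, dtype=object)
        self.patients = np.asarray(self.patients, dtype=object)
        K, L = self.reflectance.shape
        if K < 1:
            raise FormatError("a spectral library must contain at least one spectrum")
        if L != self.wavelengths.size:
            raise FormatError(
                f"reflectance has {L} bands but the grid has {self.wavelengths.size}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise FormatError("reflectance contains non-finite values")
        if self.tissues.shape != (K,) or self.patients.shape != (K,):
            raise FormatError("tissue/patient labels must have one entry per spectrum")
        for arr, what in ((self.tissues, "tissue"), (self.patients, "patient")):
            if any(not str(x) for x in arr):
                raise FormatError(f"empty {what} label")

    @property
    def n_spectra(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def subset(self, mask) -> "SpectralLibrary":
        """Library restricted to the boolean/index mask (K >= 1 enforced)."""
        mask = np.asarray(mask)
        return SpectralLibrary(
            self.wavelengths,
            self.reflectance[mask],
            self.tissues[mask],
            self.patients[mask],
        )

    def keys(self) -> list[tuple[str, str]]:
        """(tissue, patient) pair per entry, in storage order."""
        return [(str(t), str(p)) for t, p in zip(self.tissues, self.patients)]


@dataclass
class Hypercube:
    """A small annotated reflectance cube ``(x, y, band)`` with an integer
    label mask (0 = unlabeled) and an ``id -> tissue name`` map."""

    data: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = validate_grid(self.wavelengths)
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise FormatError("cube data must be a 3-D (x, y, band) array")
        if self.data.shape[2] != self.wavelengths.size:
            raise FormatError("cube band dimension does not match the grid")
        if self.labels.shape != self.data.shape[:2]:
            raise FormatError("label mask shape must match the cube (x, y) shape")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("cube contains non-finite reflectance")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise FormatError(f"mask ids without a tissue name: {sorted(missing)}")
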