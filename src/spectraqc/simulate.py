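"""Synthetic spectral libraries and cubes with clinical-like structure.

Generates labeled reflectance spectra over the 100-band 500–995 nm grid
with the three variance layers the similarity measures and the QC procedure
assume in real intraoperative data:

* a per-tissue characteristic baseline — a smooth sum of Gaussian bumps,
  loosely shaped on visible hemoglobin absorption (dips near 540–580 nm)
  and the NIR reflectance plateau;
* per-(patient, tissue) multiplicative scale and additive shift, emulating
  illumination and acquisition-geometry differences between captures;
* per-spectrum bandwise Gaussian noise.

Optionally a fraction of entries is mislabeled (labels swapped uniformly to
another tissue) with the ground truth recorded separately — the null model
for annotation-QC testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConfigurationError,
    DEFAULT_GRID,
    Hypercube,
    LayoutError,
    SpectralLibrary,
)

__all__ = [
    "TissueSpectralModel",
    "SimulationConfig",
    "default_tissue_suite",
    "sample_library",
    "sample_cube",
]


@dataclass
class TissueSpectralModel:
    """Characteristic curve and variability of one tissue class.

    ``bumps`` is a list of ``(center_nm, width_nm, amplitude)`` Gaussians
    added to a flat ``offset``; the resulting baseline must stay positive
    on the grid. Standard deviations: ``patient_scale_sd`` of the
    multiplicative patient factor (around 1), ``patient_shift_sd`` of the
    additive patient offset, ``noise_sd`` of the bandwise pixel noise, all
    in reflectance units.
    """

    tissue: str
    offset: float
    bumps: list[tuple[float, float, float]] = field(default_factory=list)
    patient_scale_sd: float = 0.08
    patient_shift_sd: float = 0.02
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if min(self.patient_scale_sd, self.patient_shift_sd, self.noise_sd) < 0:
            raise ConfigurationError("standard deviations must be >= 0")

    def baseline(self, wavelengths=DEFAULT_GRID) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=float)
        out = np.full_like(w, self.offset)
        for center, width, amp in self.bumps:
            out += amp * np.exp(-0.5 * ((w - center) / width) ** 2)
        if np.any(out <= 0):
            raise ConfigurationError(
                f"baseline of tissue {self.tissue!r} is not positive on the grid"
            )
        return out


def default_tissue_suite() -> list[TissueSpectralModel]:
    """Eleven deterministic tissue/material models over 500–995 nm.

    Separability ordering by construction: thyroid/parathyroid and
    colon/small-intestine/stomach are near-neighbours (shared hemoglobin
    dips, slightly shifted NIR plateaus); fat, gauze and instrument are far
    from every tissue (no hemoglobin signature, very different albedo).
    """

    def m(tissue, offset, bumps):
        return TissueSpectralModel(tissue=tissue, offset=offset, bumps=bumps)

    return [
        m("thyroid", 0.30, [(545, 15, -0.12), (575, 12, -0.10), (760, 40, 0.18), (900, 60, 0.22)]),
        m("parathyroid", 0.32, [(545, 15, -0.11), (575, 12, -0.09), (765, 42, 0.19), (905, 60, 0.21)]),
        m("muscle", 0.22, [(545, 15, -0.09), (575, 12, -0.08), (720, 50, 0.10), (880, 70, 0.12)]),
        m("nerve", 0.35, [(550, 18, -0.08), (760, 45, 0.25), (920, 55, 0.15)]),
        m("skin", 0.28, [(545, 14, -0.10), (575, 12, -0.08), (650, 60, 0.15), (850, 80, 0.25)]),
        m("colon", 0.26, [(545, 15, -0.10), (575, 12, -0.09), (740, 45, 0.14), (890, 65, 0.16)]),
        m("small_intestine", 0.27, [(545, 15, -0.10), (575, 12, -0.085), (745, 45, 0.15), (895, 65, 0.17)]),
        m("stomach", 0.25, [(548, 15, -0.095), (578, 12, -0.085), (735, 48, 0.13), (885, 65, 0.15)]),
        m("fat", 0.45, [(760, 80, 0.20), (930, 40, -0.10)]),
        m("gauze", 0.85, [(700, 300, 0.05)]),
        m("instrument", 0.12, [(995, 400, 0.06)]),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic library draw.

    Defaults mirror the QC experiments: 10 patients and 5 spectra per
    tissue per patient, no mislabeling unless requested.
    """

    models: list[TissueSpectralModel] = field(default_factory=default_tissue_suite)
    n_patients: int = 10
    spectra_per_tissue_per_patient: int = 5
    seed: int = 0
    mislabel_fraction: float = 0.0
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def __post_init__(self) -> None:
        if not self.models:
            raise ConfigurationError("at least one tissue model is required")
        if self.n_patients < 1 or self.spectra_per_tissue_per_patient < 1:
            raise ConfigurationError("n_patients and spectra per group must be >= 1")
        if not 0 <= self.mislabel_fraction < 1:
            raise ConfigurationError("mislabel_fraction must be in [0, 1)")
        names = [m.tissue for m in self.models]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate tissue names in the model suite")


_REFLECTANCE_FLOOR = 1e-6


def sample_library(cfg: SimulationConfig) -> tuple[SpectralLibrary, np.ndarray]:
    """Draw a labeled library; returns ``(library, true_labels)``.

    Each spectrum is ``scale_pt * baseline + shift_pt + noise`` clipped to a
    small positive floor, with one (scale, shift) draw per (patient, tissue)
    capture. ``mislabel_fraction`` of entries carry a wrong tissue label in
    the library while ``true_labels`` records the truth. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    w = cfg.wavelengths
    width = len(str(cfg.n_patients))
    spectra, tissues, patients = [], [], []
    for model in cfg.models:
        base = model.baseline(w)
        for p in range(cfg.n_patients):
            scale = max(1.0 + rng.normal(0.0, model.patient_scale_sd), 0.1)
            shift = rng.normal(0.0, model.patient_shift_sd)
            for _ in range(cfg.spectra_per_tissue_per_patient):
                s = scale * base + shift + rng.normal(0.0, model.noise_sd, w.size)
                spectra.append(np.maximum(s, _REFLECTANCE_FLOOR))
                tissues.append(model.tissue)
                patients.append(f"p{p + 1:0{width}d}")
    tissues = np.asarray(tissues, dtype=object)
    truth = tissues.copy()
    K = len(spectra)
    if cfg.mislabel_fraction > 0 and len(cfg.models) > 1:
        n_wrong = int(round(cfg.mislabel_fraction * K))
        wrong_idx = rng.choice(K, size=n_wrong, replace=False)
        names = [m.tissue for m in cfg.models]
        for i in wrong_idx:
            others = [n for n in names if n != truth[i]]
            tissues[i] = others[rng.integers(len(others))]
    lib = SpectralLibrary(w, np.vstack(spectra), tissues, patients)
    return lib, truth


def sample_cube(
    cfg: SimulationConfig,
    width: int,
    height: int,
    region_layout: list[tuple[int, int, int, int, str]],
) -> Hypercube:
    """Fill rectangular regions ``(x0, y0, dx, dy, tissue)`` of a
    ``width x height`` cube with draws from the tissue models; the mask
    matches the layout exactly (region order = mask id 1..n). One patient
    effect per region, per-pixel noise. Unlabeled pixels hold a dim flat
    background."""
    rng = np.random.default_rng(cfg.seed)
    w = cfg.wavelengths
    models = {m.tissue: m for m in cfg.models}
    data = np.full((width, height, w.size), 0.05)
    labels = np.zeros((width, height), dtype=int)
    label_names: dict[int, str] = {}
    for rid, (x0, y0, dx, dy, tissue) in enumerate(region_layout, start=1):
        if tissue not in models:
            raise LayoutError(f"no tissue model named {tissue!r}")
        if x0 < 0 or y0 < 0 or x0 + dx > width or y0 + dy > height or dx < 1 or dy < 1:
            raise LayoutError(f"region {rid} does not fit in the {width}x{height} image")
        if np.any(labels[x0 : x0 + dx, y0 : y0 + dy] != 0):
            raise LayoutError(f"region {rid} overlaps a previous region")
        model = models[tissue]
        base = model.baseline(w)
        scale = max(1.0 + rng.normal(0.0, model.patient_scale_sd), 0.1)
        shift = rng.normal(0.0, model.patient_shift_sd)
        block = scale * base + shift + rng.normal(
            0.0, model.noise_sd, (dx, dy, w.size)
        )
        data[x0 : x0 + dx, y0 : y0 + dy, :] = np.maximum(block, _REFLECTANCE_FLOOR)
        labels[x0 : x0 + dx, y0 : y0 + dy] = rid
        label_names[rid] = tissue
    return Hypercube(data, w, labels, label_names)
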