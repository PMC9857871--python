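"""Read/write labeled spectral libraries and small annotated hypercubes.

Library dialect (canonical, CSV): first row
``tissue,patient,w500,w505,...,w995`` — one spectrum per data row, UTF-8,
'.' decimal separator. A TSV variant uses tabs. Cubes travel in a compressed
numpy archive with keys ``data``, ``labels``, ``wavelengths``,
``label_ids``, ``label_names``.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np

from .core import (
    DegenerateInputError,
    FormatError,
    Hypercube,
    SpectralLibrary,
)

__all__ = ["read_library", "write_library", "read_cube", "write_cube", "extract_labeled"]

_DELIMS = {"csv": ",", "tsv": "\t"}


def _delimiter(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {sorted(_DELIMS)}")


def read_library(path, dialect: str = "csv") -> SpectralLibrary:
    """Parse a labeled spectral library from a CSV/TSV file.

    The header declares the wavelength grid (``w<nm>`` columns); every data
    row must carry exactly one reflectance value per band.
    """
    delim = _delimiter(dialect)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 4 or header[0] != "tissue" or header[1] != "patient":
        raise FormatError(f"{path}: header must start with 'tissue,patient' then band columns")
    try:
        wavelengths = [float(c[1:]) for c in header[2:] if c.startswith("w")]
        if len(wavelengths) != len(header) - 2:
            raise ValueError
    except ValueError:
        raise FormatError(f"{path}: band columns must be named w<wavelength-nm>")
    L = len(wavelengths)
    tissues, patients, spectra = [], [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != L + 2:
            raise FormatError(
                f"{path}:{lineno}: expected {L + 2} fields, found {len(row)}"
            )
        tissues.append(row[0])
        patients.append(row[1])
        try:
            spectra.append([float(v) for v in row[2:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric reflectance ({exc})")
    if not spectra:
        raise FormatError(f"{path}: no data rows")
    return SpectralLibrary(np.asarray(wavelengths), np.asarray(spectra), tissues, patients)


def _format_wavelength(w: float) -> str:
    return f"{w:g}"


def write_library(lib: SpectralLibrary, path, dialect: str = "csv") -> None:
    """Write a library in the canonical dialect; ``read_library`` round-trips it."""
    delim = _delimiter(dialect)
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter=delim, lineterminator="\n")
    writer.writerow(
        ["tissue", "patient"] + [f"w{_format_wavelength(w)}" for w in lib.wavelengths]
    )
    for i in range(lib.n_spectra):
        writer.writerow(
            [str(lib.tissues[i]), str(lib.patients[i])]
            + [repr(float(v)) for v in lib.reflectance[i]]
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_cube(cube: Hypercube, path) -> None:
    ids = sorted(cube.label_names)
    np.savez_compressed(
        path,
        data=cube.data,
        labels=cube.labels,
        wavelengths=cube.wavelengths,
        label_ids=np.asarray(ids, dtype=int),
        label_names=np.asarray([cube.label_names[i] for i in ids], dtype=object),
    )


def read_cube(path) -> Hypercube:
    with np.load(path, allow_pickle=True) as npz:
        try:
            names = {
                int(i): str(n)
                for i, n in zip(npz["label_ids"], npz["label_names"])
            }
            return Hypercube(npz["data"], npz["wavelengths"], npz["labels"], names)
        except KeyError as exc:
            raise FormatError(f"{path}: missing cube archive key {exc}")


def extract_labeled(cube: Hypercube, patient: str = "cube0") -> SpectralLibrary:
    """One labeled spectrum per nonzero mask pixel, row-major pixel order.

    Cubes carry no patient metadata, so a single patient ID is stamped on
    every extracted spectrum (``patient``).
    """
    xs, ys = np.nonzero(cube.labels)
    if xs.size == 0:
        raise DegenerateInputError("mask labels no pixels; nothing to extract")
    spectra = cube.data[xs, ys, :]
    tissues = [cube.label_names[int(cube.labels[x, y])] for x, y in zip(xs, ys)]
    return SpectralLibrary(
        cube.wavelengths, spectra, tissues, [patient] * xs.size
    )
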