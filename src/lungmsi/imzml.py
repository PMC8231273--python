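"""Centroided MSI datasets and imzML I/O.

A mass-spectrometry-imaging (MSI) acquisition rasters a tissue section on a
regular grid and records one centroid spectrum (peak list) per pixel.  This
module defines the in-memory containers (:class:`CentroidSpectrum`,
:class:`MSIDataset`) and reads/writes the open imzML format in its
"processed" dialect, where every pixel stores its own m/z array — the natural
layout for centroided data.  Continuous (profile) files are rejected rather
than silently converted.

Pixel coordinates are 1-based in imzML files, as the standard requires, and
0-based ``(x, y)`` in memory; the conversion happens only at the I/O
boundary.  m/z values are stored as 64-bit floats (extraction windows of
0.005 Da need the precision) and intensities as 32-bit floats.

imzML has no standard slot for pixel pitch, declared m/z range, or
section/group labels; those travel in the cohort manifest and may be passed
to :func:`read_msi` as overrides.
"""

from __future__ import annotations

import hashlib
import math
import re
import uuid
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter, _Spectrum

__all__ = [
    "CentroidSpectrum",
    "MSIDataset",
    "MSIValidationError",
    "MSIParseError",
    "UnsupportedModeError",
    "read_msi",
    "write_msi",
    "monoisotopic_mass",
]

#: rest mass of the electron, Da (CODATA)
ELECTRON_MASS_DA = 0.000548579909065


class MSIValidationError(ValueError):
    """A dataset or spectrum violates its invariants."""


class MSIParseError(ValueError):
    """An imzML file pair could not be interpreted."""


class UnsupportedModeError(MSIParseError):
    """The file is not a processed-mode (per-pixel m/z) centroid acquisition."""


@dataclass
class CentroidSpectrum:
    """A centroided peak list: strictly ascending m/z, non-negative intensity."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)

    def validate(self) -> None:
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise MSIValidationError("peak arrays must be one-dimensional")
        if self.mz.shape[0] != self.intensity.shape[0]:
            raise MSIValidationError(
                f"m/z and intensity lengths differ ({self.mz.shape[0]} vs "
                f"{self.intensity.shape[0]})"
            )
        if self.mz.size and not np.all(np.diff(self.mz) > 0):
            raise MSIValidationError("m/z values must be strictly ascending")
        if np.any(self.intensity < 0) or not np.all(np.isfinite(self.intensity)):
            raise MSIValidationError("intensities must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class MSIDataset:
    """Pixel-indexed centroid spectra on a regular grid.

    Parameters
    ----------
    pixels
        Mapping from 0-based integer grid coordinate ``(x, y)`` (x = column,
        y = row) to a :class:`CentroidSpectrum`.
    pixel_pitch_um
        Center-to-center pixel spacing in micrometres (the study raster is
        400 µm).
    mz_range
        Declared acquisition window ``(low, high)`` in Da.
    """

    pixels: dict[tuple[int, int], CentroidSpectrum]
    pixel_pitch_um: float = 400.0
    mz_range: tuple[float, float] = (185.0, 650.0)
    polarity: str = "positive"
    section_id: str = ""
    group_label: str = ""
    grid_shape: tuple[int, int] | None = None  # (rows, cols); bounding box if None

    def __post_init__(self) -> None:
        if self.grid_shape is None and self.pixels:
            xs = [c[0] for c in self.pixels]
            ys = [c[1] for c in self.pixels]
            self.grid_shape = (max(ys) + 1, max(xs) + 1)

    def validate(self) -> None:
        if not self.pixels:
            raise MSIValidationError("dataset has no pixels")
        lo, hi = self.mz_range
        if not lo < hi:
            raise MSIValidationError("mz_range must be (low, high) with low < high")
        nrows, ncols = self.grid_shape
        for (x, y), spec in self.pixels.items():
            if not (0 <= x < ncols and 0 <= y < nrows):
                raise MSIValidationError(
                    f"pixel ({x}, {y}) outside declared grid {self.grid_shape}"
                )
            spec.validate()
            if spec.mz.size and (spec.mz[0] < lo or spec.mz[-1] > hi):
                raise MSIValidationError(
                    f"pixel ({x}, {y}) has peaks outside mz_range {self.mz_range}"
                )

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def write_msi(dataset: MSIDataset, path: str | Path) -> None:
    """Write a dataset as a processed-mode centroid imzML/ibd file pair.

    Invariants are validated first; nothing is written on failure.
    """
    dataset.validate()
    path = Path(path)
    with ImzMLWriter(
        str(path),
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
        mode="processed",
        spec_type="centroid",
        polarity=dataset.polarity,
    ) as writer:
        # content-derived UUID instead of a random one, so the same dataset
        # always serializes to byte-identical files; the writer has already
        # placed its random UUID at the head of the ibd, so overwrite it
        digest = hashlib.sha1()
        for (x, y) in sorted(dataset.pixels, key=lambda c: (c[1], c[0])):
            spec = dataset.pixels[(x, y)]
            digest.update(np.int64([x, y]).tobytes())
            digest.update(spec.mz.tobytes())
            digest.update(spec.intensity.tobytes())
        writer.uuid = uuid.UUID(bytes=digest.digest()[:16])
        writer.ibd.seek(0)
        writer.ibd.write(writer.uuid.bytes)
        writer.ibd.seek(0, 2)
        # row-major order for reproducible byte layout
        for (x, y) in sorted(dataset.pixels, key=lambda c: (c[1], c[0])):
            spec = dataset.pixels[(x, y)]
            coords = (x + 1, y + 1)  # imzML is 1-based
            if len(spec) == 0:
                # pyimzml's addSpectrum cannot serialize zero-length peak
                # lists; append the record through its internals instead.
                mz_data = writer._encode_and_write(
                    np.array([], dtype=np.float64), writer.mz_dtype, writer.mz_compression
                )
                int_data = writer._encode_and_write(
                    np.array([], dtype=np.float32),
                    writer.intensity_dtype,
                    writer.intensity_compression,
                )
                writer.spectra.append(
                    _Spectrum(
                        coords,
                        mz_data[1], mz_data[0], mz_data[2],
                        int_data[1], int_data[0], int_data[2],
                        0.0, 0.0, 0.0, 0.0, 0.0, [],
                    )
                )
            else:
                writer.addSpectrum(spec.mz, spec.intensity, coords=coords)


def read_msi(
    path: str | Path,
    *,
    pixel_pitch_um: float = 400.0,
    mz_range: tuple[float, float] | None = None,
    section_id: str | None = None,
    group_label: str = "",
) -> MSIDataset:
    """Read a processed-mode centroid imzML file pair.

    Raises :class:`UnsupportedModeError` for continuous (profile-layout)
    files and :class:`MSIParseError` for duplicate pixel coordinates.  If
    ``mz_range`` is not given it is taken as the data's peak envelope.
    """
    path = Path(path)
    parser = ImzMLParser(str(path))
    try:
        names = parser.metadata.file_description.param_by_name
    except AttributeError:  # pragma: no cover - very old files
        names = {}
    if "continuous" in names and "processed" not in names:
        raise UnsupportedModeError(
            f"{path.name}: continuous-mode imzML is not supported; "
            "re-export as processed (centroided) data"
        )

    pixels: dict[tuple[int, int], CentroidSpectrum] = {}
    lo, hi = math.inf, -math.inf
    for i, coord in enumerate(parser.coordinates):
        x, y = int(coord[0]) - 1, int(coord[1]) - 1
        if (x, y) in pixels:
            raise MSIParseError(
                f"{path.name}: duplicate pixel coordinate at file entry {i} "
                f"(x={coord[0]}, y={coord[1]})"
            )
        mzs, ints = parser.getspectrum(i)
        spec = CentroidSpectrum(np.asarray(mzs), np.asarray(ints))
        spec.validate()
        if len(spec):
            lo = min(lo, float(spec.mz[0]))
            hi = max(hi, float(spec.mz[-1]))
        pixels[(x, y)] = spec

    if mz_range is None:
        if lo > hi:  # no peaks anywhere
            mz_range = (0.0, 1.0)
        elif lo == hi:  # a single distinct m/z: pad to a proper interval
            mz_range = (lo - 0.5, hi + 0.5)
        else:
            mz_range = (lo, hi)
    dataset = MSIDataset(
        pixels=pixels,
        pixel_pitch_um=pixel_pitch_um,
        mz_range=mz_range,
        polarity="positive",
        section_id=section_id if section_id is not None else path.stem,
        group_label=group_label,
    )
    dataset.validate()
    return dataset


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str, charge: int = 0) -> float:
    """Monoisotopic m/z of an ion written as an elemental formula.

    The formula denotes the ion's full atomic composition; the returned value
    is the sum of most-abundant-isotope masses minus ``charge`` electron
    masses, divided by ``|charge|`` when the species is charged.  Elemental
    isotope masses come from pyteomics' NIST table.

    >>> round(monoisotopic_mass("H2O"), 4)
    18.0106
    """
    from pyteomics import mass as _ptmass

    # validate symbols up-front so unknown elements fail with a clear name
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula near {formula[pos:]!r}")
        pos = m.end()
        if m.group(1) not in _ptmass.nist_mass:
            raise ValueError(f"unknown element symbol {m.group(1)!r} in {formula!r}")
    if pos != len(formula):
        raise ValueError(f"malformed formula near {formula[pos:]!r}")

    neutral = _ptmass.calculate_mass(formula=formula)
    ion = neutral - charge * ELECTRON_MASS_DA
    return ion / abs(charge) if charge else ion
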