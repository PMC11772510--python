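"""Core in-memory containers for the two imaging modalities.

A single tissue section is imaged twice: once by MALDI-type mass
spectrometry imaging (a centroided mass spectrum per pixel, the *spectral*
modality) and once by LA-ICP-MS (per-element ion-count rasters, the
*elemental* modality). The types here carry both, plus landmark
correspondences between the two pixel grids and raw time-resolved laser
line scans before rasterization.

Conventions
-----------
* Coordinates are 0-based, ``col = x``, ``row = y``, origin at the top
  left, pixel centers at integer coordinates. File formats with 1-based
  coordinates (imzML) are shifted at the I/O boundary.
* Missing elemental values are ``NaN`` — distinct from 0, which is a
  legitimate ion count.
* Units are carried explicitly on each elemental channel and never
  inferred from value magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("duomsi")

#: Unit tags for elemental channels.
COUNTS_PER_SECOND = "counts_per_second"
MG_PER_KG = "mg_per_kg"

#: Missing-value marker for elemental rasters (never 0).
MISSING = np.nan


class DuomsiError(Exception):
    """Base class for all package errors."""


class FormatError(DuomsiError):
    """A file could not be parsed as the expected format."""


class DimensionMismatchError(DuomsiError):
    """Rasters or grids that must share a shape do not."""


class UnsupportedModeError(FormatError):
    """Profile-mode spectral data; only centroided data are supported."""


class DegenerateLandmarksError(DuomsiError):
    """Landmark configuration cannot constrain the requested transform."""


class CalibrationError(DuomsiError):
    """External calibration could not be fitted or applied."""


# ---------------------------------------------------------------------------
# Spectral modality
# ---------------------------------------------------------------------------

@dataclass
class SpectralImage:
    """Pixel grid of centroided mass spectra.

    Parameters
    ----------
    width, height
        Grid size in pixels.
    pixel_size
        Isotropic pixel edge length in µm.
    mzs, intensities
        Flat row-major lists (``index = row * width + col``) of 1-D float
        arrays; within each pixel m/z is strictly increasing and
        intensities are ≥ 0. A missing pixel is an empty pair of arrays,
        never an absent entry.
    mz_range
        ``(min, max)`` acquisition mass range in Da.
    metadata
        Free-form acquisition annotations (polarity, source, ...).
    """

    width: int
    height: int
    pixel_size: float
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    mz_range: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.width * self.height
        if len(self.mzs) != n or len(self.intensities) != n:
            raise DimensionMismatchError(
                f"pixel list length {len(self.mzs)}/{len(self.intensities)} "
                f"!= width*height = {n}"
            )

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def index(self, row: int, col: int) -> int:
        return row * self.width + col

    def spectrum_at(self, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
        i = self.index(row, col)
        return self.mzs[i], self.intensities[i]

    def tic_image(self) -> np.ndarray:
        """Total ion current per pixel as a (height, width) raster."""
        tic = np.fromiter(
            (float(inten.sum()) if inten.size else 0.0 for inten in self.intensities),
            dtype=float,
            count=self.n_pixels,
        )
        return tic.reshape(self.height, self.width)

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        lo, hi = self.mz_range
        for i, (mz, inten) in enumerate(zip(self.mzs, self.intensities)):
            if mz.shape != inten.shape:
                raise DimensionMismatchError(f"pixel {i}: m/z and intensity lengths differ")
            if mz.size == 0:
                continue
            if np.any(np.diff(mz) <= 0):
                raise FormatError(f"pixel {i}: m/z not strictly increasing")
            if mz[0] < lo or mz[-1] > hi:
                raise FormatError(f"pixel {i}: m/z outside declared range {self.mz_range}")
            if np.any(inten < 0):
                raise FormatError(f"pixel {i}: negative intensity")

    def copy(self) -> "SpectralImage":
        return SpectralImage(
            width=self.width,
            height=self.height,
            pixel_size=self.pixel_size,
            mzs=[m.copy() for m in self.mzs],
            intensities=[i.copy() for i in self.intensities],
            mz_range=self.mz_range,
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# Elemental modality
# ---------------------------------------------------------------------------

@dataclass
class ElementChannel:
    """One per-element raster with its unit.

    ``values`` is a (height, width) float array; missing pixels are NaN.
    """

    label: str
    unit: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionMismatchError(f"channel {self.label}: raster must be 2-D")
        if self.unit not in (COUNTS_PER_SECOND, MG_PER_KG):
            raise ValueError(f"channel {self.label}: unknown unit {self.unit!r}")


@dataclass
class ElementalStack:
    """Named set of co-gridded per-element rasters.

    Quantified (mg/kg) and unquantified (counts/s) channels may coexist:
    elements with high endogenous background in the gelatine standards are
    kept as raw counts per second.
    """

    pixel_size: float
    channels: list[ElementChannel]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ElementalStack needs at least one channel")
        shape = self.channels[0].values.shape
        for ch in self.channels[1:]:
            if ch.values.shape != shape:
                raise DimensionMismatchError(
                    f"channel {ch.label} shape {ch.values.shape} != {shape}"
                )

    @property
    def height(self) -> int:
        return self.channels[0].values.shape[0]

    @property
    def width(self) -> int:
        return self.channels[0].values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].values.shape

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    def channel(self, label: str) -> ElementChannel:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise KeyError(f"no channel {label!r}; have {self.labels}")

    def copy(self) -> "ElementalStack":
        return ElementalStack(
            pixel_size=self.pixel_size,
            channels=[
                ElementChannel(ch.label, ch.unit, ch.values.copy()) for ch in self.channels
            ],
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# Landmarks and line scans
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Paired pixel coordinates linking the two modality grids.

    ``fixed`` and ``moving`` are (n, 2) arrays of (x, y) coordinates, each
    in its own modality's pixel grid; row *i* of both arrays marks the same
    physical spot on the section.
    """

    fixed: np.ndarray
    moving: np.ndarray
    labels: list[str] | None = None
    fixed_ref: str = "spectral"
    moving_ref: str = "elemental"

    def __post_init__(self) -> None:
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if self.fixed.shape != self.moving.shape or self.fixed.shape[1] != 2:
            raise DimensionMismatchError("fixed and moving must both be (n, 2)")
        if len(self.fixed) < 1:
            raise ValueError("no landmarks")
        if not (np.isfinite(self.fixed).all() and np.isfinite(self.moving).all()):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.fixed)


@dataclass
class LaserLineSeries:
    """Time-resolved ICP-MS readings from one ablation line.

    The laser travels at ``scan_speed`` µm/s along x; a reading at time
    *t* (seconds since line start) was ablated at position
    ``t * scan_speed`` µm from the line start. Lines are stacked in y by
    ``y_offset``.
    """

    line_index: int
    y_offset: float
    timestamps: np.ndarray
    counts: dict[str, np.ndarray]
    scan_speed: float
    beam_diameter: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise FormatError(f"line {self.line_index}: timestamps not strictly increasing")
        for el, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            self.counts[el] = arr
            if arr.shape != self.timestamps.shape:
                raise DimensionMismatchError(
                    f"line {self.line_index}: element {el} series length mismatch"
                )

    @property
    def elements(self) -> list[str]:
        return list(self.counts)
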