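"""Paired two-modality phantoms with analytic ground truth.

The generator emulates the data structure of a mouse-brain section
imaged by both modalities: a region map built from nested ellipses
(cortex-like outer tissue, white-matter-like inner ellipse, a
hippocampus-like ring), a per-channel × per-region mean-intensity
matrix, and a known similarity misalignment between the two grids.

Noise model (all configurable, defaults are the stated world of the
test suite):

* lipid peak intensities: truncated-Gaussian multiplicative noise,
  coefficient of variation 0.15 — empirical MALDI pixel variability;
* a per-pixel total-ion-current factor drawn uniformly from [0.5, 2]
  multiplying every peak of that pixel's spectrum — the explicit
  mechanism that makes TIC normalisation consequential;
* elemental counts: Poisson (ICP counting statistics) with region means
  well above 50 counts;
* landmarks: 6 fiducial points mapped through the true transform with
  Gaussian jitter of σ = 0.5 px;
* misalignment: 5° rotation about the grid center plus a
  (+4.5, −3.2) px translation.

Geometry is parametric, not atlas-based, so the population Pearson
correlation between any two channels is computable in closed form from
region areas and the mean matrix (:func:`expected_correlation`); the
analytic value refers to the *TIC-normalised* lipid signal, which is
what the pipeline correlates. Everything is deterministic given the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    COUNTS_PER_SECOND,
    ElementalStack,
    ElementChannel,
    LandmarkSet,
    LaserLineSeries,
    SpectralImage,
)
from .registration import AffineTransform2D

# Default channels: positive-mode brain lipids ([M+H]+ theoretical m/z
# from the bundled database) and a typical LA-ICP-MS element panel.
DEFAULT_LIPIDS = [
    ("PE 34:1", 718.5381),
    ("PE 36:1", 746.5694),
    ("PE 38:4", 768.5538),
    ("PE 40:6", 792.5538),
    ("HexCer 42:2;2", 810.6817),
]
DEFAULT_ELEMENTS = ["23Na", "31P", "56Fe", "66Zn"]

# Mean matrices, channels × regions (cortex, white matter, hippocampal
# ring). Lipid rows are fractions of the regional TIC (columns sum to 1)
# times a regional TIC level. Between-region contrast is strong (≥6×
# per channel, as in real gray/white-matter lipid images); this also
# keeps the noise-induced attenuation of the pixel-to-pixel Pearson
# coefficients well below the recovery tolerance of the test suite.
_REGION_TIC = np.array([2000.0, 1600.0, 1800.0])
_LIPID_SHARES = np.array(
    [
        [0.50, 0.04, 0.06],  # PE 34:1 — gray-matter dominant
        [0.06, 0.04, 0.42],  # PE 36:1 — ring dominant
        [0.32, 0.03, 0.06],  # PE 38:4 — cortex
        [0.08, 0.04, 0.42],  # PE 40:6 — ring
        [0.04, 0.85, 0.04],  # HexCer 42:2;2 — myelin/white matter
    ]
)
DEFAULT_LIPID_MEANS = _LIPID_SHARES * _REGION_TIC
DEFAULT_ELEMENT_MEANS = np.array(
    [
        [5000.0, 1100.0, 4200.0],  # 23Na
        [4200.0, 1400.0, 3200.0],  # 31P
        [500.0, 1100.0, 450.0],    # 56Fe — white-matter/vessel-like
        [1100.0, 400.0, 3200.0],   # 66Zn — hippocampus-enriched
    ]
)

# Region geometry as fractions of the grid: outer tissue ellipse,
# white-matter inner ellipse, hippocampal ring (annulus of the inner
# ellipse's normalised radius). Region areas are deliberately of the
# same order so no single region dominates the correlation statistics.
_OUTER_AX = (0.42, 0.40)
_INNER_AX = (0.24, 0.22)
_RING_RHO = (1.25, 1.60)


def default_true_transform(width: int = 640, height: int = 480) -> AffineTransform2D:
    """5° rotation about the grid center plus (+4.5, −3.2) px translation."""
    theta = math.radians(5.0)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    center = np.array([(width - 1) / 2.0, (height - 1) / 2.0])
    shift = np.array([4.5, -3.2])
    return AffineTransform2D(
        matrix=rot,
        translation=center - rot @ center + shift,
        family="similarity",
    )


@dataclass
class PhantomConfig:
    """Stated world of the synthetic section; defaults match the test suite."""

    width: int = 640
    height: int = 480
    pixel_size: float = 30.0  # µm
    n_regions: int = 3
    lipids: list[tuple[str, float]] = field(default_factory=lambda: list(DEFAULT_LIPIDS))
    element_labels: list[str] = field(default_factory=lambda: list(DEFAULT_ELEMENTS))
    lipid_means: np.ndarray = field(default_factory=lambda: DEFAULT_LIPID_MEANS.copy())
    element_means: np.ndarray = field(default_factory=lambda: DEFAULT_ELEMENT_MEANS.copy())
    lipid_cv: float = 0.15
    tic_factor_range: tuple[float, float] = (0.5, 2.0)
    poisson_elements: bool = True
    landmark_sigma: float = 0.5  # px
    n_landmarks: int = 6
    mz_shift_ppm: float = 0.0  # injected global miscalibration
    mz_range: tuple[float, float] = (200.0, 1000.0)
    scan_speed: float = 750.0  # µm/s
    beam_diameter: float = 30.0  # µm
    readings_per_pixel: int = 2
    true_transform: AffineTransform2D | None = None

    def __post_init__(self) -> None:
        self.lipid_means = np.asarray(self.lipid_means, dtype=float)
        self.element_means = np.asarray(self.element_means, dtype=float)
        if self.n_regions < 2:
            raise ValueError("need at least 2 tissue regions")
        if len(self.lipids) < 2 or len(self.element_labels) < 2:
            raise ValueError("need at least 2 channels per modality")
        if self.lipid_means.shape != (len(self.lipids), self.n_regions):
            raise ValueError(
                f"lipid_means must be {(len(self.lipids), self.n_regions)}, "
                f"got {self.lipid_means.shape}"
            )
        if self.element_means.shape != (len(self.element_labels), self.n_regions):
            raise ValueError(
                f"element_means must be {(len(self.element_labels), self.n_regions)}, "
                f"got {self.element_means.shape}"
            )
        if (self.lipid_means < 0).any() or (self.element_means < 0).any():
            raise ValueError("channel means must be >= 0")


@dataclass
class Phantom:
    """Generated ground truth: region map, means, transform, seed."""

    config: PhantomConfig
    region_map: np.ndarray  # (height, width) int, 0 = off-tissue
    true_transform: AffineTransform2D
    seed: int

    @property
    def lipid_labels(self) -> list[str]:
        return [name for name, _ in self.config.lipids]

    @property
    def lipid_mzs(self) -> np.ndarray:
        return np.array([mz for _, mz in self.config.lipids])

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.region_map > 0

    def region_areas(self) -> np.ndarray:
        """Pixel counts of tissue regions 1..R."""
        return np.bincount(self.region_map.ravel(), minlength=self.config.n_regions + 1)[1:]

    def normalized_lipid_means(self) -> np.ndarray:
        """Per-region lipid signal after TIC normalisation: share of TIC."""
        tic = self.config.lipid_means.sum(axis=0)
        return self.config.lipid_means / np.where(tic > 0, tic, 1.0)


def region_at_points(config: PhantomConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Region label of arbitrary continuous fixed-frame coordinates.

    The scene is analytic (ellipse inequalities evaluated at real
    coordinates), so both the pixelated region map and any transformed
    point sample are consistent point evaluations of the same geometry.
    """
    w, h = config.width, config.height
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    outer = ((x - cx) / (_OUTER_AX[0] * w)) ** 2 + ((y - cy) / (_OUTER_AX[1] * h)) ** 2 <= 1.0
    region = np.where(outer, 1, 0)
    a2, b2 = _INNER_AX[0] * w, _INNER_AX[1] * h
    rho = np.sqrt(((x - cx) / a2) ** 2 + ((y - cy) / b2) ** 2)
    if config.n_regions >= 3:
        region[(rho >= _RING_RHO[0]) & (rho <= _RING_RHO[1]) & outer] = 3
    if config.n_regions >= 2:
        region[rho <= 1.0] = 2
    if config.n_regions >= 4:
        blob = ((x - 0.28 * w) / (0.06 * w)) ** 2 + ((y - 0.5 * h) / (0.09 * h)) ** 2 <= 1.0
        region[blob & outer] = 4
    if config.n_regions > 4:
        raise ValueError("parametric geometry supports at most 4 regions")
    return region


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> Phantom:
    """Build the region map and fix the true transform; deterministic in seed."""
    config = config or PhantomConfig()
    w, h = config.width, config.height
    xg, yg = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    region = region_at_points(config, xg, yg)

    areas = np.bincount(region.ravel(), minlength=config.n_regions + 1)[1:]
    tissue = int((region > 0).sum())
    if tissue == 0 or (areas < max(1, 0.01 * tissue)).any():
        raise ValueError(
            f"infeasible geometry: region areas {areas.tolist()} on {tissue} tissue px"
        )
    t = config.true_transform or default_true_transform(w, h)
    return Phantom(config=config, region_map=region, true_transform=t, seed=int(seed))


def render_spectral(phantom: Phantom) -> SpectralImage:
    """Per-pixel centroided spectra: one peak per lipid channel.

    Intensity = max(0, Normal(mean, CV·mean)) × a per-pixel TIC factor
    drawn uniformly from the configured range; off-tissue pixels are
    empty. An optional global m/z shift (ppm) miscalibrates the mass axis.
    """
    cfg = phantom.config
    rng = np.random.default_rng([phantom.seed, 1])
    mz = phantom.lipid_mzs * (1.0 + cfg.mz_shift_ppm * 1e-6)
    order = np.argsort(mz)
    mz_sorted = mz[order]
    means = cfg.lipid_means[order]  # (L, R)
    h, w = cfg.height, cfg.width
    mzs: list[np.ndarray] = []
    intensities: list[np.ndarray] = []
    lo, hi = cfg.tic_factor_range
    for row in range(h):
        for col in range(w):
            r = phantom.region_map[row, col]
            if r == 0:
                mzs.append(np.empty(0))
                intensities.append(np.empty(0))
                continue
            mu = means[:, r - 1]
            if cfg.lipid_cv > 0:
                inten = np.maximum(0.0, rng.normal(mu, cfg.lipid_cv * mu))
            else:
                inten = mu.copy()
            inten *= rng.uniform(lo, hi)
            mzs.append(mz_sorted.copy())
            intensities.append(inten)
    return SpectralImage(
        width=w,
        height=h,
        pixel_size=cfg.pixel_size,
        mzs=mzs,
        intensities=intensities,
        mz_range=cfg.mz_range,
        metadata={"polarity": "positive", "source": "duomsi synthetic phantom"},
    )


def _scene_element_values(phantom: Phantom, points: np.ndarray) -> np.ndarray:
    """Region index (0 off-tissue) of continuous fixed-frame points."""
    return region_at_points(phantom.config, points[:, 0], points[:, 1])


def render_elemental(
    phantom: Phantom, emit_lines: bool = False
) -> tuple[ElementalStack, LandmarkSet, list[LaserLineSeries]]:
    """Elemental rasters on the misaligned grid, landmarks, line scans.

    The moving-grid pixel at (x, y) samples the fixed-frame scene at
    ``true_transform((x, y))``: Poisson counts around the region mean
    (or exact means with Poisson off), 0 off tissue. Landmarks are
    fiducial points in the moving frame paired with their true-transform
    images in the fixed frame, jittered by ``landmark_sigma``. With
    ``emit_lines`` the same rasters are also emitted as time-resolved
    line scans consistent with the scan geometry (30 µm pixels at
    750 µm/s → 0.04 s per pixel), so rasterization can be round-tripped.
    """
    cfg = phantom.config
    rng = np.random.default_rng([phantom.seed, 2])
    w, h = cfg.width, cfg.height
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    reg = _scene_element_values(phantom, phantom.true_transform(pts))

    channels = []
    means_ext = np.column_stack([np.zeros(len(cfg.element_labels)), cfg.element_means])
    for i, label in enumerate(cfg.element_labels):
        mu = means_ext[i, reg]
        vals = rng.poisson(mu).astype(float) if cfg.poisson_elements else mu.astype(float)
        channels.append(ElementChannel(label, COUNTS_PER_SECOND, vals.reshape(h, w)))
    stack = ElementalStack(
        pixel_size=cfg.pixel_size,
        channels=channels,
        metadata={"source": "duomsi synthetic phantom", "scan_speed": cfg.scan_speed},
    )

    jitter_rng = np.random.default_rng([phantom.seed, 3])
    # fiducials near the slide corners and edge midpoints: a wide hull
    # keeps the fitted transform interpolating (not extrapolating) over
    # the whole tissue, as recommended landmark placement does
    frac = np.array(
        [[0.05, 0.05], [0.95, 0.05], [0.05, 0.95], [0.95, 0.95], [0.50, 0.03], [0.50, 0.97]]
    )
    if cfg.n_landmarks > len(frac):
        extra = jitter_rng.uniform(0.1, 0.9, size=(cfg.n_landmarks - len(frac), 2))
        frac = np.vstack([frac, extra])
    moving = frac[: cfg.n_landmarks] * np.array([w - 1, h - 1])
    fixed = phantom.true_transform(moving)
    if cfg.landmark_sigma > 0:
        fixed = fixed + jitter_rng.normal(0.0, cfg.landmark_sigma, size=fixed.shape)
    landmarks = LandmarkSet(fixed=fixed, moving=moving)

    lines: list[LaserLineSeries] = []
    if emit_lines:
        dwell = cfg.pixel_size / cfg.scan_speed
        k = np.arange(w)
        offs = (np.arange(cfg.readings_per_pixel) + 0.5) / cfg.readings_per_pixel
        times = (k[:, None] + offs[None, :]).ravel() * dwell
        for row in range(h):
            counts = {
                ch.label: np.repeat(ch.values[row], cfg.readings_per_pixel)
                for ch in stack.channels
            }
            lines.append(
                LaserLineSeries(
                    line_index=row,
                    y_offset=row * cfg.pixel_size,
                    timestamps=times.copy(),
                    counts=counts,
                    scan_speed=cfg.scan_speed,
                    beam_diameter=cfg.beam_diameter,
                )
            )
    return stack, landmarks, lines


def expected_correlation(
    phantom: Phantom, lipid_label: str, element_label: str
) -> float:
    """Analytic population Pearson r over the tissue mask.

    Computed from region areas and the noiseless per-pixel mean images
    the pipeline would see: the TIC-normalised lipid signal (regional
    share of TIC) against the elemental region mean. NaN when either
    channel is constant over the tissue.
    """
    li = phantom.lipid_labels.index(lipid_label)
    ei = phantom.config.element_labels.index(element_label)
    x = phantom.normalized_lipid_means()[li]  # per-region
    y = phantom.config.element_means[ei]
    wts = phantom.region_areas().astype(float)
    wsum = wts.sum()
    mx = float(np.dot(wts, x)) / wsum
    my = float(np.dot(wts, y)) / wsum
    cov = float(np.dot(wts, (x - mx) * (y - my))) / wsum
    vx = float(np.dot(wts, (x - mx) ** 2)) / wsum
    vy = float(np.dot(wts, (y - my) ** 2)) / wsum
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(np.clip(cov / math.sqrt(vx * vy), -1.0, 1.0))


def expected_correlation_matrix(phantom: Phantom) -> np.ndarray:
    """(lipids × elements) analytic coefficients."""
    return np.array(
        [
            [expected_correlation(phantom, l, e) for e in phantom.config.element_labels]
            for l in phantom.lipid_labels
        ]
    )


def write_phantom_dataset(phantom: Phantom, outdir: str | Path, emit_lines: bool = True) -> dict:
    """Write the phantom through the standard writers.

    Produces ``spectral.imzML``(+``.ibd``), ``elements/`` CSV grids with
    sidecar, ``landmarks.tsv``, ``lines/`` per-line CSVs + run sheet,
    ``targets.csv``, and a ground-truth sidecar (region map, true
    transform, analytic correlation table). Returns the path map.
    """
    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectral = render_spectral(phantom)
    stack, landmarks, lines = render_elemental(phantom, emit_lines=emit_lines)

    paths = {"root": outdir}
    dio.write_imzml(spectral, outdir / "spectral.imzML")
    paths["imzml"] = outdir / "spectral.imzML"
    dio.write_element_csv(stack, outdir / "elements")
    paths["elements"] = outdir / "elements"
    dio.write_landmarks(landmarks, outdir / "landmarks.tsv")
    paths["landmarks"] = outdir / "landmarks.tsv"
    if emit_lines:
        paths["run_sheet"] = dio.write_line_scans(lines, outdir / "lines")
    dio.write_targets_csv(list(phantom.config.lipids), outdir / "targets.csv")
    paths["targets"] = outdir / "targets.csv"

    truth = outdir / "ground_truth"
    truth.mkdir(exist_ok=True)
    dio.write_raster_csv(phantom.region_map.astype(float), truth / "region_map.csv")
    phantom.true_transform.save(truth / "true_transform.txt")
    import pandas as pd

    pd.DataFrame(
        expected_correlation_matrix(phantom),
        index=phantom.lipid_labels,
        columns=phantom.config.element_labels,
    ).to_csv(truth / "expected_correlations.csv", na_rep="NA", float_format="%.6f")
    paths["ground_truth"] = truth
    return paths


def simulate_standards(
    element: str,
    slope: float,
    intercept: float,
    concentrations: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 50.0),
    n_readings: int = 200,
    poisson: bool = True,
    seed: int = 0,
) -> list:
    """Synthetic spiked-gelatine standards for calibration tests.

    True signal is ``slope·c + intercept`` counts/s; readings are Poisson
    around it (or exact). Returns :class:`CalibrationStandard` objects.
    """
    from .elemental import CalibrationStandard

    rng = np.random.default_rng([seed, 4])
    out = []
    for c in concentrations:
        mu = slope * c + intercept
        readings = rng.poisson(mu, size=n_readings).astype(float) if poisson else np.full(
            n_readings, mu
        )
        out.append(CalibrationStandard(element=element, nominal_concentration=c, observed=readings))
    return out
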