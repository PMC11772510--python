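"""Ion-image rendering from centroided spectral data.

The rendering chain mirrors standard MALDI-MSI display settings: a
two-sided ppm window around the target m/z (default 10 ppm), total ion
current (TIC) normalisation, and hot-spot removal by clipping at the 99%
quantile of the in-tissue, nonzero pixel values. A global multiplicative
mass-axis recalibration against known endogenous lipid signals and a
ppm-binned mean spectrum round out the module.

Numerical conventions:

* the ppm window is symmetric and inclusive: ``|mz - target| <=
  target * tol * 1e-6``;
* the clip quantile uses the linear-interpolation definition over the
  *nonzero* pixel values (zeros are off-tissue background and would
  deflate the quantile); computing it over all pixels is available via
  ``nonzero_only=False``;
* TIC normalisation returns pure ratios — no rescaling by the mean TIC,
  which would cancel in any scale-invariant downstream statistic anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import DimensionMismatchError, DuomsiError, SpectralImage

log = logging.getLogger("duomsi")


@dataclass
class IonImage:
    """Raster of summed peak intensity around one target m/z."""

    target_mz: float
    tolerance_ppm: float
    values: np.ndarray
    normalized: bool = False
    clipped_at: float | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.label:
            self.label = f"m/z {self.target_mz:.4f}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RecalibrationModel:
    """Single global multiplicative m/z correction.

    ``factor`` multiplies every observed m/z; ``reference_pairs`` records
    the matched (observed, theoretical) peak pairs and ``skipped`` the
    reference masses with no mean-spectrum peak inside the search window.
    """

    reference_pairs: list[tuple[float, float]]
    factor: float
    skipped: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.reference_pairs:
            raise DuomsiError("recalibration model needs at least one reference pair")
        if abs(self.factor - 1.0) > 100e-6:
            raise DuomsiError(
                f"recalibration factor {self.factor!r} implies a shift beyond 100 ppm; "
                "check the reference list"
            )

    @property
    def shift_ppm(self) -> float:
        """Correction expressed in ppm (positive = observed masses were low)."""
        return (self.factor - 1.0) * 1e6


def extract_ion_image(
    img: SpectralImage, target_mz: float, tolerance_ppm: float = 10.0
) -> IonImage:
    """Sum, per pixel, all peak intensities within ``tolerance_ppm`` of
    ``target_mz``. Empty spectra give 0. The result is neither normalised
    nor clipped."""
    lo_r, hi_r = img.mz_range
    if not (lo_r <= target_mz <= hi_r):
        raise ValueError(
            f"target m/z {target_mz} outside acquisition range {img.mz_range}"
        )
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    half = target_mz * tolerance_ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    out = np.zeros(img.n_pixels)
    for i, (mz, inten) in enumerate(zip(img.mzs, img.intensities)):
        if mz.size == 0:
            continue
        a = np.searchsorted(mz, lo, side="left")
        b = np.searchsorted(mz, hi, side="right")
        if b > a:
            out[i] = inten[a:b].sum()
    return IonImage(
        target_mz=target_mz,
        tolerance_ppm=tolerance_ppm,
        values=out.reshape(img.height, img.width),
    )


def tic_normalize(ionimg: IonImage, img: SpectralImage) -> IonImage:
    """Divide each pixel by that pixel's total ion current.

    Pixels with zero TIC (empty spectra) stay 0. Idempotent flags: the
    result is marked ``normalized``.
    """
    tic = img.tic_image()
    if tic.shape != ionimg.values.shape:
        raise DimensionMismatchError(
            f"ion image shape {ionimg.values.shape} != spectral grid {tic.shape}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(tic > 0, ionimg.values / tic, 0.0)
    return IonImage(
        target_mz=ionimg.target_mz,
        tolerance_ppm=ionimg.tolerance_ppm,
        values=values,
        normalized=True,
        clipped_at=ionimg.clipped_at,
        label=ionimg.label,
        metadata=dict(ionimg.metadata),
    )


def quantile_hotspot_clip(
    ionimg: IonImage,
    q: float = 0.99,
    mask: np.ndarray | None = None,
    nonzero_only: bool = True,
) -> IonImage:
    """Clip hot spots at the ``q``-quantile of the in-mask pixel values.

    The threshold is the linear-interpolation quantile of the nonzero
    (by default) pixel values inside ``mask`` (everywhere if no mask);
    values above it are set to the threshold. An all-zero image is
    returned unchanged with ``clipped_at = 0``.

    Idempotent: an image already clipped (its recorded ``clipped_at``
    bounds every value) is returned unchanged — recomputing the
    interpolated quantile on a clipped distribution would otherwise walk
    the threshold down on every application.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie strictly between 0 and 1")
    v = ionimg.values
    if ionimg.clipped_at is not None and np.nanmax(v, initial=0.0) <= ionimg.clipped_at:
        return ionimg
    sel = np.isfinite(v)
    if mask is not None:
        if mask.shape != v.shape:
            raise DimensionMismatchError("mask shape mismatch")
        sel &= mask.astype(bool)
    if nonzero_only:
        sel &= v != 0
    pool = v[sel]
    threshold = float(np.quantile(pool, q)) if pool.size else 0.0
    clipped = np.where(np.isfinite(v), np.minimum(v, threshold), v) if pool.size else v.copy()
    meta = dict(ionimg.metadata)
    meta["hotspot_quantile"] = q
    meta["hotspot_pool"] = "nonzero" if nonzero_only else "all"
    return IonImage(
        target_mz=ionimg.target_mz,
        tolerance_ppm=ionimg.tolerance_ppm,
        values=clipped,
        normalized=ionimg.normalized,
        clipped_at=threshold,
        label=ionimg.label,
        metadata=meta,
    )


def mean_spectrum(
    img: SpectralImage, bin_width_ppm: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Dataset mean spectrum on a ppm-constant (geometric) bin grid.

    Peaks from all pixels are pooled into bins of constant relative width
    ``bin_width_ppm``; each bin reports the intensity-weighted mean m/z of
    its peaks and the per-pixel mean intensity (pixels without a peak in
    the bin contribute 0). Empty bins are dropped.

    Returns ``(mz_centers, mean_intensities)``, both 1-D ascending.
    """
    if bin_width_ppm <= 0:
        raise ValueError("bin_width_ppm must be positive")
    nonempty = [i for i, m in enumerate(img.mzs) if m.size]
    if not nonempty:
        return np.empty(0), np.empty(0)
    all_mz = np.concatenate([img.mzs[i] for i in nonempty])
    all_int = np.concatenate([img.intensities[i] for i in nonempty])
    mz_min = float(all_mz.min())
    w = np.log1p(bin_width_ppm * 1e-6)
    idx = np.floor(np.log(all_mz / mz_min) / w).astype(np.int64)
    idx -= idx.min()
    nbins = int(idx.max()) + 1
    tot_int = np.bincount(idx, weights=all_int, minlength=nbins)
    tot_wmz = np.bincount(idx, weights=all_int * all_mz, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    occupied = counts > 0
    centers = np.where(
        tot_int[occupied] > 0,
        tot_wmz[occupied] / np.where(tot_int[occupied] > 0, tot_int[occupied], 1.0),
        # all-zero-intensity bin: plain mean m/z
        np.bincount(idx, weights=all_mz, minlength=nbins)[occupied]
        / counts[occupied],
    )
    means = tot_int[occupied] / img.n_pixels
    order = np.argsort(centers)
    return centers[order], means[order]


def fit_recalibration(
    img: SpectralImage,
    references: list[float],
    search_ppm: float = 20.0,
    bin_width_ppm: float = 2.0,
) -> RecalibrationModel:
    """Fit a global multiplicative mass correction from reference masses.

    For each theoretical reference m/z, the nearest mean-spectrum peak
    within ``search_ppm`` is paired with it; the correction factor is the
    intensity-weighted mean of theoretical/observed ratios. References
    with no peak in the window are skipped and reported on the model.
    """
    if not references:
        raise DuomsiError("no reference masses given")
    centers, means = mean_spectrum(img, bin_width_ppm=bin_width_ppm)
    if centers.size == 0:
        raise DuomsiError("image has no peaks; cannot recalibrate")
    pairs: list[tuple[float, float]] = []
    weights: list[float] = []
    skipped: list[float] = []
    for theo in references:
        ppm = (centers - theo) / theo * 1e6
        inside = np.abs(ppm) <= search_ppm
        if not inside.any():
            skipped.append(theo)
            continue
        cand = np.flatnonzero(inside)
        best = cand[np.argmin(np.abs(ppm[cand]))]
        pairs.append((float(centers[best]), float(theo)))
        weights.append(float(means[best]))
    if not pairs:
        raise DuomsiError(
            f"none of the {len(references)} reference masses matched a peak "
            f"within {search_ppm} ppm"
        )
    if skipped:
        log.warning("recalibration skipped %d unmatched references: %s", len(skipped), skipped)
    obs = np.array([p[0] for p in pairs])
    theo = np.array([p[1] for p in pairs])
    wts = np.array(weights)
    if wts.sum() <= 0:
        wts = np.ones_like(wts)
    factor = float(np.average(theo / obs, weights=wts))
    return RecalibrationModel(reference_pairs=pairs, factor=factor, skipped=skipped)


def apply_recalibration(img: SpectralImage, model: RecalibrationModel) -> SpectralImage:
    """Multiply every m/z by the model's correction factor; intensities
    are untouched."""
    f = model.factor
    out = img.copy()
    out.mzs = [m * f for m in out.mzs]
    out.mz_range = (img.mz_range[0] * f, img.mz_range[1] * f)
    out.metadata["recalibration_factor"] = f
    return out
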