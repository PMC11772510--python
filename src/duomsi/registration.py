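"""Landmark-based co-registration of the two modality grids.

A 2-D transform (translation, similarity = rotation+scale+translation,
or full affine) is estimated by least squares from paired landmark pixel
coordinates, then the moving modality (elemental, by default) is
pull-resampled onto the fixed (spectral) grid: each fixed pixel center is
mapped through the inverse transform and the moving raster is sampled
there. The two acquisitions image the same physical section, so
non-rigid models are deliberately excluded. When landmarks are given in
each modality's own pixel grid, the affine/similarity families absorb
any pixel-size difference between the grids.

Bilinear sampling is missing-aware: NaN or out-of-bounds neighbors are
dropped and the remaining weights renormalised; if all four neighbors
are missing the output pixel is missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from .datamodel import (
    DegenerateLandmarksError,
    ElementalStack,
    ElementChannel,
    LandmarkSet,
)

log = logging.getLogger("duomsi")

FAMILIES = ("translation", "similarity", "affine")


@dataclass
class AffineTransform2D:
    """Affine map from moving-grid (x, y) pixels to the fixed frame.

    ``fixed = matrix @ moving + translation``.
    """

    matrix: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    family: str = "affine"
    residual_rmse: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-8:
            raise DegenerateLandmarksError("transform linear part is singular")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(
            matrix=inv,
            translation=-inv @ self.translation,
            family=self.family,
            residual_rmse=self.residual_rmse,
        )

    @property
    def params(self) -> np.ndarray:
        """Six numbers: a11 a12 a21 a22 tx ty."""
        return np.concatenate([self.matrix.ravel(), self.translation])

    def save(self, path: str | Path) -> None:
        p = self.params
        Path(path).write_text(
            f"family {self.family}\nresidual_rmse {self.residual_rmse!r}\n"
            + " ".join(repr(float(v)) for v in p)
            + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform2D":
        lines = Path(path).read_text().strip().splitlines()
        family = lines[0].split()[1]
        rmse = float(lines[1].split()[1])
        vals = [float(v) for v in lines[2].split()]
        return cls(
            matrix=np.array(vals[:4]).reshape(2, 2),
            translation=np.array(vals[4:6]),
            family=family,
            residual_rmse=rmse,
        )


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    c = points - points.mean(axis=0)
    return np.linalg.matrix_rank(c, tol=tol) < 2


def estimate_transform(landmarks: LandmarkSet, family: str = "auto") -> AffineTransform2D:
    """Least-squares transform fit from landmark pairs.

    ``family='auto'`` picks the richest family the pair count supports:
    affine for ≥3 non-collinear pairs, similarity for 2 (or collinear ≥3),
    translation for 1. Collinear landmarks with an explicit
    ``family='affine'`` raise, naming the offending points.
    """
    fixed, moving = landmarks.fixed, landmarks.moving
    n = len(landmarks)
    if family == "auto":
        if n >= 3 and not _collinear(moving):
            family = "affine"
        elif n >= 2:
            family = "similarity"
        else:
            family = "translation"
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES} or 'auto'")

    if family == "translation":
        matrix = np.eye(2)
        translation = (fixed - moving).mean(axis=0)
    elif family == "similarity":
        if n < 2:
            raise DegenerateLandmarksError("similarity needs >= 2 landmark pairs")
        st = sktransform.SimilarityTransform()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            ok = st.estimate(moving, fixed)
        if not ok:
            raise DegenerateLandmarksError("similarity estimation failed (coincident points?)")
        matrix, translation = st.params[:2, :2], st.params[:2, 2]
    else:  # affine
        if n < 3:
            raise DegenerateLandmarksError("affine needs >= 3 landmark pairs")
        if _collinear(moving):
            labels = landmarks.labels or [str(i) for i in range(n)]
            raise DegenerateLandmarksError(
                f"landmarks {labels} are collinear in the moving frame; "
                "an affine transform is underdetermined"
            )
        # ordinary least squares per output coordinate; x and y rows of
        # the affine map are independent given the shared design matrix
        design = np.column_stack([moving, np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, fixed, rcond=None)
        matrix = coef[:2].T
        translation = coef[2]

    t = AffineTransform2D(matrix=matrix, translation=translation, family=family)
    residuals = t(moving) - fixed
    t.residual_rmse = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    log.info(
        "estimated %s transform from %d landmarks, residual RMSE %.3f px",
        family, n, t.residual_rmse,
    )
    return t


def _resample_channel(
    values: np.ndarray, xm: np.ndarray, ym: np.ndarray, interpolation: str
) -> np.ndarray:
    """Sample a moving raster at (xm, ym) moving-grid coordinates."""
    h, w = values.shape
    if interpolation == "nearest":
        xi = np.round(xm).astype(np.int64)
        yi = np.round(ym).astype(np.int64)
        inside = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        out = np.full(xm.shape, np.nan)
        out[inside] = values[yi[inside], xi[inside]]
        return out
    if interpolation != "bilinear":
        raise ValueError("interpolation must be 'nearest' or 'bilinear'")
    x0 = np.floor(xm).astype(np.int64)
    y0 = np.floor(ym).astype(np.int64)
    fx = xm - x0
    fy = ym - y0
    acc = np.zeros(xm.shape)
    wsum = np.zeros(xm.shape)
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            xi, yi = x0 + dx, y0 + dy
            inside = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            vals = np.zeros(xm.shape)
            vals[inside] = values[yi[inside], xi[inside]]
            ok = inside & np.isfinite(vals)
            wgt = np.where(ok, wx * wy, 0.0)
            acc += np.where(ok, wgt * vals, 0.0)
            wsum += wgt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, acc / wsum, np.nan)
    return out


def resample_to_fixed(
    stack: ElementalStack,
    t: AffineTransform2D,
    fixed_shape: tuple[int, int],
    interpolation: str = "bilinear",
    fixed_pixel_size: float | None = None,
) -> ElementalStack:
    """Resample every channel of the moving stack onto the fixed grid.

    For each fixed-grid pixel center, the moving raster is sampled at
    ``t⁻¹(center)``; out-of-bounds samples and (for bilinear) all-missing
    neighborhoods are missing in the output.
    """
    height, width = fixed_shape
    inv = t.inverse()
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    mpts = inv(pts)
    xm = mpts[:, 0].reshape(fixed_shape)
    ym = mpts[:, 1].reshape(fixed_shape)
    channels = [
        ElementChannel(ch.label, ch.unit, _resample_channel(ch.values, xm, ym, interpolation))
        for ch in stack.channels
    ]
    meta = dict(stack.metadata)
    meta["registered"] = {
        "family": t.family,
        "residual_rmse": t.residual_rmse,
        "interpolation": interpolation,
    }
    return ElementalStack(
        pixel_size=fixed_pixel_size if fixed_pixel_size is not None else stack.pixel_size,
        channels=channels,
        metadata=meta,
    )
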