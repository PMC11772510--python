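"""Pixel-to-pixel Pearson correlation between the registered modalities.

Each TIC-normalised lipid ion image is correlated with each elemental
channel over a shared tissue mask (TIC > 0 and all elemental channels
present). Deletion is pairwise-complete per channel pair — each cell of
the matrix uses every pixel where *its two* channels are both present,
which is exactly a "pixel-to-pixel" comparison of two images at a time.
Pearson's r is affine-invariant, so it does not matter whether elemental
channels enter as raw counts per second or quantified mg/kg.

Cells where either channel is constant (or fewer than two complete
pixels exist) are undefined and carried as NaN, serialized as "NA" —
never silently set to 0, which would fabricate "no correlation".

Also here: two-channel false-colour composites (red/blue or
magenta/cyan) and the heatmap/CSV export of the correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import DimensionMismatchError, ElementalStack
from .ion_imaging import IonImage, quantile_hotspot_clip

log = logging.getLogger("duomsi")

PALETTES = {
    "red_blue": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
    "magenta_cyan": (np.array([1.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0])),
}


@dataclass
class CorrelationMatrix:
    """Lipid × element Pearson coefficients with per-cell pixel counts."""

    row_labels: list[str]
    col_labels: list[str]
    r: np.ndarray
    n_pixels: np.ndarray
    mask_size: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        expected = (len(self.row_labels), len(self.col_labels))
        if self.r.shape != expected or self.n_pixels.shape != expected:
            raise DimensionMismatchError(
                f"matrix shape {self.r.shape} inconsistent with labels {expected}"
            )
        defined = np.isfinite(self.r)
        if defined.any() and (np.abs(self.r[defined]) > 1 + 1e-12).any():
            raise ValueError("Pearson coefficients outside [-1, 1]")

    def cell(self, row_label: str, col_label: str) -> float:
        return float(
            self.r[self.row_labels.index(row_label), self.col_labels.index(col_label)]
        )


def build_mask(spectral_tic: np.ndarray, elemental: ElementalStack) -> np.ndarray:
    """Tissue mask: TIC > 0 and every elemental channel non-missing."""
    tic = np.asarray(spectral_tic, dtype=float)
    if tic.shape != elemental.shape:
        raise DimensionMismatchError(
            f"TIC raster {tic.shape} != elemental grid {elemental.shape}"
        )
    mask = tic > 0
    for ch in elemental.channels:
        mask &= np.isfinite(ch.values)
    return mask


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass Pearson r; NaN when undefined (constant input or n < 2)."""
    if x.size < 2:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def pearson_matrix(
    lipid_images: list[IonImage],
    element_stack: ElementalStack,
    mask: np.ndarray,
) -> CorrelationMatrix:
    """Pearson r for every (lipid, element) pair over the mask.

    Per cell, pixels where both channels are present (finite) inside the
    mask are used; the count is recorded in ``n_pixels``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    shape = element_stack.shape
    for ion in lipid_images:
        if ion.values.shape != shape:
            raise DimensionMismatchError(
                f"{ion.label}: shape {ion.values.shape} != elemental grid {shape}"
            )
    if mask.shape != shape:
        raise DimensionMismatchError("mask shape mismatch")

    nrow, ncol = len(lipid_images), len(element_stack.channels)
    r = np.full((nrow, ncol), np.nan)
    n = np.zeros((nrow, ncol), dtype=int)
    for i, ion in enumerate(lipid_images):
        li = ion.values
        for j, ch in enumerate(element_stack.channels):
            ok = mask & np.isfinite(li) & np.isfinite(ch.values)
            n[i, j] = int(ok.sum())
            if n[i, j] >= 2:
                r[i, j] = _pearson(li[ok], ch.values[ok])
    return CorrelationMatrix(
        row_labels=[ion.label for ion in lipid_images],
        col_labels=element_stack.labels,
        r=r,
        n_pixels=n,
        mask_size=int(mask.sum()),
    )


def composite_overlay(
    a: np.ndarray,
    b: np.ndarray,
    palette: str = "magenta_cyan",
    mask: np.ndarray | None = None,
    clip_q: float = 0.99,
) -> np.ndarray:
    """Two-channel additive false-colour composite, (h, w, 3) in [0, 1].

    Each channel is independently clipped at its own ``clip_q`` quantile
    (of nonzero values), rescaled to [0, 1], tinted with the palette's
    colour and additively blended; masked-out pixels are black. Where
    both channels saturate the colours add toward white.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"composite inputs differ in shape: {a.shape} vs {b.shape}")
    if palette not in PALETTES:
        raise ValueError(f"unknown palette {palette!r}; choose from {sorted(PALETTES)}")
    ca, cb = PALETTES[palette]

    def scaled(v: np.ndarray) -> np.ndarray:
        img = IonImage(target_mz=1.0, tolerance_ppm=1.0, values=np.nan_to_num(v, nan=0.0))
        clipped = quantile_hotspot_clip(img, q=clip_q).values
        top = clipped.max()
        return clipped / top if top > 0 else clipped

    sa, sb = scaled(a), scaled(b)
    rgb = sa[..., None] * ca + sb[..., None] * cb
    rgb = np.clip(rgb, 0.0, 1.0)
    if mask is not None:
        if mask.shape != a.shape:
            raise DimensionMismatchError("mask shape mismatch")
        rgb[~np.asarray(mask, dtype=bool)] = 0.0
    return rgb


def export_heatmap(cm: CorrelationMatrix, base_path: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.csv`` (undefined cells as "NA") and ``<base>.png``
    (diverging colour scale centered at 0). Returns both paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    png_path = base.with_suffix(".png")

    df = pd.DataFrame(cm.r, index=cm.row_labels, columns=cm.col_labels)
    df.to_csv(csv_path, na_rep="NA", float_format="%.6f")

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * len(cm.col_labels), 1.0 + 0.5 * len(cm.row_labels))
    )
    im = ax.imshow(cm.r, cmap="RdBu_r", vmin=-1.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(len(cm.col_labels)), cm.col_labels, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.row_labels)), cm.row_labels)
    for i in range(cm.r.shape[0]):
        for j in range(cm.r.shape[1]):
            v = cm.r[i, j]
            ax.text(
                j, i, "NA" if not np.isfinite(v) else f"{v:.2f}",
                ha="center", va="center", fontsize=7,
            )
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return csv_path, png_path


def read_heatmap_csv(path: str | Path) -> CorrelationMatrix:
    """Parse a heatmap CSV back into a (coefficients-only) matrix."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    return CorrelationMatrix(
        row_labels=[str(r) for r in df.index],
        col_labels=[str(c) for c in df.columns],
        r=df.to_numpy(dtype=float),
        n_pixels=np.zeros(df.shape, dtype=int),
    )
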