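"""Feature-vector to 2D-barcode encoding.

A sample's expression vector (QC ratios, one per glycopeptide feature) is laid
out on a small grid — either in elution-time order (rt layout, a
structure-free control) or by principal-component loadings (pca layout, which
places co-expressed features in the same column) — and each cell's brightness
encodes the expression ratio on a symmetric log2 scale. Optionally the serum
tumor markers CA125 and HE4 attenuate the red and green channels, so
high-marker samples render blue-shifted. The grid is upscaled with
nearest-neighbor interpolation to a square raster a CNN can consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .peaks import FeatureMatrix

#: Study-default grid: 41 columns x 42 rows = 1722 cells, 10 blanks for 1712 features.
DEFAULT_NCOLS = 41
DEFAULT_NROWS = 42
DEFAULT_IMAGE_SIDE = 227

#: Clinical reference points for the marker color transform.
CA125_REF = 35.0  # U/mL
HE4_REF = 70.0  # pmol/L
MARKER_SCALE = 2.0


@dataclass(frozen=True)
class GridSpec:
    ncols: int = DEFAULT_NCOLS
    nrows: int = DEFAULT_NROWS

    @property
    def capacity(self) -> int:
        return self.ncols * self.nrows

    def blanks(self, n_features: int) -> int:
        return self.capacity - n_features

    @classmethod
    def for_n_features(cls, n: int) -> "GridSpec":
        """Grid for arbitrary n: nrows = ceil(sqrt(n)), ncols = ceil(n / nrows)."""
        if n == 1712:
            return cls()
        nrows = math.ceil(math.sqrt(n))
        ncols = math.ceil(n / nrows)
        return cls(ncols=ncols, nrows=nrows)


@dataclass
class BarcodeLayout:
    """Injective map feature index -> (column, row) grid cell."""

    grid: GridSpec
    cell_of: dict[int, tuple[int, int]]
    method: str  # "rt" or "pca"

    def __post_init__(self) -> None:
        cells = list(self.cell_of.values())
        if len(set(cells)) != len(cells):
            raise ValueError("layout is not injective")
        for c, r in cells:
            if not (0 <= c < self.grid.ncols and 0 <= r < self.grid.nrows):
                raise ValueError(f"cell ({c}, {r}) outside grid")

    @property
    def n_features(self) -> int:
        return len(self.cell_of)

    def blank_cells(self) -> set[tuple[int, int]]:
        assigned = set(self.cell_of.values())
        return {
            (c, r)
            for c in range(self.grid.ncols)
            for r in range(self.grid.nrows)
            if (c, r) not in assigned
        }

    def to_frame(self, feature_ids: Sequence[str] | None = None) -> pd.DataFrame:
        rows = []
        for k in sorted(self.cell_of):
            c, r = self.cell_of[k]
            fid = feature_ids[k] if feature_ids is not None else k
            rows.append({"feature_id": fid, "column": c, "row": r})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MarkerPanel:
    """Serum tumor marker values: CA125 in U/mL, HE4 in pmol/L."""

    ca125: float
    he4: float

    def __post_init__(self) -> None:
        if self.ca125 < 0 or self.he4 < 0:
            raise ValueError("marker values must be non-negative")


@dataclass
class BarcodeImage:
    """ncols x nrows x 3 grid of 8-bit channel values (stored row-major HxWx3)."""

    channels: np.ndarray  # (nrows, ncols, 3) uint8
    grid: GridSpec

    def is_monochrome(self) -> bool:
        ch = self.channels
        return bool(np.all(ch[..., 0] == ch[..., 1]) and np.all(ch[..., 1] == ch[..., 2]))


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

def rt_layout(feature_meta: pd.DataFrame, grid: GridSpec | None = None) -> BarcodeLayout:
    """Place features in elution order, row-major from top-left to bottom-right.

    Features are sorted ascending by retention time (ties by m/z, then feature
    id); the k-th feature occupies column ``k mod ncols``, row ``k div ncols``.
    """
    n = len(feature_meta)
    if grid is None:
        grid = GridSpec.for_n_features(n)
    if n > grid.capacity:
        raise ValueError(f"{n} features exceed grid capacity {grid.capacity}")
    order = np.lexsort(
        (np.arange(n), feature_meta["mz"].to_numpy(), feature_meta["rt"].to_numpy())
    )
    cell_of = {
        int(feat): (k % grid.ncols, k // grid.ncols) for k, feat in enumerate(order)
    }
    return BarcodeLayout(grid=grid, cell_of=cell_of, method="rt")


def _canonicalize_sign(loading: np.ndarray) -> np.ndarray:
    """Fix a component's sign so its largest-|.| loading is positive."""
    i = int(np.argmax(np.abs(loading)))
    return -loading if loading[i] < 0 else loading


def layout_from_loadings(
    l1: np.ndarray, l2: np.ndarray, grid: GridSpec
) -> BarcodeLayout:
    """Grid placement from two per-feature loading vectors.

    Features are sorted ascending by the first loading (ties by feature
    index) and cut into consecutive groups of ``nrows``; within each group
    they are sorted ascending by the second loading. Column = group index,
    row = within-group rank, so blanks trail at the bottom of the last column.
    """
    n = len(l1)
    if n > grid.capacity:
        raise ValueError(f"{n} features exceed grid capacity {grid.capacity}")
    order1 = np.lexsort((np.arange(n), l1))
    cell_of: dict[int, tuple[int, int]] = {}
    for g in range(math.ceil(n / grid.nrows)):
        group = order1[g * grid.nrows : (g + 1) * grid.nrows]
        within = group[np.lexsort((group, l2[group]))]
        for r, feat in enumerate(within):
            cell_of[int(feat)] = (g, r)
    return BarcodeLayout(grid=grid, cell_of=cell_of, method="pca")


def scale_features(values: np.ndarray) -> np.ndarray:
    """Zero-center and unit-variance scale each feature column.

    Zero-variance features are mapped to all-0 rather than left unscaled.
    """
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    out = values - mu
    nz = sd > 0
    out[:, nz] = out[:, nz] / sd[nz]
    out[:, ~nz] = 0.0
    return out


def pca_loadings(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature loadings of the first two principal components.

    The samples x features matrix is unit-variance scaled and zero-centered
    feature-wise, decomposed, and each component's sign canonicalized so the
    largest-|.| loading is positive (reproducible across backends).
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("PCA layout needs >= 2 samples and >= 2 features")
    scaled = scale_features(np.asarray(values, dtype=float))
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(scaled)
    if np.sum(pca.explained_variance_ > 1e-12) < 2:
        raise ValueError(
            "matrix has rank < 2 after scaling; cannot derive two components"
        )
    l1 = _canonicalize_sign(pca.components_[0])
    l2 = _canonicalize_sign(pca.components_[1])
    return l1, l2


def pca_layout(matrix: FeatureMatrix | np.ndarray, grid: GridSpec | None = None) -> BarcodeLayout:
    """Place features by (first-loading group, second-loading rank)."""
    values = matrix.values.to_numpy() if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    if grid is None:
        grid = GridSpec.for_n_features(values.shape[1])
    l1, l2 = pca_loadings(values)
    return layout_from_loadings(l1, l2, grid)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def to_grayscale(
    values: np.ndarray, layout: BarcodeLayout, clip: float = 2.0
) -> BarcodeImage:
    """Map one sample's QC-ratio vector to cell brightness.

    Symmetric log2 map: ratio 1 (sample = QC pool) is mid-gray, ratios at or
    beyond 2**clip render black (strong expression), at or below 2**-clip
    white. Unassigned (blank) cells are white.
    """
    values = np.asarray(values, dtype=float)
    if clip <= 0:
        raise ValueError("clip must be positive")
    if np.any(values < 0):
        raise ValueError("expression ratios must be non-negative")
    if len(values) != layout.n_features:
        raise ValueError("value vector length does not match layout")
    grid = layout.grid
    ch = np.full((grid.nrows, grid.ncols), 255, dtype=float)
    logr = np.clip(np.log2(np.maximum(values, 1e-12)), -clip, clip)
    v = 255.0 * (1.0 - (logr + clip) / (2.0 * clip))
    for k, (c, r) in layout.cell_of.items():
        ch[r, c] = v[k]
    ch8 = _round_half_up(ch).astype(np.uint8)
    return BarcodeImage(channels=np.stack([ch8] * 3, axis=-1), grid=grid)


def marker_attenuation(value: float, ref: float, scale: float = MARKER_SCALE) -> float:
    """Channel attenuation in [0, 1]: 1 at marker 0, decaying as log10(1 + value/ref)/scale."""
    if value < 0:
        raise ValueError("marker value must be non-negative")
    return float(np.clip(1.0 - math.log10(1.0 + value / ref) / scale, 0.0, 1.0))


def colorize(
    image: BarcodeImage,
    markers: MarkerPanel,
    ca125_ref: float = CA125_REF,
    he4_ref: float = HE4_REF,
    scale: float = MARKER_SCALE,
) -> BarcodeImage:
    """Attenuate red by CA125 and green by HE4, leaving blue unchanged.

    Rising CA125 lowers the red level and rising HE4 the green level, so
    high-marker samples (typically EOC) render blue-shifted while low-marker
    samples stay light. Blank cells are white in the monochrome input and so
    carry pure marker color.
    """
    if not image.is_monochrome():
        raise ValueError("colorize expects a monochrome barcode")
    f_r = marker_attenuation(markers.ca125, ca125_ref, scale)
    f_g = marker_attenuation(markers.he4, he4_ref, scale)
    v = image.channels[..., 0].astype(float)
    out = np.stack(
        [
            _round_half_up(v * f_r),
            _round_half_up(v * f_g),
            v,
        ],
        axis=-1,
    ).astype(np.uint8)
    return BarcodeImage(channels=out, grid=image.grid)


def render(image: BarcodeImage, side: int = DEFAULT_IMAGE_SIDE) -> np.ndarray:
    """Nearest-neighbor upscale of the channel grid to a side x side raster."""
    grid = image.grid
    if side < max(grid.ncols, grid.nrows):
        raise ValueError("raster side smaller than the grid")
    pil = Image.fromarray(image.channels, mode="RGB")
    big = pil.resize((side, side), resample=Image.NEAREST)
    return np.asarray(big)


def save_png(image: BarcodeImage, path: str | Path, side: int = DEFAULT_IMAGE_SIDE) -> None:
    Image.fromarray(render(image, side), mode="RGB").save(path, format="PNG")


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class BarcodeEncoder(BaseEstimator, TransformerMixin):
    """Transformer from expression matrices to barcode rasters.

    Parameters
    ----------
    layout : {"pca", "rt"}
        Feature placement: principal-component loadings (co-expressed
        features adjacent) or elution-time order (control).
    color : {"mono", "multicolor"}
        Grayscale expression only, or with CA125/HE4 marker coloring.
    ncols, nrows : int or None
        Grid dimensions; derived from the feature count when None.
    clip : float
        Half-width of the log2 brightness window (ratios beyond 2**clip
        saturate).
    image_side : int
        Side of the rendered square raster in pixels.

    The layout is learned from the matrix passed to :meth:`fit` (the study
    derived its PCA placement from the full cohort, labels unseen) and reused
    for every matrix passed to :meth:`transform`.
    """

    def __init__(
        self,
        layout: str = "pca",
        color: str = "mono",
        ncols: int | None = None,
        nrows: int | None = None,
        clip: float = 2.0,
        ca125_ref: float = CA125_REF,
        he4_ref: float = HE4_REF,
        marker_scale: float = MARKER_SCALE,
        image_side: int = DEFAULT_IMAGE_SIDE,
    ):
        self.layout = layout
        self.color = color
        self.ncols = ncols
        self.nrows = nrows
        self.clip = clip
        self.ca125_ref = ca125_ref
        self.he4_ref = he4_ref
        self.marker_scale = marker_scale
        self.image_side = image_side

    def _grid(self, n_features: int) -> GridSpec:
        if self.ncols is not None and self.nrows is not None:
            return GridSpec(ncols=self.ncols, nrows=self.nrows)
        return GridSpec.for_n_features(n_features)

    @staticmethod
    def _values(X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            return X.values.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y=None, feature_meta: pd.DataFrame | None = None):
        if self.layout not in ("pca", "rt"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.color not in ("mono", "multicolor"):
            raise ValueError(f"unknown color mode {self.color!r}")
        values = self._values(X)
        grid = self._grid(values.shape[1])
        if self.layout == "rt":
            if feature_meta is None:
                if isinstance(X, FeatureMatrix):
                    feature_meta = X.feature_meta
                else:
                    raise ValueError("rt layout requires feature_meta with rt/mz")
            self.layout_ = rt_layout(feature_meta, grid)
        else:
            self.layout_ = pca_layout(values, grid)
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X, markers: Sequence[MarkerPanel] | pd.DataFrame | None = None) -> np.ndarray:
        """Encode samples to rasters, shape (n_samples, image_side, image_side, 3)."""
        if not hasattr(self, "layout_"):
            raise ValueError("BarcodeEncoder is not fitted")
        values = self._values(X)
        if values.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        panels = self._marker_panels(markers, values.shape[0])
        out = np.empty((values.shape[0], self.image_side, self.image_side, 3), dtype=np.uint8)
        for i in range(values.shape[0]):
            img = to_grayscale(values[i], self.layout_, clip=self.clip)
            if self.color == "multicolor":
                img = colorize(
                    img, panels[i], self.ca125_ref, self.he4_ref, self.marker_scale
                )
            out[i] = render(img, self.image_side)
        return out

    def _marker_panels(self, markers, n: int) -> list[MarkerPanel]:
        if self.color == "mono":
            return [MarkerPanel(0.0, 0.0)] * n
        if markers is None:
            raise ValueError("multicolor encoding requires CA125/HE4 marker values")
        if isinstance(markers, pd.DataFrame):
            panels = [
                MarkerPanel(float(r["ca125"]), float(r["he4"])) for _, r in markers.iterrows()
            ]
        else:
            panels = [
                m if isinstance(m, MarkerPanel) else MarkerPanel(float(m[0]), float(m[1]))
                for m in markers
            ]
        if len(panels) != n:
            raise ValueError("marker panel count does not match sample count")
        return panels
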