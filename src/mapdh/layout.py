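"""Image-to-layout compilation for multi-domain photopatterning.

A pixel-art image is turned into per-ink patterning instructions in four
steps: (1) bin the raster image down to an ``n x n`` grid of mean colors,
(2) cluster the cell colors with k-means in RGB space, (3) emit one binary
*location map* per cluster (the grid cells each ink domain occupies), and
(4) map the 1-cells of each location map onto micrometer stage coordinates.

Hand-specified layouts — such as a strip of adjacent square domains with
deliberately overlapping borders — are built directly with
:func:`make_strip_layout`.

Conventions: the coordinate origin is the top-left corner of the field,
x increases rightward and y downward (image convention), all stage
coordinates are micrometers, and grid indices are 0-based row-major.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from sklearn.cluster import KMeans

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "ColorClustering",
    "DomainLayout",
    "LayoutSite",
    "LocationGrid",
    "bin_image",
    "build_location_maps",
    "cluster_colors",
    "grids_to_layout",
    "load_image",
    "make_strip_layout",
]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an ``(H, W, 3)`` uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def _as_rgb_array(img: np.ndarray, what: str = "image") -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"{what} must have shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidInputError(f"{what} is empty: shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError(f"{what} channel values must lie in [0, 255]")
    return arr


def bin_image(img: np.ndarray, n: int) -> np.ndarray:
    """Downsample an RGB image to an ``n x n`` grid of block-mean colors.

    The image is tiled into ``n x n`` rectangular blocks of ``H // n`` by
    ``W // n`` pixels; remainder rows/columns (when ``H`` or ``W`` is not a
    multiple of ``n``) are folded into the final row/column of blocks. Each
    cell color is the per-channel arithmetic mean of its block, rounded to
    the nearest integer.

    Parameters
    ----------
    img : (H, W, 3) uint8 array
    n : grid side length in cells; must satisfy ``n <= min(H, W)``.

    Returns
    -------
    (n, n, 3) uint8 array of cell colors.
    """
    arr = _as_rgb_array(img)
    h, w = arr.shape[:2]
    if n < 1 or n > min(h, w):
        raise InvalidParameterError(
            f"grid side {n} must satisfy 1 <= n <= min(H, W) = {min(h, w)}"
        )
    row_edges = [i * (h // n) for i in range(n)] + [h]
    col_edges = [j * (w // n) for j in range(n)] + [w]
    out = np.empty((n, n, 3), dtype=np.uint8)
    flt = arr.astype(np.float64)
    for i in range(n):
        for j in range(n):
            block = flt[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            out[i, j] = np.rint(block.mean(axis=(0, 1)))
    return out


@dataclass(frozen=True)
class ColorClustering:
    """Result of k-means color quantization of a binned grid.

    Attributes
    ----------
    k : number of (non-degenerate) clusters actually produced.
    centroids : (k, 3) float array of RGB cluster centers.
    assignment : (n, n) int array of cluster indices in ``[0, k)``.
    """

    k: int
    centroids: np.ndarray
    assignment: np.ndarray

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment.ravel(), minlength=self.k)


def cluster_colors(grid: np.ndarray, k: int, seed: int = 0) -> ColorClustering:
    """Cluster the cell colors of a binned grid with seeded k-means.

    Uses k-means++ initialization with up to 50 restarts; for a fixed
    ``(grid, k, seed)`` the result is deterministic. If ``k`` exceeds the
    number of distinct cell colors the degenerate clusters are collapsed
    (fewer clusters are returned) and a warning is emitted.
    """
    arr = _as_rgb_array(grid, "grid")
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    pixels = arr.reshape(-1, 3).astype(np.float64)
    if k > pixels.shape[0]:
        raise InvalidParameterError(
            f"k={k} exceeds the number of cells {pixels.shape[0]}"
        )
    n_distinct = np.unique(pixels, axis=0).shape[0]
    k_eff = min(k, n_distinct)
    if k_eff < k:
        warnings.warn(
            f"k={k} exceeds the {n_distinct} distinct cell colors; "
            f"collapsed to {k_eff} clusters",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=50, random_state=seed)
    labels = km.fit_predict(pixels)
    return ColorClustering(
        k=k_eff,
        centroids=km.cluster_centers_.copy(),
        assignment=labels.reshape(arr.shape[:2]).astype(np.intp),
    )


@dataclass(frozen=True)
class LocationGrid:
    """Binary occupancy matrix for one ink domain (a "location map").

    ``mask[i, j] == 1`` means grid cell ``(i, j)`` is patterned with this
    domain's ink. Across all maps from one clustering the masks partition
    the grid: their elementwise sum is 1 everywhere.
    """

    mask: np.ndarray
    domain_id: int
    label_color: tuple[int, int, int]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or not np.isin(m, (0, 1)).all():
            raise InvalidInputError("location map must be a 2D binary matrix")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def save_png(self, path: str | Path) -> None:
        """Write the map as a 1-bit PNG (on-cells white)."""
        Image.fromarray((self.mask * 255).astype(np.uint8)).convert("1").save(path)

    def to_json_dict(self) -> dict:
        return {
            "domain_id": self.domain_id,
            "label_color": list(self.label_color),
            "mask": self.mask.astype(int).tolist(),
        }


def build_location_maps(clustering: ColorClustering) -> list[LocationGrid]:
    """Split a clustering into one binary location map per cluster.

    Maps are ordered by descending cell count (the largest domain becomes
    domain 0 / ink 1), ties broken by cluster index, and together they
    partition the grid.
    """
    sizes = clustering.cluster_sizes()
    order = sorted(range(clustering.k), key=lambda c: (-int(sizes[c]), c))
    maps = []
    for domain_id, c in enumerate(order):
        mask = (clustering.assignment == c).astype(np.uint8)
        color = tuple(int(round(v)) for v in np.clip(clustering.centroids[c], 0, 255))
        maps.append(LocationGrid(mask=mask, domain_id=domain_id, label_color=color))
    return maps


@dataclass(frozen=True)
class LayoutSite:
    """One patterning site: a domain footprint centered at stage coordinates."""

    domain_id: int
    center_x_um: float
    center_y_um: float
    width_um: float
    height_um: float
    shape: str = "rect"


@dataclass
class DomainLayout:
    """Micrometer-space arrangement of patterning sites for each domain."""

    sites: list[LayoutSite] = field(default_factory=list)
    pitch_um: float = 0.0
    overlap_um: float = 0.0

    @property
    def domain_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for s in self.sites:
            seen.setdefault(s.domain_id, None)
        return list(seen)

    def sites_of(self, domain_id: int) -> list[LayoutSite]:
        return [s for s in self.sites if s.domain_id == domain_id]

    def to_json_dict(self) -> dict:
        return {
            "units": "um",
            "pitch_um": self.pitch_um,
            "overlap_um": self.overlap_um,
            "sites": [
                {
                    "domain_id": s.domain_id,
                    "center_x_um": s.center_x_um,
                    "center_y_um": s.center_y_um,
                    "width_um": s.width_um,
                    "height_um": s.height_um,
                    "shape": s.shape,
                }
                for s in self.sites
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def from_json_dict(cls, d: dict) -> "DomainLayout":
        sites = [
            LayoutSite(
                domain_id=int(s["domain_id"]),
                center_x_um=float(s["center_x_um"]),
                center_y_um=float(s["center_y_um"]),
                width_um=float(s["width_um"]),
                height_um=float(s["height_um"]),
                shape=s.get("shape", "rect"),
            )
            for s in d["sites"]
        ]
        return cls(
            sites=sites,
            pitch_um=float(d.get("pitch_um", 0.0)),
            overlap_um=float(d.get("overlap_um", 0.0)),
        )


def grids_to_layout(
    maps: list[LocationGrid],
    post_size_um: float,
    pitch_um: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> DomainLayout:
    """Convert location maps into stage coordinates for pixel-art patterning.

    Each 1-cell ``(i, j)`` becomes a square site of side ``post_size_um``
    centered at ``origin + (j * pitch, i * pitch)``. Sites are grouped by
    domain id and ordered row-major within each domain. ``pitch >=
    post_size`` is required so pixel-art posts do not unintentionally
    overlap.
    """
    if post_size_um <= 0 or pitch_um <= 0:
        raise InvalidParameterError("post size and pitch must be positive")
    if pitch_um < post_size_um:
        raise InvalidParameterError(
            f"pitch {pitch_um} um must be >= post size {post_size_um} um"
        )
    ox, oy = origin_um
    sites = []
    for grid in sorted(maps, key=lambda g: g.domain_id):
        for i, j in np.argwhere(grid.mask == 1):
            sites.append(
                LayoutSite(
                    domain_id=grid.domain_id,
                    center_x_um=ox + float(j) * pitch_um,
                    center_y_um=oy + float(i) * pitch_um,
                    width_um=post_size_um,
                    height_um=post_size_um,
                )
            )
    return DomainLayout(sites=sites, pitch_um=pitch_um, overlap_um=0.0)


def make_strip_layout(n_domains: int, size_um: float, overlap_um: float) -> DomainLayout:
    """Lay out adjacent square domains in a horizontal strip.

    Domain ``i`` is centered at ``x = i * (size - overlap)`` so that
    consecutive footprints intersect in a vertical strip of width exactly
    ``overlap_um``; with zero overlap the domains abut.
    """
    if n_domains < 1:
        raise InvalidParameterError("n_domains must be >= 1")
    if size_um <= 0:
        raise InvalidParameterError("size must be positive")
    if not 0 <= overlap_um < size_um:
        raise InvalidParameterError(
            f"overlap {overlap_um} um must satisfy 0 <= overlap < size {size_um} um"
        )
    step = size_um - overlap_um
    sites = [
        LayoutSite(
            domain_id=i,
            center_x_um=i * step,
            center_y_um=0.0,
            width_um=size_um,
            height_um=size_um,
        )
        for i in range(n_domains)
    ]
    return DomainLayout(sites=sites, pitch_um=step, overlap_um=overlap_um)
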