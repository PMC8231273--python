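"""Spatial statistics on ion-intensity rasters.

The procedure quantifying how a drug spreads through a lung section:

1. z-score the section's on-tissue intensities (scale + mean-center);
2. bin pixels into intensity quartiles by rank;
3. group adjacent top-quartile (Q4) pixels into connected components —
   "clumps" — and summarize their number and median size;
4. delineate the tissue border as the alpha hull of the on-tissue pixel
   centers (the heme-positive area) and measure each Q4 pixel's distance to
   that border, binned in 3-mm bands.

A rank correlation between two channels over shared tissue pixels serves as
a colocalization score (drug vs surfactant protein C in consecutive
sections).

All physical quantities are millimetres; pixel ``(x, y)`` has its center at
``(x * pitch, y * pitch)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage, stats
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiLineString, Polygon
from shapely.ops import unary_union

from .ionmap import IonImage, TissueMask

__all__ = [
    "QuartileMap",
    "ClumpSet",
    "BorderCurve",
    "DistanceProfile",
    "zscore_section",
    "quartile_bin",
    "find_clumps",
    "clump_summary",
    "alpha_hull_border",
    "distance_profile",
    "colocalization_score",
]

#: Fig-5-style distance bands from the tissue border, millimetres.
DEFAULT_BIN_EDGES_MM = (0.0, 3.0, 6.0, 9.0, 12.0)


@dataclass
class QuartileMap:
    """Per-pixel quartile labels 1–4 on tissue, 0 elsewhere."""

    labels: np.ndarray  # int8, shape (rows, cols); 0 = off-tissue/missing
    source_section: str = ""

    def pixels_in_quartile(self, q: int) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates with the given label."""
        ys, xs = np.nonzero(self.labels == q)
        return np.column_stack([xs, ys])


@dataclass
class ClumpSet:
    """Disjoint connected components of top-quartile pixels."""

    clumps: list[set[tuple[int, int]]]
    connectivity: str = "8-neighbor"

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clumps]


@dataclass
class BorderCurve:
    """Closed polyline(s) delineating tissue, vertices in mm."""

    rings: list[np.ndarray]  # each (n, 2), closed (first == last vertex)
    alpha_mm: float
    _region: object = field(default=None, repr=False)  # shapely (Multi)Polygon

    @property
    def boundary(self) -> MultiLineString:
        return MultiLineString([r for r in self.rings])

    def total_length_mm(self) -> float:
        return float(self.boundary.length)


@dataclass
class DistanceProfile:
    """Distances of top-quartile pixels from the tissue border, binned."""

    per_pixel_mm: np.ndarray
    bin_edges_mm: tuple[float, ...]
    bin_counts: np.ndarray
    bin_fractions: np.ndarray
    outside_border_count: int = 0  # pixels outside all rings, assigned d=0


def zscore_section(image: IonImage, mask: TissueMask) -> IonImage:
    """Scale and mean-center the on-tissue intensities of one section.

    Uses the on-tissue sample mean and SD (ddof=1 when n > 1); off-tissue
    pixels stay missing.  A constant section has no dispersion to scale by
    and is rejected.
    """
    v = image.values
    sel = mask.on_tissue & np.isfinite(v)
    vals = v[sel]
    if vals.size < 2:
        raise ValueError("z-scoring needs at least 2 on-tissue pixels")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise ValueError("constant section: zero on-tissue standard deviation")
    out = np.full_like(v, np.nan)
    out[sel] = (vals - float(np.mean(vals))) / sd
    return IonImage(out, image.pixel_pitch_um, image.target, image.section_id)


def quartile_bin(image: IonImage, mask: TissueMask) -> QuartileMap:
    """Rank-based quartile labels over on-tissue pixels.

    Pixels are ranked ascending (ties broken by row-major pixel order, so the
    result is deterministic); rank ``r`` of ``n`` gets label ``ceil(4r/n)``.
    Class sizes therefore differ by at most one pixel.  Because the rule is
    rank-based, any strictly monotone transform of the intensities (including
    z-scoring) yields the same map.
    """
    v = image.values
    sel = mask.on_tissue & np.isfinite(v)
    ys, xs = np.nonzero(sel)  # row-major order
    n = ys.size
    if n < 4:
        raise ValueError(f"quartile binning needs >= 4 tissue pixels, got {n}")
    vals = v[ys, xs]
    order = np.argsort(vals, kind="stable")  # stable: ties keep row-major order
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    labels4 = np.ceil(4 * ranks / n).astype(np.int8)
    labels = np.zeros(v.shape, dtype=np.int8)
    labels[ys, xs] = labels4
    return QuartileMap(labels, source_section=image.section_id)


_STRUCTURES = {
    "4-neighbor": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int),
    "8-neighbor": np.ones((3, 3), dtype=int),
}


def find_clumps(qmap: QuartileMap, connectivity: str = "8-neighbor") -> ClumpSet:
    """Connected components of top-quartile pixels ("clumps").

    Singletons count as clumps of size 1; no Q4 pixels yields an empty set.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    binary = qmap.labels == 4
    labeled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    clumps: list[set[tuple[int, int]]] = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(labeled == i)
        clumps.append({(int(x), int(y)) for x, y in zip(xs, ys)})
    return ClumpSet(clumps, connectivity)


def clump_summary(clumps: ClumpSet) -> tuple[int, float | None]:
    """Number of clumps and median clump size in pixels (None if empty)."""
    sizes = clumps.sizes
    if not sizes:
        return 0, None
    return len(sizes), float(np.median(sizes))


def _triangle_circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    p = points[simplices]  # (m, 3, 2)
    a = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    b = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    area2 = np.abs(cross)  # 2 * area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (2 * area2)
    r[area2 == 0] = np.inf  # degenerate slivers never pass the alpha test
    return r


def alpha_hull_border(mask: TissueMask, alpha_mm: float, pixel_pitch_um: float = 400.0) -> BorderCurve:
    """Alpha shape of the on-tissue pixel centers.

    The alpha shape is the union of Delaunay triangles whose circumradius is
    at most ``alpha_mm``; as alpha grows it converges to the convex hull,
    while small alpha lets the outline follow concavities of the lobe.
    Collinear rings are simplified away so hull vertices are exactly the
    extreme points.
    """
    ys, xs = np.nonzero(mask.on_tissue)
    if ys.size < 3:
        raise ValueError("alpha hull needs at least 3 on-tissue pixels")
    pitch_mm = pixel_pitch_um / 1000.0
    points = np.column_stack([xs, ys]).astype(float) * pitch_mm
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError("on-tissue pixel centers are collinear; no area to hull") from exc
    radii = _triangle_circumradii(points, tri.simplices)
    keep = tri.simplices[radii <= alpha_mm]
    if keep.size == 0:
        raise ValueError(
            f"alpha={alpha_mm} mm keeps no triangle; increase alpha "
            f"(pixel pitch is {pitch_mm} mm)"
        )
    triangles = [Polygon(points[s]) for s in keep]
    region = unary_union(triangles).simplify(0)
    polys = [region] if isinstance(region, Polygon) else list(region.geoms)
    rings: list[np.ndarray] = []
    for poly in polys:
        rings.append(np.asarray(poly.exterior.coords))
        for interior in poly.interiors:
            rings.append(np.asarray(interior.coords))
    return BorderCurve(rings=rings, alpha_mm=float(alpha_mm), _region=region)


def distance_profile(
    pixels_xy: np.ndarray,
    border: BorderCurve,
    pixel_pitch_um: float = 400.0,
    bin_edges_mm: tuple[float, ...] = DEFAULT_BIN_EDGES_MM,
) -> DistanceProfile:
    """Distance of each (Q4) pixel center to the nearest border point.

    Distances are Euclidean point-to-polyline, binned into half-open bands
    ``[e0, e1), [e1, e2), ...``; fractions are counts over the total pixel
    count.  Pixels falling outside every ring (possible with small alpha)
    get distance 0 and are tallied separately.
    """
    pixels_xy = np.asarray(pixels_xy, dtype=float).reshape(-1, 2)
    pitch_mm = pixel_pitch_um / 1000.0
    edges = tuple(float(e) for e in bin_edges_mm)
    nbins = len(edges) - 1
    if pixels_xy.shape[0] == 0:
        zero = np.zeros(nbins, dtype=int)
        return DistanceProfile(np.array([]), edges, zero, zero.astype(float), 0)
    centers = shapely.points(pixels_xy * pitch_mm)
    boundary = border.boundary
    d = shapely.distance(centers, boundary)
    outside = 0
    if border._region is not None:
        inside = shapely.covers(border._region, centers)
        outside = int(np.sum(~inside))
        d = np.where(inside, d, 0.0)
    idx = np.digitize(d, edges)  # bin i in 1..nbins means edges[i-1] <= d < edges[i]
    counts = np.array([int(np.sum(idx == i)) for i in range(1, nbins + 1)])
    fractions = counts / pixels_xy.shape[0]
    return DistanceProfile(d, edges, counts, fractions, outside)


def colocalization_score(image_a: IonImage, image_b: IonImage, mask: TissueMask) -> float:
    """Spearman rank correlation of two channels over shared tissue pixels."""
    if image_a.shape != image_b.shape or image_a.shape != mask.shape:
        raise ValueError("images and mask must share one grid")
    a, b = image_a.values, image_b.values
    sel = mask.on_tissue & np.isfinite(a) & np.isfinite(b)
    va, vb = a[sel], b[sel]
    if va.size < 3:
        raise ValueError("colocalization needs >= 3 shared tissue pixels")
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        raise ValueError("constant channel: rank correlation undefined")
    rho = stats.spearmanr(va, vb).statistic
    return float(rho)
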