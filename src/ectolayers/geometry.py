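"""Epithelium mask, relative-depth field, heights and areas.

Every layer metric is expressed in a band coordinate system spanned by the
annotated apical and basal borders: the *relative depth* of a pixel is

    d(p) = D_a(p) / (D_a(p) + D_b(p))

where ``D_a`` and ``D_b`` are Euclidean distances from the pixel center to
the apical and basal polylines.  ``d`` runs from 0 at the apical border
(lumen) to 1 at the basal border (stroma).  The Euclidean (not geodesic)
definition is exact and cheap for band-shaped tissue without folds; folded
tissue is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .imgio import BorderPair

log = logging.getLogger(__name__)

_EPS_ON_LINE = 1e-9  # pixel counts as lying on a polyline below this distance


@dataclass
class EpitheliumMask:
    """Boolean raster of pixels inside the annotated epithelial band."""

    mask: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("epithelium mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class DepthField:
    """Relative depth in [0, 1] on the mask, NaN elsewhere."""

    depth: np.ndarray
    mask: np.ndarray


def _band_polygon(borders: BorderPair) -> Polygon:
    """Closed region bounded by the two polylines and the connecting end caps."""
    ring = np.vstack([borders.apical, borders.basal[::-1]])
    poly = Polygon(ring[:, ::-1])  # shapely is (x=col, y=row)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0:
        raise ValueError("epithelium region is empty or degenerate")
    return poly


def epithelium_mask(image_shape: tuple[int, int], borders: BorderPair) -> EpitheliumMask:
    """Rasterize the band between the borders.

    A pixel belongs to the mask when its center lies in the closed polygon
    bounded by the two polylines and the connecting end segments.  To keep
    the raster half-open in the depth direction (so that stacked bands tile
    without double counting), pixels lying exactly on the deeper of the two
    polylines are excluded; the convention is applied to the geometrically
    lower polyline regardless of labels, so a label swap yields the same
    mask (with a logged warning).
    """
    poly = _band_polygon(borders)
    if np.mean(borders.basal[:, 0]) < np.mean(borders.apical[:, 0]):
        log.warning("basal border lies above apical border; treating labels "
                    "as swapped for rasterization purposes")
    # the polyline with the larger mean row is the exclusive (deeper) side
    if (np.mean(borders.apical[:, 0]), np.mean(borders.apical[:, 1])) <= (
            np.mean(borders.basal[:, 0]), np.mean(borders.basal[:, 1])):
        exclusive = LineString(borders.basal[:, ::-1])
    else:
        exclusive = LineString(borders.apical[:, ::-1])

    rows, cols = image_shape
    minx, miny, maxx, maxy = poly.bounds
    r0, r1 = max(0, int(np.floor(miny))), min(rows - 1, int(np.ceil(maxy)))
    c0, c1 = max(0, int(np.floor(minx))), min(cols - 1, int(np.ceil(maxx)))
    mask = np.zeros(image_shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        raise ValueError("epithelium region lies outside the image")

    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel()).reshape(rr.shape)
    if inside.any():
        pts = shapely.points(np.column_stack([cc.ravel()[inside.ravel()],
                                              rr.ravel()[inside.ravel()]]))
        on_excl = shapely.distance(pts, exclusive) < _EPS_ON_LINE
        inside_flat = inside.ravel().copy()
        idx = np.flatnonzero(inside_flat)
        inside_flat[idx[on_excl]] = False
        inside = inside_flat.reshape(rr.shape)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    if not mask.any():
        raise ValueError("epithelium region rasterized to an empty mask")
    return EpitheliumMask(mask=mask, um_per_px=borders.um_per_px)


def depth_field(mask: EpitheliumMask, borders: BorderPair) -> DepthField:
    """Relative depth d = D_a / (D_a + D_b) at every mask pixel."""
    rr, cc = np.nonzero(mask.mask)
    pts = shapely.points(np.column_stack([cc, rr]).astype(float))
    d_a = shapely.distance(pts, borders.apical_line())
    d_b = shapely.distance(pts, borders.basal_line())
    denom = d_a + d_b
    if np.any(denom == 0):
        raise ValueError("pixel equidistant-zero from both borders "
                         "(borders touch inside the mask)")
    depth = np.full(mask.shape, np.nan)
    depth[rr, cc] = d_a / denom
    return DepthField(depth=depth, mask=mask.mask)


def _probe_points_and_normals(borders: BorderPair, n_probes: int):
    """Sample points along the apical polyline with outward (basal-ward) normals."""
    line = borders.apical_line()
    length = line.length
    s = (np.arange(n_probes) + 0.5) / n_probes * length
    ds = max(length * 1e-4, 1e-9)
    pts = np.array([[p.x, p.y] for p in (line.interpolate(v) for v in s)])
    ahead = np.array([[p.x, p.y] for p in (line.interpolate(min(v + ds, length)) for v in s)])
    behind = np.array([[p.x, p.y] for p in (line.interpolate(max(v - ds, 0.0)) for v in s)])
    tang = ahead - behind
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    norm /= np.linalg.norm(norm, axis=1, keepdims=True)
    # orient normals toward the basal side
    basal_c = np.array(borders.basal_line().centroid.coords[0])
    flip = np.einsum("ij,ij->i", norm, basal_c - pts) < 0
    norm[flip] *= -1
    return pts, norm


def total_height_um(mask: EpitheliumMask, borders: BorderPair,
                    n_probes: int = 200) -> float:
    """Mean epithelial thickness along normal probes from the apical border.

    For each of ``n_probes`` arc-length-uniform sample points on the apical
    polyline, a ray is cast along the local normal; the distance to its first
    intersection with the basal polyline is one thickness sample.  Probes
    whose normal never meets the basal polyline are skipped; more than 50 %
    skipped is an error.
    """
    if n_probes < 10:
        raise ValueError("n_probes must be >= 10")
    heights = _probe_heights_px(mask, borders, n_probes)
    return float(np.mean(heights) * borders.um_per_px)


def _probe_heights_px(mask: EpitheliumMask, borders: BorderPair,
                      n_probes: int) -> np.ndarray:
    pts, norm = _probe_points_and_normals(borders, n_probes)
    basal = borders.basal_line()
    reach = 4.0 * (basal.length + borders.apical_line().length) + 10.0
    heights = []
    for p, n in zip(pts, norm):
        ray = LineString([p, p + n * reach])
        hit = ray.intersection(basal)
        if hit.is_empty:
            continue
        d = shapely.distance(shapely.points(p), hit)
        heights.append(float(d))
    if len(heights) < 0.5 * n_probes:
        raise ValueError(f"only {len(heights)}/{n_probes} normal probes hit "
                         "the basal border")
    return np.asarray(heights)


def area_um2(mask: EpitheliumMask) -> float:
    """Total epithelial area: pixel count times the pixel area."""
    return float(mask.area_px() * mask.um_per_px ** 2)
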