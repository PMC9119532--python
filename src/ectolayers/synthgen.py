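"""Synthetic multiplex immunofluorescence scenes of stratified squamous epithelium.

The generator builds a band-shaped epithelium between a sinusoidally
undulating apical border and a parallel basal border, and paints channels
that emulate the staining structure of ectocervical tissue sections:

* ``ecadherin`` — a Voronoi mesh ("net") around epithelial cells that is
  absent in the superficial zone, fragmented (edges deleted independently
  with probability ``broken_fraction_upper``) in the upper intermediate
  zone, and closed from the lower intermediate zone down.
* ``nuclei`` — Gaussian nuclear spots, Poisson-placed with a high density
  in the parabasal zone and a low density elsewhere.
* ``dsg1`` / ``cldn1`` — a uniform marker-positive band over a configured
  relative-depth interval (desmoglein-1 / claudin-1 style mid-band).
* ``cd4`` — bright disk-shaped spots with a controllable per-layer depth
  distribution.

Noise is additive Gaussian followed by Poisson resampling (scaled by
``poisson_scale``), clipped at zero — a standard fluorescence noise model.
Every scene is reproducible from its integer seed; channel sub-streams are
derived deterministically so toggling one channel never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Polygon
from scipy.ndimage import binary_dilation
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from . import geometry
from .imgio import BorderPair, MultiplexImage, write_borders, write_multiplex_tiff

LAYER_NAMES = ("superficial", "upper_im", "lower_im", "parabasal")

# fixed rendering constants (documented in docs/methods.md)
MESH_LINE_WIDTH_UM = 1.6     # drawn width of a junction-mesh edge
NUCLEUS_DIAMETER_UM = 6.0    # nominal nucleus size
NUCLEUS_INTENSITY = 10_000.0
CD4_SPOT_RADIUS_UM = 3.5     # CD4+ cell footprint radius
CD4_INTENSITY = 9_000.0

_STREAMS = {"borders": 0, "ecadherin": 1, "nuclei": 2, "cd4": 3,
            "dsg1": 4, "cldn1": 5, "noise": 6}


@dataclass
class MarkerBand:
    """A marker-positive mid-band: name, relative-depth interval, mean intensity."""

    name: str
    depth_lo: float
    depth_hi: float
    intensity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth_lo < self.depth_hi <= 1.0):
            raise ValueError("marker band needs 0 <= depth_lo < depth_hi <= 1")
        if self.intensity < 0:
            raise ValueError("marker intensity must be >= 0")


@dataclass
class SceneParams:
    """Complete description of one synthetic scene."""

    image_size_px: tuple[int, int] = (512, 512)
    um_per_px: float = 0.8
    total_height_um: float = 300.0
    #: (superficial, upper IM, lower IM, parabasal) fractions, sum to 1
    layer_fracs: tuple[float, float, float, float] = (0.23, 71 / 300, 100 / 300, 0.20)
    mesh_cell_diameter_um: float = 15.0
    broken_fraction_upper: float = 0.50
    ecad_intensity: float = 8000.0
    marker_band: MarkerBand | None = None
    nucleus_density_parabasal: float = 12.0   # spots per 1000 um^2
    nucleus_density_other: float = 1.5
    cd4_count: int = 150
    cd4_depth_weights: tuple[float, float, float, float] = (0.0, 0.10, 0.44, 0.46)
    noise: tuple[float, float] = (150.0, 0.05)  # (gaussian_sd, poisson_scale)
    curvature_amp_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.layer_fracs, dtype=float)
        if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("layer_fracs must be four non-negatives summing to 1")
        for name in ("um_per_px", "total_height_um", "mesh_cell_diameter_um"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real")
        if not 0.0 <= self.broken_fraction_upper <= 1.0:
            raise ValueError("broken_fraction_upper must lie in [0, 1]")
        for name in ("ecad_intensity", "nucleus_density_parabasal",
                     "nucleus_density_other", "curvature_amp_um"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative finite real")
        if self.cd4_count < 0:
            raise ValueError("cd4_count must be >= 0")
        w = np.asarray(self.cd4_depth_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or (self.cd4_count > 0 and w.sum() == 0):
            raise ValueError("cd4_depth_weights must be four non-negative reals")
        if len(self.noise) != 2 or any(not np.isfinite(v) or v < 0 for v in self.noise):
            raise ValueError("noise must be (gaussian_sd >= 0, poisson_scale >= 0)")

    @property
    def boundary_depths(self) -> tuple[float, float, float]:
        """Cumulative layer fractions (b1, b2, b3)."""
        c = np.cumsum(self.layer_fracs)
        return (float(c[0]), float(c[1]), float(c[2]))

    def channel_names(self) -> list[str]:
        names = ["nuclei", "ecadherin", "cd4"]
        if self.marker_band is not None:
            names.append(self.marker_band.name)
        return names


class VectorMesh:
    """The generator's junction mesh in vector form, kept for oracle checks.

    Attributes
    ----------
    sites : (n, 2) float array of Voronoi site coordinates, (row, col).
    edges : list of ((r0, c0), (r1, c1)) finite ridge segments.
    kept : boolean array, False where the edge was deleted ("broken net").
    region_polys : per-site shapely Polygon (None for unbounded regions).
    region_closed : per-site bool, True when all of the region's edges were kept.
    """

    def __init__(self, sites, edges, kept, site_edges, region_polys):
        self.sites = sites
        self.edges = edges
        self.kept = kept
        self._site_edges = site_edges
        self.region_polys = region_polys
        # -1 entries mark ridges with no drawn counterpart (unbounded, out of
        # band, or superficial): such regions are open by construction
        self.region_closed = np.array([
            bool(site_edges[i]) and all(e >= 0 and kept[e] for e in site_edges[i])
            for i in range(len(sites))
        ])


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the analysis pipeline."""

    params: SceneParams
    apical_polyline: np.ndarray
    basal_polyline: np.ndarray
    layer_boundary_depths: tuple[float, float, float]
    true_layer_thickness_um: tuple[float, float, float, float]
    true_ecad_coverage_pct_by_layer: dict[str, float]
    true_band_mfi: float | None
    cd4_positions: list[tuple[float, float, str]]
    nucleus_positions: list[tuple[float, float]] = field(default_factory=list)
    mesh: VectorMesh | None = None

    def __post_init__(self) -> None:
        tot = sum(self.true_layer_thickness_um)
        if abs(tot - self.params.total_height_um) > 1e-6:
            raise ValueError("layer thicknesses do not sum to total height")
        for v in self.true_ecad_coverage_pct_by_layer.values():
            if not 0.0 <= v <= 100.0:
                raise ValueError("coverage out of [0, 100]")


def scenario_params(name: str, seed: int = 0) -> SceneParams:
    """Deterministic scene parameters for the two study-arm-like scenarios.

    ``control_like`` mirrors the no-hormonal-contraception arm: superficial
    69 um, upper IM 71 um, total 300 um, a moderately fragmented upper net
    and a desmoglein-1-style band at 10e3 AU.  ``dmpa_like`` mirrors the
    DMPA arm: superficial 36 um, upper IM 86 um, total 297 um, a strongly
    fragmented upper net, a dimmer band (ratio 6:10) and a more apical CD4
    distribution.  Lower-IM and parabasal heights are free choices (the
    study reports only group totals and the two upper layers); they are
    fixed at 100/60 um (control) and 110/65 um (DMPA).
    """
    if name == "control_like":
        thick = (69.0, 71.0, 100.0, 60.0)
        return SceneParams(
            total_height_um=sum(thick),
            layer_fracs=tuple(t / sum(thick) for t in thick),
            broken_fraction_upper=0.50,
            marker_band=MarkerBand("dsg1", 0.51, 0.93, 10_000.0),
            cd4_depth_weights=(0.0, 0.10, 0.44, 0.46),
            seed=seed,
        )
    if name == "dmpa_like":
        thick = (36.0, 86.0, 110.0, 65.0)
        return SceneParams(
            total_height_um=sum(thick),
            layer_fracs=tuple(t / sum(thick) for t in thick),
            broken_fraction_upper=0.65,
            marker_band=MarkerBand("dsg1", 0.40, 0.96, 6_000.0),
            cd4_depth_weights=(0.0, 0.18, 0.34, 0.48),
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}; expected 'control_like' or 'dmpa_like'")


def _rng(params: SceneParams, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, _STREAMS[stream]]))


def _make_borders(params: SceneParams) -> BorderPair:
    rows, cols = params.image_size_px
    h_px = params.total_height_um / params.um_per_px
    amp_px = params.curvature_amp_um / params.um_per_px
    r0 = (rows - h_px) / 2.0
    if r0 - amp_px < 1.0 or r0 + h_px + amp_px > rows - 2.0:
        raise ValueError(
            f"image of {rows} rows cannot hold a {params.total_height_um} um band "
            f"at {params.um_per_px} um/px (needs ~{h_px + 2 * amp_px + 4:.0f} rows)")
    phase = float(_rng(params, "borders").uniform(0, 2 * math.pi))
    cs = np.linspace(0.0, cols - 1.0, max(2, cols // 8))
    k = 2 * math.pi / cols
    ra = r0 + amp_px * np.sin(k * cs + phase)
    slope = amp_px * k * np.cos(k * cs + phase)
    # unit normal pointing toward larger row (basal side)
    nn = np.column_stack([np.ones_like(slope), -slope])
    nn /= np.linalg.norm(nn, axis=1, keepdims=True)
    apical = np.column_stack([ra, cs])
    basal = apical + h_px * nn
    return BorderPair(apical=apical, basal=basal, um_per_px=params.um_per_px)


def _point_depths(points_rc: np.ndarray, borders: BorderPair) -> np.ndarray:
    pts = shapely.points(points_rc[:, ::-1])
    d_a = shapely.distance(pts, borders.apical_line())
    d_b = shapely.distance(pts, borders.basal_line())
    return d_a / (d_a + d_b)


def _build_mesh(params: SceneParams, borders: BorderPair,
                band_poly: Polygon) -> VectorMesh:
    rng = _rng(params, "ecadherin")
    cell_d_px = params.mesh_cell_diameter_um / params.um_per_px
    density = 1.0 / (math.pi * (cell_d_px / 2.0) ** 2)  # sites per px^2
    minx, miny, maxx, maxy = band_poly.bounds
    pad = 2.0 * cell_d_px
    lo = np.array([miny - pad, minx - pad])   # (row, col)
    hi = np.array([maxy + pad, maxx + pad])
    area = float(np.prod(hi - lo))
    n_sites = max(8, rng.poisson(density * area))
    sites = rng.uniform(lo, hi, size=(n_sites, 2))
    vor = Voronoi(sites[:, ::-1])  # (x=col, y=row)

    b1, b2, _ = params.boundary_depths
    edges: list[tuple[tuple[float, float], tuple[float, float]]] = []
    kept_flags: list[bool] = []
    site_edges: dict[int, list[int]] = {i: [] for i in range(n_sites)}
    mids = []
    finite_ridges = []
    for (p1, p2), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in verts:
            # unbounded ridge: mark both regions open
            site_edges[p1].append(-1)
            site_edges[p2].append(-1)
            continue
        v0 = vor.vertices[verts[0]][::-1]  # back to (row, col)
        v1 = vor.vertices[verts[1]][::-1]
        finite_ridges.append((p1, p2, tuple(v0), tuple(v1)))
        mids.append((v0 + v1) / 2.0)
    mids = np.asarray(mids) if mids else np.empty((0, 2))
    if len(mids):
        in_band = shapely.intersects_xy(
            band_poly, mids[:, 1], mids[:, 0])
        depths = _point_depths(mids, borders)
    else:
        in_band = np.zeros(0, dtype=bool)
        depths = np.zeros(0)

    deletion = rng.uniform(size=len(mids))
    for i, (p1, p2, v0, v1) in enumerate(finite_ridges):
        if not in_band[i] or depths[i] < b1:
            # superficial zone / outside band: no mesh; the adjoining cells
            # are open on this side
            site_edges[p1].append(-1)
            site_edges[p2].append(-1)
            continue
        kept = not (depths[i] < b2 and deletion[i] < params.broken_fraction_upper)
        eid = len(edges)
        edges.append((v0, v1))
        kept_flags.append(kept)
        site_edges[p1].append(eid)
        site_edges[p2].append(eid)

    # finite region polygons (row/col frame)
    region_polys: list[Polygon | None] = []
    for i in range(n_sites):
        reg = vor.regions[vor.point_region[i]]
        if not reg or -1 in reg:
            region_polys.append(None)
            continue
        region_polys.append(Polygon(vor.vertices[reg]))  # (x=col, y=row) frame
    kept_arr = np.asarray(kept_flags, dtype=bool)
    return VectorMesh(sites, edges, kept_arr, site_edges, region_polys)


def _rasterize_mesh(mesh: VectorMesh, shape, params: SceneParams) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    rows, cols = shape
    for (v0, v1), kept in zip(mesh.edges, mesh.kept):
        if not kept:
            continue
        r0, c0 = int(round(v0[0])), int(round(v0[1]))
        r1, c1 = int(round(v1[0])), int(round(v1[1]))
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        canvas[rr[ok], cc[ok]] = True
    radius = max(1, int(round(MESH_LINE_WIDTH_UM / 2.0 / params.um_per_px)))
    return binary_dilation(canvas, structure=disk_footprint(radius))


def _offset_polyline(borders: BorderPair, depth: float) -> np.ndarray:
    """Polyline at a fixed relative depth between the (parallel) borders."""
    return borders.apical + depth * (borders.basal - borders.apical)


def zone_polygon(borders: BorderPair, d_lo: float, d_hi: float) -> Polygon:
    """Vector polygon of the band slice between two relative depths."""
    top = _offset_polyline(borders, d_lo)
    bot = _offset_polyline(borders, d_hi)
    return Polygon(np.vstack([top, bot[::-1]])[:, ::-1])


def mesh_closure_by_zone(gt: GroundTruth, borders: BorderPair) -> dict[str, float]:
    """Closed-cell area fraction per intermediate zone, from the vector mesh.

    A Voronoi region counts as closed when every one of its ridge edges was
    kept.  Region polygons are shrunk by half the drawn line width so the
    rate is comparable with raster measurements that exclude mesh-line
    pixels.  Returns area fractions for the upper and lower IM zones.
    """
    mesh = gt.mesh
    if mesh is None:
        raise ValueError("ground truth carries no vector mesh")
    b1, b2, b3 = gt.layer_boundary_depths
    half_w = MESH_LINE_WIDTH_UM / 2.0 / gt.params.um_per_px
    closed = [poly.buffer(-half_w)
              for poly, ok in zip(mesh.region_polys, mesh.region_closed)
              if ok and poly is not None]
    out = {}
    for name, lo, hi in (("upper_im", b1, b2), ("lower_im", b2, b3)):
        zone = zone_polygon(borders, lo, hi)
        covered = sum(poly.intersection(zone).area for poly in closed)
        out[name] = covered / zone.area if zone.area > 0 else float("nan")
    return out


def _place_in_zone(rng, zone_px_rc: np.ndarray, n: int,
                   min_sep_px: float = 0.0, jitter: bool = True) -> np.ndarray:
    """Sample n positions from the given zone pixels, optionally separated."""
    if n == 0 or len(zone_px_rc) == 0:
        return np.empty((0, 2))
    chosen: list[np.ndarray] = []
    tries = 0
    max_tries = 200 * n + 1000
    while len(chosen) < n and tries < max_tries:
        tries += 1
        p = zone_px_rc[rng.integers(len(zone_px_rc))].astype(float)
        if jitter:
            p = p + rng.uniform(-0.5, 0.5, size=2)
        if min_sep_px > 0 and chosen:
            d2 = np.sum((np.asarray(chosen) - p) ** 2, axis=1)
            if d2.min() < min_sep_px ** 2:
                continue
        chosen.append(p)
    return np.asarray(chosen)


def _gaussian_splat(canvas: np.ndarray, positions: np.ndarray,
                    sigma_px: float, amplitude: float) -> None:
    if len(positions) == 0:
        return
    r = int(math.ceil(3 * sigma_px))
    ax = np.arange(-r, r + 1)
    kern = amplitude * np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma_px ** 2))
    rows, cols = canvas.shape
    for pr, pc in positions:
        ir, ic = int(round(pr)), int(round(pc))
        r0, r1 = max(0, ir - r), min(rows, ir + r + 1)
        c0, c1 = max(0, ic - r), min(cols, ic + r + 1)
        canvas[r0:r1, c0:c1] += kern[r0 - ir + r:r1 - ir + r, c0 - ic + r:c1 - ic + r]


def generate_scene(params: SceneParams) -> tuple[MultiplexImage, BorderPair, GroundTruth]:
    """Render one scene and emit its ground truth.

    Identical parameters (including the seed) give bit-identical output.
    """
    borders = _make_borders(params)
    emask = geometry.epithelium_mask(params.image_size_px, borders)
    dfield = geometry.depth_field(emask, borders)
    depth = dfield.depth
    mask = emask.mask
    shape = mask.shape
    b1, b2, b3 = params.boundary_depths
    px_area_um2 = params.um_per_px ** 2
    band_poly = _band_polygon(borders)

    channels: dict[str, np.ndarray] = {}

    # ---- E-cadherin mesh -------------------------------------------------
    mesh = _build_mesh(params, borders, band_poly)
    mesh_raster = _rasterize_mesh(mesh, shape, params)
    mesh_raster &= mask
    mesh_raster &= ~(depth < b1)  # crisp superficial cutoff
    channels["ecadherin"] = np.where(mesh_raster, params.ecad_intensity, 0.0)

    coverage = {}
    zones = {"superficial": (0.0, b1), "upper_im": (b1, b2),
             "lower_im": (b2, b3), "parabasal": (b3, 1.0 + 1e-12)}
    for name, (lo, hi) in zones.items():
        zone = mask & (depth >= lo) & (depth < hi)
        coverage[name] = 100.0 * mesh_raster[zone].sum() / zone.sum() if zone.sum() else 0.0
    lower3 = mask & (depth >= b1)
    coverage["combined"] = (100.0 * mesh_raster[lower3].sum() / lower3.sum()
                            if lower3.sum() else 0.0)

    # ---- nuclei ----------------------------------------------------------
    rng_nuc = _rng(params, "nuclei")
    nuc_canvas = np.zeros(shape, dtype=float)
    nucleus_positions: list[tuple[float, float]] = []
    sigma_px = NUCLEUS_DIAMETER_UM / 2.8 / params.um_per_px
    for dens, zsel in ((params.nucleus_density_parabasal, mask & (depth >= b3)),
                       (params.nucleus_density_other, mask & (depth < b3))):
        zone_px = np.column_stack(np.nonzero(zsel))
        n = rng_nuc.poisson(dens / 1000.0 * zsel.sum() * px_area_um2)
        pos = _place_in_zone(rng_nuc, zone_px, int(n))
        nucleus_positions.extend(map(tuple, pos))
        _gaussian_splat(nuc_canvas, pos, sigma_px, NUCLEUS_INTENSITY)
    channels["nuclei"] = nuc_canvas

    # ---- marker band -----------------------------------------------------
    true_band_mfi = None
    if params.marker_band is not None:
        mb = params.marker_band
        band_sel = mask & (depth >= mb.depth_lo) & (depth <= mb.depth_hi)
        channels[mb.name] = np.where(band_sel, mb.intensity, 0.0)
        true_band_mfi = mb.intensity

    # ---- CD4 spots -------------------------------------------------------
    rng_cd4 = _rng(params, "cd4")
    cd4_canvas = np.zeros(shape, dtype=float)
    cd4_positions: list[tuple[float, float, str]] = []
    if params.cd4_count > 0:
        w = np.asarray(params.cd4_depth_weights, dtype=float)
        layer_of = rng_cd4.choice(4, size=params.cd4_count, p=w / w.sum())
        r_px = CD4_SPOT_RADIUS_UM / params.um_per_px
        min_sep = 2.0 * r_px + 3.0
        layer_bounds = [(0.0, b1), (b1, b2), (b2, b3), (b3, 1.0 + 1e-12)]
        zone_px_by_layer = []
        for lo, hi in layer_bounds:
            zsel = mask & (depth >= lo) & (depth < hi)
            zone_px_by_layer.append(np.column_stack(np.nonzero(zsel)))
        placed = np.empty((params.cd4_count, 2))
        n_placed = 0
        for li in layer_of:
            zone_px = zone_px_by_layer[li]
            if len(zone_px) == 0:
                continue
            p = None
            for _ in range(60):  # keep spots disjoint so components stay countable
                cand = zone_px[rng_cd4.integers(len(zone_px))] + rng_cd4.uniform(-0.5, 0.5, 2)
                if (n_placed == 0
                        or np.min(np.sum((placed[:n_placed] - cand) ** 2,
                                         axis=1)) >= min_sep ** 2):
                    p = cand
                    break
            if p is None:  # crowded zone: accept an overlapping position
                p = zone_px[rng_cd4.integers(len(zone_px))] + rng_cd4.uniform(-0.5, 0.5, 2)
            placed[n_placed] = p
            n_placed += 1
            cd4_positions.append((float(p[0]), float(p[1]), LAYER_NAMES[int(li)]))
        for pr, pc, _ in cd4_positions:
            rr, cc = draw_disk((pr, pc), r_px, shape=shape)
            cd4_canvas[rr, cc] = CD4_INTENSITY
        cd4_canvas[~mask] = 0.0
    channels["cd4"] = cd4_canvas

    # ---- noise -----------------------------------------------------------
    g_sd, p_scale = params.noise
    for name in list(channels):
        rng_n = np.random.default_rng(
            np.random.SeedSequence([params.seed, _STREAMS["noise"], _STREAMS[name]]))
        arr = channels[name]
        if g_sd > 0:
            arr = arr + rng_n.normal(0.0, g_sd, size=arr.shape)
        arr = np.clip(arr, 0.0, None)
        if p_scale > 0:
            arr = rng_n.poisson(arr * p_scale).astype(float) / p_scale
        channels[name] = arr

    image = MultiplexImage(channels=channels, um_per_px=params.um_per_px,
                           sample_id=f"synth-seed{params.seed}")
    gt = GroundTruth(
        params=params,
        apical_polyline=borders.apical.copy(),
        basal_polyline=borders.basal.copy(),
        layer_boundary_depths=(b1, b2, b3),
        true_layer_thickness_um=tuple(f * params.total_height_um
                                      for f in params.layer_fracs),
        true_ecad_coverage_pct_by_layer=coverage,
        true_band_mfi=true_band_mfi,
        cd4_positions=cd4_positions,
        nucleus_positions=nucleus_positions,
        mesh=mesh,
    )
    return image, borders, gt


def _band_polygon(borders: BorderPair) -> Polygon:
    ring = np.vstack([borders.apical, borders.basal[::-1]])
    return Polygon(ring[:, ::-1])


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Serialize the ground truth (minus the vector mesh) as JSON."""
    params = dataclasses.asdict(gt.params)
    payload = {
        "params": params,
        "apical_polyline": gt.apical_polyline.tolist(),
        "basal_polyline": gt.basal_polyline.tolist(),
        "layer_boundary_depths": list(gt.layer_boundary_depths),
        "true_layer_thickness_um": list(gt.true_layer_thickness_um),
        "true_ecad_coverage_pct_by_layer": gt.true_ecad_coverage_pct_by_layer,
        "true_band_mfi": gt.true_band_mfi,
        "cd4_positions": [[r, c, lab] for r, c, lab in gt.cd4_positions],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_scene(params: SceneParams, out_dir) -> None:
    """Generate a scene and write image.tif, borders.json and ground_truth.json."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    image, borders, gt = generate_scene(params)
    write_multiplex_tiff(image, os.path.join(out_dir, "image.tif"))
    write_borders(borders, os.path.join(out_dir, "borders.json"))
    write_ground_truth(gt, os.path.join(out_dir, "ground_truth.json"))
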