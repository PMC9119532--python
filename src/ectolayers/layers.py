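"""Staining-pattern-based layer segmentation and layer-resolved metrics.

Two segmentation schemes are implemented, both operating on depth-binned
staining profiles rather than on individual pixels (the layers of a
stratified epithelium are bands; binning regularizes noisy staining):

*Four-layer scheme* (junction-mesh channel, E-cadherin): superficial layer
with no mesh, an upper intermediate (IM) layer with a fragmented ("broken
net") mesh, a lower IM layer with a closed ("intact net") mesh, and a
nucleus-dense parabasal layer.

*Three-layer scheme* (band marker, desmoglein-1 / claudin-1): an upper and
a lower marker-negative layer flanking the contiguous marker-positive
mid-band.

All positivity calls use Otsu's threshold computed over epithelium-mask
pixels only; boundary detections use a two-consecutive-bin persistence rule
to guard against single-bin noise.  Both are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label

from .geometry import DepthField, EpitheliumMask, _probe_heights_px
from .imgio import BorderPair

log = logging.getLogger(__name__)

SUPERFICIAL, UPPER_IM, LOWER_IM, PARABASAL = 0, 1, 2, 3
LAYER4_NAMES = ("superficial", "upper_im", "lower_im", "parabasal")
UPPER, MARKER_POS, LOWER = 0, 1, 2
LAYER3_NAMES = ("upper", "marker_pos", "lower")


@dataclass
class LayerConfig:
    """Tunable thresholds of the layer module (YAML key ``layers.*``)."""

    n_bins: int = 50
    persistence: int = 2          # consecutive bins required for a boundary call
    theta_net: float = 0.05       # net area-fraction that starts the mesh zone
    theta_nuc: float = 2.0        # parabasal = density >= theta_nuc x median
    theta_intact_rel: float = 0.5  # intact = profile >= rel x max(profile)
    theta_band: float = 0.25      # marker-positive bin area-fraction
    min_object_um2: float = 4.0   # speckle removal for the net mask
    nucleus_diameter_um: float = 6.0
    band_min_snr: float = 8.0     # signal/background separation for a valid band
    n_probes: int = 200


@dataclass
class NetMask:
    """Junction-protein-positive pixels within the epithelium mask."""

    mask: np.ndarray
    um_per_px: float

    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class IntactnessProfile:
    """Per-depth-bin fraction of area covered by closed mesh cells."""

    values: np.ndarray
    bin_edges: np.ndarray


@dataclass
class LayerMap4:
    """Per-pixel four-layer label (-1 outside the epithelium)."""

    labels: np.ndarray
    boundaries: tuple[float, float, float]
    warnings: list[str] = field(default_factory=list)

    def layer_mask(self, layer: int) -> np.ndarray:
        return self.labels == layer


@dataclass
class LayerMap3:
    """Per-pixel three-layer label for a marker mid-band (-1 outside)."""

    labels: np.ndarray
    boundaries: tuple[float, float]
    ok: bool = True
    warnings: list[str] = field(default_factory=list)

    def layer_mask(self, layer: int) -> np.ndarray:
        return self.labels == layer


# ---------------------------------------------------------------------------
# positivity and profiles
# ---------------------------------------------------------------------------

def _drop_small_components(flags: np.ndarray, min_um2: float,
                           um_per_px: float) -> np.ndarray:
    """Remove connected components smaller than ``min_um2``."""
    min_px = max(1, int(round(min_um2 / um_per_px ** 2)))
    lab = cc_label(flags, connectivity=2)
    counts = np.bincount(lab.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[lab]


def _otsu_positive(channel: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float]:
    vals = channel[mask]
    if vals.size == 0:
        return np.zeros_like(mask, dtype=bool), float("inf")
    if vals.max() == vals.min():
        # constant within the mask: uniformly positive if nonzero, else empty
        if vals.max() > 0:
            return mask.copy(), 0.0
        return np.zeros_like(mask, dtype=bool), float("inf")
    thr = threshold_otsu(vals)
    return (channel > thr) & mask, float(thr)


def segment_net(ecad_channel: np.ndarray, mask: EpitheliumMask,
                min_object_um2: float = 4.0) -> NetMask:
    """Otsu positivity within the mask, then small-speckle removal."""
    pos, _ = _otsu_positive(ecad_channel, mask.mask)
    if not pos.any():
        log.warning("junction channel is flat within the mask; empty net mask")
        return NetMask(mask=pos, um_per_px=mask.um_per_px)
    pos = _drop_small_components(pos, min_object_um2, mask.um_per_px)
    return NetMask(mask=pos, um_per_px=mask.um_per_px)


def _bin_indices(depth: DepthField, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Depth-bin index per mask pixel, and the bin edges."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    d = depth.depth[depth.mask]
    idx = np.minimum((d * n_bins).astype(int), n_bins - 1)
    return idx, edges


def _bin_fraction(flag_raster: np.ndarray, depth: DepthField,
                  n_bins: int) -> np.ndarray:
    """Per-bin fraction of mask pixels for which ``flag_raster`` is True."""
    idx, _ = _bin_indices(depth, n_bins)
    flags = flag_raster[depth.mask]
    tot = np.bincount(idx, minlength=n_bins).astype(float)
    hit = np.bincount(idx, weights=flags.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, hit / tot, 0.0)


def intactness_profile(net: NetMask, mask: EpitheliumMask, depth: DepthField,
                       cell_diameter_um: float, n_bins: int = 50) -> IntactnessProfile:
    """Fraction of each depth bin covered by closed mesh cells.

    Closed cells are connected components of (mask AND NOT net) that do not
    touch the mask boundary and whose area lies within [0.1, 10] times the
    nominal cell area pi (d/2)^2.  Merged neighbouring cells below the area
    cap still count as closed; large percolating background regions do not.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    if not net.mask.any():
        raise ValueError("net mask is empty; intactness undefined")
    bg = mask.mask & ~net.mask
    lab = cc_label(bg, connectivity=1)
    boundary = mask.mask & ~binary_erosion(mask.mask)
    touching = np.unique(lab[boundary & bg])
    nominal_px = np.pi * (cell_diameter_um / 2.0 / mask.um_per_px) ** 2
    counts = np.bincount(lab.ravel())
    ok_area = (counts >= 0.1 * nominal_px) & (counts <= 10.0 * nominal_px)
    ok_area[0] = False
    ok_area[touching[touching > 0]] = False
    closed = ok_area[lab]
    values = _bin_fraction(closed, depth, n_bins)
    return IntactnessProfile(values=values, bin_edges=np.linspace(0, 1, n_bins + 1))


def detect_nuclei(nuclei_channel: np.ndarray, mask: EpitheliumMask,
                  nucleus_diameter_um: float = 6.0) -> np.ndarray:
    """Nucleus centroids as local maxima of the smoothed channel above Otsu."""
    sigma = nucleus_diameter_um / 4.0 / mask.um_per_px
    smoothed = gaussian(nuclei_channel, sigma=sigma, preserve_range=True)
    vals = smoothed[mask.mask]
    if vals.size == 0 or vals.max() == vals.min():
        return np.empty((0, 2), dtype=int)
    thr = threshold_otsu(vals)
    min_dist = max(1, int(round(0.5 * nucleus_diameter_um / mask.um_per_px)))
    peaks = peak_local_max(smoothed, min_distance=min_dist, threshold_abs=thr,
                           labels=mask.mask)
    return peaks


def nucleus_density_profile(nuclei_channel: np.ndarray, mask: EpitheliumMask,
                            depth: DepthField, n_bins: int = 50,
                            nucleus_diameter_um: float = 6.0) -> np.ndarray:
    """Detected nuclei per 1000 um^2, per depth bin."""
    peaks = detect_nuclei(nuclei_channel, mask, nucleus_diameter_um)
    idx, _ = _bin_indices(depth, n_bins)
    tot_px = np.bincount(idx, minlength=n_bins).astype(float)
    if len(peaks):
        d = depth.depth[peaks[:, 0], peaks[:, 1]]
        d = d[np.isfinite(d)]
        pk_idx = np.minimum((d * n_bins).astype(int), n_bins - 1)
        n_per_bin = np.bincount(pk_idx, minlength=n_bins).astype(float)
    else:
        n_per_bin = np.zeros(n_bins)
    area_um2 = tot_px * mask.um_per_px ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(area_um2 > 0, n_per_bin / area_um2 * 1000.0, 0.0)
    return dens


# ---------------------------------------------------------------------------
# boundary detection
# ---------------------------------------------------------------------------

def _first_persistent(cond: np.ndarray, persistence: int,
                      start: int = 0, stop: int | None = None) -> int | None:
    """Index of the first bin opening a run of `persistence` True bins."""
    stop = len(cond) if stop is None else stop
    run = 0
    for i in range(start, stop):
        run = run + 1 if cond[i] else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def segment_four_layers(net: NetMask, intactness: IntactnessProfile | None,
                        nucdens: np.ndarray, depth: DepthField,
                        mask: EpitheliumMask,
                        config: LayerConfig | None = None) -> LayerMap4:
    """Four-layer segmentation from the binned staining profiles.

    b1 (superficial/upper IM) is where the net area-fraction first stays
    above ``theta_net``; b3 (lower IM/parabasal) is where nucleus density
    first stays above ``theta_nuc`` times the median density below b1; b2
    (upper/lower IM) is where mesh intactness first stays above
    ``theta_intact_rel`` times the profile maximum, searched within
    (b1, b3).  Undetectable boundaries collapse onto the adjacent boundary
    (empty layer) with a warning.
    """
    cfg = config or LayerConfig()
    n_bins = cfg.n_bins
    if intactness is not None and len(intactness.values) != n_bins:
        raise ValueError("intactness profile computed on a different bin grid")
    if len(nucdens) != n_bins:
        raise ValueError("nucleus profile computed on a different bin grid")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    warnings: list[str] = []

    f_net = _bin_fraction(net.mask, depth, n_bins)
    i1 = _first_persistent(f_net >= cfg.theta_net, cfg.persistence)
    if i1 is None:
        warnings.append("no depth reaches the net threshold; superficial layer "
                        "spans the whole non-parabasal epithelium")
        b1_eff = 0.0
    else:
        b1_eff = float(edges[i1])

    deeper = edges[:-1] > b1_eff
    med = float(np.median(nucdens[deeper])) if deeper.any() else 0.0
    cond_nuc = nucdens >= cfg.theta_nuc * max(med, 1e-12)
    i3 = _first_persistent(cond_nuc & deeper, cfg.persistence)
    if i3 is None:
        warnings.append("no nucleus-dense zone found; parabasal layer empty")
        b3 = 1.0
    else:
        b3 = float(edges[i3])

    if i1 is None:
        b1 = b2 = b3
        warnings.append("net absent; upper and lower IM layers empty")
    else:
        b1 = b1_eff
        if intactness is None:
            raise ValueError("intactness profile required when a net is present")
        theta_i = cfg.theta_intact_rel * float(intactness.values.max())
        in_window = (edges[:-1] >= b1) & (edges[:-1] < b3)
        i2 = _first_persistent((intactness.values >= theta_i) & in_window,
                               cfg.persistence)
        if i2 is None:
            warnings.append("no intact-net zone found; lower IM layer empty")
            b2 = b3
        else:
            # closed-cell coverage ramps up over about one cell diameter at
            # the broken/intact transition; localize the onset at half the
            # calling threshold within the persistence window
            first_ok = int(np.argmax(in_window)) if in_window.any() else 0
            steps = 0
            while (i2 > first_ok and steps < cfg.persistence
                   and intactness.values[i2 - 1] >= 0.5 * theta_i):
                i2 -= 1
                steps += 1
            b2 = float(edges[i2])
    if not (b1 <= b2 <= b3):
        raise ValueError(f"layer boundaries out of order: {(b1, b2, b3)}")
    if b2 - b1 <= 3.0 / n_bins:
        warnings.append("upper IM layer (broken net) is essentially empty")
    for w in warnings:
        log.warning("%s", w)

    labels = np.full(depth.depth.shape, -1, dtype=np.int8)
    d = depth.depth
    m = depth.mask
    labels[m & (d < b1)] = SUPERFICIAL
    labels[m & (d >= b1) & (d < b2)] = UPPER_IM
    labels[m & (d >= b2) & (d < b3)] = LOWER_IM
    labels[m & (d >= b3)] = PARABASAL
    return LayerMap4(labels=labels, boundaries=(b1, b2, b3), warnings=warnings)


def segment_marker_band(marker_channel: np.ndarray, mask: EpitheliumMask,
                        depth: DepthField, n_bins: int = 50,
                        theta_band: float = 0.25,
                        band_min_snr: float = 8.0) -> LayerMap3:
    """Three-layer segmentation around the contiguous marker-positive band.

    The marker-positive band is the longest contiguous run of depth bins
    whose Otsu-positive area fraction reaches ``theta_band``.  When no bin
    qualifies, or the positive/negative intensity separation is below
    ``band_min_snr`` standard deviations of the background (an all-negative
    stain thresholded on noise), the sample is marked as a segmentation
    failure rather than raising.
    """
    labels = np.full(marker_channel.shape, -1, dtype=np.int8)
    pos, _thr = _otsu_positive(marker_channel, mask.mask)
    failed = LayerMap3(labels=labels, boundaries=(0.0, 0.0), ok=False,
                       warnings=["marker band segmentation failed"])
    if not pos.any():
        return failed
    neg = mask.mask & ~pos
    mu_pos = float(marker_channel[pos].mean())
    mu_neg = float(marker_channel[neg].mean()) if neg.any() else 0.0
    sd_neg = float(marker_channel[neg].std()) if neg.any() else 0.0
    if mu_pos - mu_neg < band_min_snr * max(sd_neg, 1e-9):
        return failed
    frac = _bin_fraction(pos, depth, n_bins)
    qual = frac >= theta_band
    if not qual.any():
        return failed
    # longest contiguous qualifying run (first on ties)
    best_start = best_len = cur_start = cur_len = 0
    for i, q in enumerate(qual):
        if q:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    binw = 1.0 / n_bins
    m1 = float(edges[best_start])
    m2 = float(edges[best_start + best_len])
    # refine the band edges sub-bin from the edge bins' partial coverage:
    # a boundary bin with positive fraction f contains the true edge at
    # (1 - f) of the bin width from its qualifying side
    f_lo = float(np.clip(frac[best_start], 0.0, 1.0))
    m1 += (1.0 - f_lo) * binw
    f_hi = float(np.clip(frac[best_start + best_len - 1], 0.0, 1.0))
    m2 -= (1.0 - f_hi) * binw
    if not m1 < m2:  # single-bin band: fall back to the raw bin edges
        m1 = float(edges[best_start])
        m2 = float(edges[best_start + best_len])
    d = depth.depth
    m = depth.mask
    labels[m & (d < m1)] = UPPER
    labels[m & (d >= m1) & (d < m2)] = MARKER_POS
    if m2 >= 1.0 - 1e-12:
        labels[m & (d >= m2)] = MARKER_POS
    else:
        labels[m & (d >= m2)] = LOWER
    return LayerMap3(labels=labels, boundaries=(m1, m2))


# ---------------------------------------------------------------------------
# layer metrics
# ---------------------------------------------------------------------------

def layer_thickness_um(layermap: LayerMap4, borders: BorderPair,
                       n_probes: int = 200) -> dict[str, float]:
    """Mean thickness per layer (and total) along apical normal probes.

    Per probe, a layer's extent is its relative-depth width times the local
    band height; the reported thickness is the mean over probes, so the four
    layers sum to the total by construction.
    """
    heights = _probe_heights_px(None, borders, n_probes)
    mean_h_um = float(np.mean(heights)) * borders.um_per_px
    b1, b2, b3 = layermap.boundaries
    widths = (b1, b2 - b1, b3 - b2, 1.0 - b3)
    out = {name: w * mean_h_um for name, w in zip(LAYER4_NAMES, widths)}
    out["total"] = mean_h_um
    return out


def ecad_area_coverage_pct(net: NetMask, layermap: LayerMap4,
                           which_layers) -> float:
    """Net-positive area as % of the selected layers' area.

    ``which_layers`` is an iterable of layer ids from {UPPER_IM, LOWER_IM,
    PARABASAL}, or the string ``"combined"`` to pool the three sub-superficial
    layers.
    """
    if which_layers == "combined":
        which_layers = (UPPER_IM, LOWER_IM, PARABASAL)
    sel = np.isin(layermap.labels, list(which_layers))
    denom = sel.sum()
    if denom == 0:
        log.warning("selected layers are empty; coverage undefined")
        return float("nan")
    return 100.0 * float((net.mask & sel).sum()) / float(denom)


def layer_mfi(channel: np.ndarray, region: np.ndarray,
              positive: np.ndarray | None = None,
              mode: str = "all") -> float:
    """Mean fluorescence intensity over a region (AU).

    ``mode="positive_only"`` averages over positive pixels within the region
    (requires ``positive``); ``mode="all"`` averages over every region pixel.
    """
    if mode == "positive_only":
        if positive is None:
            raise ValueError("positive mask required in positive_only mode")
        region = region & positive
    elif mode != "all":
        raise ValueError(f"unknown MFI mode {mode!r}")
    if not region.any():
        log.warning("MFI region empty; undefined")
        return float("nan")
    return float(channel[region].mean())


def relative_heights_pct(layermap3: LayerMap3, borders: BorderPair,
                         n_probes: int = 200) -> tuple[float, float, float]:
    """Relative height (%) of the upper, marker-positive and lower layers.

    Computed as mean per-probe layer extent over mean total height; because
    the layers are depth bands, this reduces to the boundary-depth widths
    and the three values sum to exactly 100.
    """
    if not layermap3.ok:
        raise ValueError("cannot compute relative heights for a failed segmentation")
    _probe_heights_px(None, borders, n_probes)  # validates probe geometry
    m1, m2 = layermap3.boundaries
    return (100.0 * m1, 100.0 * (m2 - m1), 100.0 * (1.0 - m2))


def band_mfi_per_um2(channel: np.ndarray, layermap3: LayerMap3,
                     um_per_px: float) -> tuple[float, float]:
    """MFI of the marker-positive layer and MFI normalized by the layer area."""
    band = layermap3.layer_mask(MARKER_POS)
    if not layermap3.ok or not band.any():
        raise ValueError("marker-positive layer is empty")
    mfi = float(channel[band].mean())
    area = float(band.sum()) * um_per_px ** 2
    return mfi, mfi / area
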