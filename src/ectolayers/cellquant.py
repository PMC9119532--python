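"""CD4+ quantification: area fraction, per-layer distribution, apical distance.

The positively stained area fraction serves as the proxy for CD4+ cell
frequency; connected components (with centroids) back the spatial readouts
(per-layer proportions and mean distance to the apical border).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from skimage.measure import label as cc_label, regionprops

from .geometry import EpitheliumMask
from .imgio import BorderPair
from .layers import LAYER4_NAMES, LayerMap4

log = logging.getLogger(__name__)


@dataclass
class Cd4Mask:
    """CD4-positive pixels and their connected components."""

    mask: np.ndarray
    centroids: np.ndarray  # (n, 2) float (row, col)
    component_pixels: list[np.ndarray]  # per component, (k, 2) int (row, col)
    um_per_px: float

    @property
    def n_components(self) -> int:
        return len(self.centroids)


def detect_cd4(cd4_channel: np.ndarray, mask: EpitheliumMask,
               min_object_um2: float = 10.0) -> Cd4Mask:
    """Otsu positivity within the mask; components below the area floor removed."""
    from .layers import _otsu_positive

    pos, _ = _otsu_positive(cd4_channel, mask.mask)
    min_px = max(1, int(round(min_object_um2 / mask.um_per_px ** 2)))
    lab = cc_label(pos, connectivity=2)
    keep = np.zeros(pos.shape, dtype=bool)
    cents, pixels = [], []
    for rp in regionprops(lab):
        if rp.area >= min_px:
            keep[lab == rp.label] = True
            cents.append(rp.centroid)
            pixels.append(np.asarray(rp.coords))
    cents = np.asarray(cents, dtype=float) if cents else np.empty((0, 2))
    return Cd4Mask(mask=keep, centroids=cents, component_pixels=pixels,
                   um_per_px=mask.um_per_px)


def cd4_frequency_pct(cd4: Cd4Mask, mask: EpitheliumMask,
                      layermap: LayerMap4 | None = None) -> dict[str, float]:
    """Positive-area fraction (%) in the total epithelium and per layer."""
    out = {"total": 100.0 * float((cd4.mask & mask.mask).sum()) / mask.area_px()}
    if layermap is not None:
        for li, name in enumerate(LAYER4_NAMES):
            region = layermap.layer_mask(li)
            denom = region.sum()
            if denom == 0:
                log.warning("layer %s empty; CD4 frequency undefined", name)
                out[name] = float("nan")
            else:
                out[name] = 100.0 * float((cd4.mask & region).sum()) / float(denom)
    return out


def cd4_layer_proportions_pct(cd4: Cd4Mask, layermap: LayerMap4,
                              weight: str = "count") -> dict[str, float]:
    """Share (%) of CD4+ components per layer, assigned by centroid.

    A centroid exactly on a layer boundary belongs to the deeper layer
    (the labels raster is half-open toward depth).  Proportions sum to 100.
    ``weight="count"`` counts components; ``weight="area"`` weights each
    component by its pixel area.
    """
    if weight not in ("count", "area"):
        raise ValueError("weight must be 'count' or 'area'")
    if cd4.n_components == 0:
        log.warning("no CD4 components; proportions undefined")
        return {name: float("nan") for name in LAYER4_NAMES}
    labs = []
    for cent, pix in zip(cd4.centroids, cd4.component_pixels):
        r = int(round(cent[0]))
        c = int(round(cent[1]))
        r = np.clip(r, 0, layermap.labels.shape[0] - 1)
        c = np.clip(c, 0, layermap.labels.shape[1] - 1)
        lab = layermap.labels[r, c]
        if lab < 0:  # centroid off the labeled raster: use nearest own pixel
            d2 = np.sum((pix - cent) ** 2, axis=1)
            order = np.argsort(d2)
            for j in order:
                lab = layermap.labels[pix[j, 0], pix[j, 1]]
                if lab >= 0:
                    break
        labs.append(lab)
    labs = np.asarray(labs)
    w = (np.array([len(p) for p in cd4.component_pixels], dtype=float)
         if weight == "area" else np.ones(len(labs)))
    out = {}
    tot = float(w.sum())
    for li, name in enumerate(LAYER4_NAMES):
        out[name] = 100.0 * float(w[labs == li].sum()) / tot
    return out


def mean_distance_to_apical_um(cd4: Cd4Mask, borders: BorderPair) -> float:
    """Mean Euclidean distance from CD4+ centroids to the apical polyline (um)."""
    if cd4.n_components == 0:
        log.warning("no CD4 components; apical distance undefined")
        return float("nan")
    pts = shapely.points(cd4.centroids[:, ::-1])
    d = shapely.distance(pts, borders.apical_line())
    return float(np.mean(d) * borders.um_per_px)
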