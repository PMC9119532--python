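"""Readers and writers for images, border annotations, sample sheets and metric tables.

Conventions used throughout the package
---------------------------------------
* Coordinates are 0-based ``(row, col)`` pixel indices with pixel centers at
  integer coordinates.  Polylines and polygons live in the same frame.
* The channel vocabulary is closed: ``nuclei``, ``ecadherin``, ``cd4``,
  ``dsg1``, ``cldn1`` — one per stain (DAPI, E-cadherin, CD4, desmoglein-1,
  claudin-1).
* Intensities are non-negative floats in arbitrary units (AU).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import LineString

log = logging.getLogger(__name__)

#: closed channel vocabulary (maps to the five stains)
CHANNELS = ("nuclei", "ecadherin", "cd4", "dsg1", "cldn1")

#: closed units vocabulary for metric records
UNITS = ("um", "%", "AU", "AU/um2", "um2", "count")

#: closed group vocabulary for sample sheets
GROUPS = ("DMPA", "control")


@dataclass
class MultiplexImage:
    """Calibrated 2D multi-channel intensity raster.

    Parameters
    ----------
    channels
        Mapping channel name -> 2D float array; all arrays share one shape.
    um_per_px
        Pixel pitch in micrometers per pixel (isotropic).
    sample_id
        Identifier of the tissue section the image was taken from.
    """

    channels: dict[str, np.ndarray]
    um_per_px: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiplexImage needs at least one channel")
        if not np.isfinite(self.um_per_px) or self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters disagree in shape: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def _as_polyline(points, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError(f"{name} polyline needs >= 2 (row, col) points")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} polyline has non-finite coordinates")
    if not LineString(pts[:, ::-1]).is_simple:
        raise ValueError(f"{name} polyline is self-intersecting")
    return pts


@dataclass
class BorderPair:
    """Ordered apical and basal polylines delimiting the epithelium.

    The apical border faces the lumen, the basal border faces the stroma.
    Both are ``(n, 2)`` arrays of 0-based ``(row, col)`` pixel coordinates.
    """

    apical: np.ndarray
    basal: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        self.apical = _as_polyline(self.apical, "apical")
        self.basal = _as_polyline(self.basal, "basal")
        if not np.isfinite(self.um_per_px) or self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")
        a = LineString(self.apical[:, ::-1])
        b = LineString(self.basal[:, ::-1])
        if a.intersects(b):
            raise ValueError("apical and basal polylines intersect")

    def apical_line(self) -> LineString:
        """Apical polyline as a shapely LineString in (x=col, y=row) frame."""
        return LineString(self.apical[:, ::-1])

    def basal_line(self) -> LineString:
        return LineString(self.basal[:, ::-1])


@dataclass
class MetricRecord:
    """One named per-sample measurement with units."""

    sample_id: str
    metric_name: str
    value: float
    units: str

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; allowed: {UNITS}")
        if not np.isfinite(self.value):
            raise ValueError(f"metric {self.metric_name!r} value is not finite")


@dataclass
class SampleSheet:
    """Cohort description: one row per sample with group label and covariates."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample_id", "group")
    OPTIONAL = ("image", "borders", "age", "sex_work_months")

    def __post_init__(self) -> None:
        df = self.frame
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"sample sheet misses required column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; allowed: {GROUPS}")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def write_multiplex_tiff(image: MultiplexImage, path) -> None:
    """Write one TIFF page per channel; channel name stored in the page description."""
    with tifffile.TiffWriter(path) as tw:
        for name, arr in image.channels.items():
            tw.write(
                arr.astype(np.float32),
                description=name,
                resolution=(1.0 / image.um_per_px, 1.0 / image.um_per_px),
                resolutionunit="MICROMETER",
                metadata=None,
            )


def read_multiplex_tiff(path, channel_map: dict | None = None,
                        um_per_px: float | None = None,
                        sample_id: str = "") -> MultiplexImage:
    """Read a multipage TIFF into a :class:`MultiplexImage`.

    Parameters
    ----------
    channel_map
        Maps page index (int) or page description (str) to a channel name.
        When omitted, page descriptions are used as channel names directly.
    um_per_px
        Overrides the calibration stored in the file.  If neither is
        available, falls back to 1.0 um/px with a logged warning.
    """
    pages = []
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            desc = (page.description or "").strip()
            pages.append((i, desc, page.asarray()))
            if um_per_px is None:
                try:
                    xres = page.tags["XResolution"].value
                    unit = page.tags["ResolutionUnit"].value
                    if getattr(unit, "name", str(unit)).upper().endswith("MICROMETER"):
                        um_per_px = xres[1] / xres[0]
                except (KeyError, ZeroDivisionError, TypeError):
                    pass
    if um_per_px is None:
        log.warning("%s: no pixel calibration found, assuming 1.0 um/px", path)
        um_per_px = 1.0

    channels: dict[str, np.ndarray] = {}
    for i, desc, arr in pages:
        if channel_map is not None:
            if i in channel_map:
                name = channel_map[i]
            elif desc in channel_map:
                name = channel_map[desc]
            else:
                continue
        else:
            name = desc or f"page{i}"
        if name in channels:
            raise ValueError(f"duplicate channel name {name!r} in {path}")
        channels[name] = np.asarray(arr, dtype=float)
    return MultiplexImage(channels=channels, um_per_px=float(um_per_px),
                          sample_id=sample_id)


# ---------------------------------------------------------------------------
# Borders JSON
# ---------------------------------------------------------------------------

def write_borders(borders: BorderPair, path) -> None:
    payload = {
        "apical": borders.apical.tolist(),
        "basal": borders.basal.tolist(),
        "um_per_px": borders.um_per_px,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_borders(path) -> BorderPair:
    with open(path) as fh:
        payload = json.load(fh)
    return BorderPair(
        apical=np.asarray(payload["apical"], dtype=float),
        basal=np.asarray(payload["basal"], dtype=float),
        um_per_px=float(payload["um_per_px"]),
    )


# ---------------------------------------------------------------------------
# Metrics CSV
# ---------------------------------------------------------------------------

def write_metrics(records: list[MetricRecord], path) -> None:
    """Write metric records as CSV, rows sorted by (sample_id, metric_name)."""
    if not records:
        raise ValueError("no metric records to write")
    df = pd.DataFrame(
        [(r.sample_id, r.metric_name, r.value, r.units) for r in records],
        columns=["sample_id", "metric_name", "value", "units"],
    )
    df = df.sort_values(["sample_id", "metric_name"], kind="stable")
    df["value"] = df["value"].map(lambda v: float(f"{v:.6g}"))
    df.to_csv(path, index=False)


def read_metrics(path) -> list[MetricRecord]:
    df = pd.read_csv(path)
    return [MetricRecord(str(r.sample_id), str(r.metric_name), float(r.value), str(r.units))
            for r in df.itertuples(index=False)]


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype={"sample_id": str}))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, index=False)
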