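"""Config-driven orchestration: per-sample metric extraction, cohort
comparison, QC reporting.

A sample never aborts the cohort: metrics that cannot be computed from the
available channels (missing stain, failed band segmentation, empty region)
are recorded in the per-sample QC report and simply absent from the metric
table, mirroring per-stain quality exclusions in real studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import yaml

from . import cellquant, geometry, layers, stats
from .imgio import (BorderPair, MetricRecord, MultiplexImage, SampleSheet,
                    read_borders, read_multiplex_tiff, read_sample_sheet,
                    write_metrics)
from .layers import LAYER4_NAMES, LayerConfig

log = logging.getLogger(__name__)

#: closed metric vocabulary: name -> units
METRIC_VOCABULARY: dict[str, str] = {"epithelium_area_um2": "um2"}
for _l in ("total",) + LAYER4_NAMES:
    METRIC_VOCABULARY[f"thickness_{_l}_um"] = "um"
for _l in ("upper_im", "lower_im", "parabasal", "combined"):
    METRIC_VOCABULARY[f"ecad_coverage_{_l}_pct"] = "%"
    METRIC_VOCABULARY[f"ecad_mfi_{_l}_au"] = "AU"
for _l in ("total",) + LAYER4_NAMES:
    METRIC_VOCABULARY[f"cd4_freq_{_l}_pct"] = "%"
for _l in LAYER4_NAMES:
    METRIC_VOCABULARY[f"cd4_prop_{_l}_pct"] = "%"
METRIC_VOCABULARY["cd4_count"] = "count"
METRIC_VOCABULARY["cd4_dist_apical_um"] = "um"
for _m in ("dsg1", "cldn1"):
    for _l in ("upper", "band", "lower"):
        METRIC_VOCABULARY[f"{_m}_height_{_l}_um"] = "um"
        METRIC_VOCABULARY[f"{_m}_relheight_{_l}_pct"] = "%"
    METRIC_VOCABULARY[f"{_m}_mfi_au"] = "AU"
    METRIC_VOCABULARY[f"{_m}_mfi_per_um2"] = "AU/um2"


@dataclasses.dataclass
class RunConfig:
    """Everything a cohort run needs; loadable from YAML."""

    sample_sheet: str = ""
    out_dir: str = "out"
    channel_map: dict | None = None
    seed: int = 0
    n_probes: int = 200
    layers: LayerConfig = dataclasses.field(default_factory=LayerConfig)
    mesh_cell_diameter_um: float = 15.0
    cd4_min_object_um2: float = 10.0
    cd4_proportions_weight: str = "count"
    metric_set: list[str] | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        layer_cfg = LayerConfig(**raw.pop("layers", {}))
        geom = raw.pop("geometry", {})
        cellq = raw.pop("cellquant", {})
        cfg = cls(layers=layer_cfg, **raw)
        if "n_probes" in geom:
            cfg.n_probes = int(geom["n_probes"])
        if "min_object_um2" in cellq:
            cfg.cd4_min_object_um2 = float(cellq["min_object_um2"])
        if "proportions_weight" in cellq:
            cfg.cd4_proportions_weight = str(cellq["proportions_weight"])
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _emit(records: list[MetricRecord], qc: dict, sample_id: str,
          name: str, value: float) -> None:
    units = METRIC_VOCABULARY[name]
    if value is None or not np.isfinite(value):
        qc["failed_metrics"].append(name)
        return
    records.append(MetricRecord(sample_id, name, float(value), units))


def run_sample(image: MultiplexImage, borders: BorderPair,
               config: RunConfig | None = None) -> tuple[list[MetricRecord], dict]:
    """Compute every metric the available channels support for one sample."""
    cfg = config or RunConfig()
    lc = cfg.layers
    sid = image.sample_id or "sample"
    qc: dict = {"sample_id": sid, "status": "ok", "warnings": [],
                "failed_metrics": []}
    records: list[MetricRecord] = []

    emask = geometry.epithelium_mask(image.shape, borders)
    depth = geometry.depth_field(emask, borders)
    _emit(records, qc, sid, "epithelium_area_um2", geometry.area_um2(emask))

    layermap4 = None
    if "ecadherin" in image and "nuclei" in image:
        net = layers.segment_net(image["ecadherin"], emask, lc.min_object_um2)
        intact = None
        if net.mask.any():
            intact = layers.intactness_profile(net, emask, depth,
                                               cfg.mesh_cell_diameter_um,
                                               lc.n_bins)
        nucdens = layers.nucleus_density_profile(image["nuclei"], emask, depth,
                                                 lc.n_bins, lc.nucleus_diameter_um)
        layermap4 = layers.segment_four_layers(net, intact, nucdens, depth,
                                               emask, lc)
        qc["warnings"].extend(layermap4.warnings)
        thick = layers.layer_thickness_um(layermap4, borders, cfg.n_probes)
        for lname, v in thick.items():
            _emit(records, qc, sid, f"thickness_{lname}_um", v)
        for sel, lname in ((layers.UPPER_IM, "upper_im"),
                           (layers.LOWER_IM, "lower_im"),
                           (layers.PARABASAL, "parabasal"),
                           ("combined", "combined")):
            which = sel if sel == "combined" else (sel,)
            cov = layers.ecad_area_coverage_pct(net, layermap4, which)
            _emit(records, qc, sid, f"ecad_coverage_{lname}_pct", cov)
            region = (np.isin(layermap4.labels, [layers.UPPER_IM, layers.LOWER_IM,
                                                 layers.PARABASAL])
                      if sel == "combined" else layermap4.layer_mask(sel))
            mfi = layers.layer_mfi(image["ecadherin"], region,
                                   positive=net.mask, mode="positive_only")
            _emit(records, qc, sid, f"ecad_mfi_{lname}_au", mfi)

    if "cd4" in image and layermap4 is not None:
        cd4 = cellquant.detect_cd4(image["cd4"], emask, cfg.cd4_min_object_um2)
        _emit(records, qc, sid, "cd4_count", cd4.n_components)
        freq = cellquant.cd4_frequency_pct(cd4, emask, layermap4)
        for lname, v in freq.items():
            _emit(records, qc, sid, f"cd4_freq_{lname}_pct", v)
        if cd4.n_components:
            props = cellquant.cd4_layer_proportions_pct(
                cd4, layermap4, weight=cfg.cd4_proportions_weight)
            for lname, v in props.items():
                _emit(records, qc, sid, f"cd4_prop_{lname}_pct", v)
            _emit(records, qc, sid, "cd4_dist_apical_um",
                  cellquant.mean_distance_to_apical_um(cd4, borders))
        else:
            qc["failed_metrics"].extend(
                [f"cd4_prop_{n}_pct" for n in LAYER4_NAMES] + ["cd4_dist_apical_um"])

    for marker in ("dsg1", "cldn1"):
        if marker not in image:
            continue
        lm3 = layers.segment_marker_band(image[marker], emask, depth,
                                         lc.n_bins, lc.theta_band,
                                         lc.band_min_snr)
        if not lm3.ok:
            qc["warnings"].append(f"{marker} band segmentation failed")
            qc["failed_metrics"].extend(
                [f"{marker}_height_{s}_um" for s in ("upper", "band", "lower")]
                + [f"{marker}_relheight_{s}_pct" for s in ("upper", "band", "lower")]
                + [f"{marker}_mfi_au", f"{marker}_mfi_per_um2"])
            continue
        rel = layers.relative_heights_pct(lm3, borders, cfg.n_probes)
        total_um = geometry.total_height_um(emask, borders, cfg.n_probes)
        for s, r in zip(("upper", "band", "lower"), rel):
            _emit(records, qc, sid, f"{marker}_relheight_{s}_pct", r)
            _emit(records, qc, sid, f"{marker}_height_{s}_um", r / 100.0 * total_um)
        mfi, mfi_density = layers.band_mfi_per_um2(image[marker], lm3,
                                                   image.um_per_px)
        _emit(records, qc, sid, f"{marker}_mfi_au", mfi)
        _emit(records, qc, sid, f"{marker}_mfi_per_um2", mfi_density)

    if qc["failed_metrics"] or qc["warnings"]:
        qc["status"] = "warning"
    return records, qc


def run_cohort(config: RunConfig) -> dict:
    """Process every sample in the sheet; write metrics, comparison and QC.

    Returns a summary dict with per-sample statuses.  Output files:
    ``metrics.csv``, ``comparison.tsv``, ``qc.json`` and ``config.yaml``
    (the echoed configuration) inside ``config.out_dir``.
    """
    sheet = read_sample_sheet(config.sample_sheet)
    if len(sheet) == 0:
        raise ValueError("empty cohort")
    os.makedirs(config.out_dir, exist_ok=True)
    base = os.path.dirname(os.path.abspath(config.sample_sheet))

    all_records: list[MetricRecord] = []
    qcs: list[dict] = []
    aborted = 0
    for row in sheet.frame.itertuples(index=False):
        try:
            img_path = os.path.join(base, row.image)
            bor_path = os.path.join(base, row.borders)
            image = read_multiplex_tiff(img_path, config.channel_map,
                                        sample_id=row.sample_id)
            borders = read_borders(bor_path)
            records, qc = run_sample(image, borders, config)
            all_records.extend(records)
            qcs.append(qc)
        except Exception as exc:  # per-sample isolation
            log.error("sample %s aborted: %s", row.sample_id, exc)
            qcs.append({"sample_id": row.sample_id, "status": "aborted",
                        "warnings": [str(exc)], "failed_metrics": []})
            aborted += 1

    if all_records:
        write_metrics(all_records, os.path.join(config.out_dir, "metrics.csv"))
    counts = sheet.frame.group.value_counts()
    if all(counts.get(g, 0) >= 2 for g in ("DMPA", "control")):
        results = stats.compare_groups(all_records, sheet, config.metric_set)
        stats.results_frame(results).to_csv(
            os.path.join(config.out_dir, "comparison.tsv"), sep="\t",
            index=False, float_format="%.6g")
    else:
        log.warning("a group has < 2 samples; comparison skipped")
    with open(os.path.join(config.out_dir, "qc.json"), "w") as fh:
        json.dump(qcs, fh, indent=1, sort_keys=True)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    return {"n_samples": len(sheet), "n_aborted": aborted, "qc": qcs}
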