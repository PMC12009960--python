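"""File I/O, run configuration and the three end-to-end assays.

The assays compose the other modules:

* :func:`run_quantify` — pathology time-course: threshold → colocalised
  fragment extraction → per-field normalised metrics → Grubbs-filtered
  chamber medians → trend regression;
* :func:`run_cfse` — transport vs transfer: reverse-chamber fields within
  400 µm of the microchannels, fragments split into CFSE-positive
  (transported) and CFSE-negative (transferred) populations;
* :func:`run_kymo` — microchannel transport: per-lane kymographs, trace
  detection, direction and exit counts.

Each assay exists in two forms: an in-memory function operating on a
:class:`~synspread.synth.StudyDataset` (or arrays), used by tests and
scripts, and a file-based runner driven by a YAML config that reads TIFFs
and writes CSV/JSON outputs atomically (temp file + rename), with every
applied threshold logged so runs are auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import quantify as q
from . import segment as seg
from .geometry import (
    MAIN_BAND_UM,
    NEAR_BAND_UM,
    DeviceGeometry,
    FieldImage,
    RoiBand,
    load_geometry,
    make_roi_mask,
)
from .kymo import TraceParams, build_kymograph, detect_traces
from .synth import StudyDataset

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_stack",
    "write_field_tiff",
    "quantify_field",
    "quantify_study",
    "run_quantify",
    "cfse_study",
    "run_cfse",
    "run_kymo",
]


# --------------------------------------------------------------------------
# TIFF reading with calibration sidecars


def read_stack(
    path,
    *,
    pixel_size: float | None = None,
    offset: tuple[float, float] | None = None,
    channel_map: dict[int, str] | None = None,
):
    """Read a TIFF as FieldImage(s) or a movie stack.

    Calibration (``pixel_size``, ``offset``) and the page→channel mapping
    come from the arguments or from a JSON sidecar ``<path>.json``; a
    missing pixel size is a hard error naming the key.  A multi-page file
    with a channel map yields one :class:`FieldImage` per mapped page; with
    ``channel_map=None`` and multiple pages the raw (frames, rows, cols)
    array is returned for movie analysis.
    """
    path = Path(path)
    meta = {}
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if pixel_size is None:
        raise ValueError(f"pixel_size required for {path}")
    if offset is None:
        offset = tuple(meta.get("offset", (0.0, 0.0)))
    if channel_map is None and "channels" in meta:
        channel_map = {int(k): v for k, v in meta["channels"].items()}

    data = tifffile.imread(path)
    if data.ndim == 2:
        channel = channel_map.get(0, "psyn") if channel_map else "psyn"
        return FieldImage(data, channel, pixel_size, offset, image_id=path.stem)
    if channel_map is not None:
        n = data.shape[0]
        images = []
        for page, channel in sorted(channel_map.items()):
            if not 0 <= page < n:
                raise ValueError(f"channel map page {page} outside stack of {n}")
            images.append(
                FieldImage(data[page], channel, pixel_size, offset, image_id=path.stem)
            )
        return images
    return data


def write_field_tiff(path, *images: FieldImage) -> None:
    """Write channel images as a multi-page TIFF with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, np.stack([im.data for im in images]), photometric="minisblack"
    )
    meta = {
        "pixel_size": images[0].pixel_size,
        "offset": list(images[0].offset),
        "channels": {i: im.channel for i, im in enumerate(images)},
    }
    _atomic_write_text(path.with_name(path.name + ".json"), json.dumps(meta, indent=2))


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    _atomic_write_text(path, df.to_csv(index=False))


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """YAML-backed configuration for the file-based runners."""

    assay: str  # quantify | cfse | kymo | synth | stats
    out_dir: str = "."
    geometry_path: str | None = None
    manifest_path: str | None = None  # CSV of per-field image paths
    seg_params: seg.SegmentationParams = field(default_factory=seg.SegmentationParams)
    tubulin_params: seg.SegmentationParams | None = None
    cfse_params: seg.SegmentationParams | None = None
    band_um: tuple[float, float] = MAIN_BAND_UM
    grubbs_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seg_params" in raw:
            raw["seg_params"] = seg.SegmentationParams(**raw["seg_params"])
        if raw.get("tubulin_params"):
            raw["tubulin_params"] = seg.SegmentationParams(**raw["tubulin_params"])
        if raw.get("cfse_params"):
            raw["cfse_params"] = seg.SegmentationParams(**raw["cfse_params"])
        if "band_um" in raw:
            raw["band_um"] = tuple(raw["band_um"])
        return cls(**raw)

    def echo(self, out_dir: Path) -> None:
        payload = dataclasses.asdict(self)
        _atomic_write_text(out_dir / "run_config.yaml", yaml.safe_dump(payload))


# --------------------------------------------------------------------------
# in-memory assay cores


def quantify_field(
    psyn: FieldImage,
    tubulin: FieldImage,
    geometry: DeviceGeometry,
    params: seg.SegmentationParams,
    *,
    tubulin_params: seg.SegmentationParams | None = None,
    band_um: tuple[float, float] = MAIN_BAND_UM,
    chamber: str | None = None,
    compute_length: bool = True,
):
    """Full detection chain for one field; returns (metrics, fragments).

    ``tubulin_params`` allows a separate threshold for the neurite channel
    (needed with manual levels; per-image Otsu adapts on its own).
    """
    tubulin_params = tubulin_params or params
    psyn_mask = seg.threshold_mask(psyn, params)
    tub_mask = seg.threshold_mask(tubulin, tubulin_params)
    log.info(
        "field %s: psyn threshold=%s tubulin threshold=%s",
        psyn.image_id,
        seg.applied_threshold(psyn, params),
        seg.applied_threshold(tubulin, tubulin_params),
    )
    fragments = seg.extract_fragments(
        psyn_mask,
        tub_mask,
        geometry,
        params,
        pixel_size=psyn.pixel_size,
        offset=psyn.offset,
        image_id=psyn.image_id,
        compute_length=compute_length,
    )
    if chamber is None:
        mid_x = psyn.offset[0] + psyn.shape[1] * psyn.pixel_size / 2
        chamber = geometry.chamber_of(mid_x)
    roi = make_roi_mask(geometry, RoiBand(chamber, band_um), psyn)
    metrics = q.summarize_field(
        fragments, roi, tub_mask, geometry,
        pixel_size=psyn.pixel_size, image_id=psyn.image_id,
    )
    return metrics, fragments


def quantify_study(
    study: StudyDataset,
    geometry: DeviceGeometry | None = None,
    params: seg.SegmentationParams | None = None,
    *,
    tubulin_params: seg.SegmentationParams | None = None,
    band_um: tuple[float, float] | None = None,
    alpha: float = 0.05,
    compute_length: bool = False,
):
    """Run the quantification assay over an in-memory synthetic study.

    Returns ``(device_table, field_table, fragment_table)`` where the
    device table holds one Grubbs-filtered chamber median per device plus
    its truth columns, ready for trend regression.
    """
    cfg = study.config
    geometry = geometry or DeviceGeometry(pixel_size=cfg.pixel_size_um)
    params = params or seg.SegmentationParams()
    dev_rows, field_rows, frag_tables = [], [], []
    for dev in study.devices:
        metrics_list = []
        for fd in dev.fields:
            band = _band_covering(fd.psyn, geometry) if band_um is None else band_um
            try:
                metrics, fragments = quantify_field(
                    fd.psyn, fd.tubulin, geometry, params,
                    tubulin_params=tubulin_params,
                    band_um=band, compute_length=compute_length,
                )
            except Exception as exc:  # stage error aborts the field, run continues
                log.error("device %s field %s failed: %s", dev.device_id, fd.image_id, exc)
                continue
            metrics_list.append(metrics)
            field_rows.append(
                {
                    "device_id": dev.device_id,
                    "t_weeks": dev.t_weeks,
                    "seeded": dev.seeded,
                    **dataclasses.asdict(metrics),
                }
            )
            ft = seg.fragments_to_table(fragments)
            if not ft.empty:
                ft.insert(0, "device_id", dev.device_id)
                frag_tables.append(ft)
        if len(metrics_list) < 3:
            log.error("device %s: fewer than 3 usable fields, skipped", dev.device_id)
            continue
        summary = q.aggregate_chamber(
            metrics_list, alpha, device_id=dev.device_id, chamber="forward"
        )
        dev_rows.append(
            {
                "device_id": dev.device_id,
                "t_weeks": dev.t_weeks,
                "seeded": dev.seeded,
                "n_fields": summary.n_fields,
                "area_per_qmm2": summary.medians["area_per_qmm2"],
                "frags_per_qmm2": summary.medians["frags_per_qmm2"],
                "pct_neurite": summary.medians["pct_neurite"],
                "excluded_fields": ";".join(
                    sorted({i for ids in summary.excluded.values() for i in ids})
                ),
                "expected_area_per_qmm2": dev.expected_area_per_qmm2,
                "expected_count_per_qmm2": dev.expected_count_per_qmm2,
            }
        )
    device_table = pd.DataFrame(dev_rows)
    field_table = pd.DataFrame(field_rows)
    fragment_table = (
        pd.concat(frag_tables, ignore_index=True) if frag_tables else pd.DataFrame()
    )
    return device_table, field_table, fragment_table


def _band_covering(image: FieldImage, geometry: DeviceGeometry) -> tuple[float, float]:
    """Distance band spanned by an image (used when no band is forced)."""
    from .geometry import distance_to_barrier

    x = image.x_centers()
    d = distance_to_barrier(x, geometry)
    return (float(d.min()), float(d.max()))


def cfse_study(
    study: StudyDataset,
    geometry: DeviceGeometry | None = None,
    params: seg.SegmentationParams | None = None,
    cfse_params: seg.SegmentationParams | None = None,
    *,
    tubulin_params: seg.SegmentationParams | None = None,
    band_um: tuple[float, float] = NEAR_BAND_UM,
):
    """CFSE transport-vs-transfer quantification over a synthetic study.

    Restricts to the near-channel band, classifies each fragment against
    the thresholded CFSE channel, and reports CFSE-positive and -negative
    area and count per 0.25 mm² per device.  Fields lacking a CFSE channel
    are a hard error.
    """
    cfg = study.config
    geometry = geometry or DeviceGeometry(pixel_size=cfg.pixel_size_um)
    params = params or seg.SegmentationParams()
    cfse_params = cfse_params or params
    tubulin_params = tubulin_params or params
    rows = []
    for dev in study.devices:
        pos_area = neg_area = 0.0
        pos_n = neg_n = 0
        roi_mm2 = 0.0
        for fd in dev.fields:
            if fd.cfse is None:
                raise ValueError(f"field {fd.image_id} has no CFSE channel")
            psyn_mask = seg.threshold_mask(fd.psyn, params)
            tub_mask = seg.threshold_mask(fd.tubulin, tubulin_params)
            cfse_mask = seg.threshold_mask(fd.cfse, cfse_params)
            fragments = seg.extract_fragments(
                psyn_mask, tub_mask, geometry, params,
                pixel_size=fd.psyn.pixel_size, offset=fd.psyn.offset,
                image_id=fd.image_id, compute_length=False,
            )
            seg.classify_cfse(fragments, cfse_mask, params, band_um=band_um)
            chamber = geometry.chamber_of(
                fd.psyn.offset[0] + fd.psyn.shape[1] * fd.psyn.pixel_size / 2
            )
            roi = make_roi_mask(geometry, RoiBand(chamber, band_um), fd.psyn)
            roi_mm2 += roi.sum() * fd.psyn.pixel_size**2 / 1e6
            for frag in fragments:
                if frag.cfse_status == "positive":
                    pos_area += frag.area_um2
                    pos_n += 1
                elif frag.cfse_status == "negative":
                    neg_area += frag.area_um2
                    neg_n += 1
        if roi_mm2 == 0:
            continue
        scale = 0.25 / roi_mm2
        rows.append(
            {
                "device_id": dev.device_id,
                "t_weeks": dev.t_weeks,
                "seeded": dev.seeded,
                "cfse_pos_area_per_qmm2": pos_area * scale,
                "cfse_neg_area_per_qmm2": neg_area * scale,
                "cfse_pos_frags_per_qmm2": pos_n * scale,
                "cfse_neg_frags_per_qmm2": neg_n * scale,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty and (table[["cfse_pos_frags_per_qmm2", "cfse_neg_frags_per_qmm2"]].to_numpy().sum() == 0):
        log.warning("no fragments within the %s µm band", band_um)
    return table


def kymo_movie(
    movie: np.ndarray,
    geometry: DeviceGeometry,
    *,
    frame_interval_s: float,
    pixel_size: float | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
    lanes_um: list[tuple[float, float]] | None = None,
    params: TraceParams | None = None,
):
    """Per-lane kymograph + trace analysis of a movie stack.

    Returns ``(traces_table, kymographs)``.  Lanes default to the geometry's
    channel lanes; having none is an error.
    """
    lanes = lanes_um if lanes_um is not None else geometry.channel_lanes
    if not lanes:
        raise ValueError("no lanes defined")
    params = params or TraceParams()
    rows, kymos = [], []
    for li, lane in enumerate(lanes):
        kymo = build_kymograph(
            movie, lane, geometry,
            frame_interval_s=frame_interval_s,
            pixel_size=pixel_size, offset=offset, lane_id=f"lane{li:02d}",
        )
        kymos.append(kymo)
        for ti, trace in enumerate(detect_traces(kymo, params)):
            rows.append(
                {
                    "trace_id": f"lane{li:02d}_t{ti:02d}",
                    "lane": kymo.lane_id,
                    "n_frames": len(trace.times_s),
                    "speed_um_s": trace.speed_um_s,
                    "direction": trace.direction,
                    "exited": trace.exited_barrier,
                    "t_start_s": float(trace.times_s[0]),
                    "t_end_s": float(trace.times_s[-1]),
                }
            )
    columns = [
        "trace_id", "lane", "n_frames", "speed_um_s", "direction",
        "exited", "t_start_s", "t_end_s",
    ]
    return pd.DataFrame(rows, columns=columns), kymos


# --------------------------------------------------------------------------
# file-based runners


def _prepare(config: RunConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    geometry = (
        load_geometry(config.geometry_path)
        if config.geometry_path
        else DeviceGeometry()
    )
    config.echo(out)
    return out, geometry


def _read_manifest(config: RunConfig) -> pd.DataFrame:
    if not config.manifest_path:
        raise ValueError("manifest_path required")
    manifest = pd.read_csv(config.manifest_path)
    required = {"device_id", "chamber", "t_weeks", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def run_quantify(config: RunConfig):
    """File-based pathology quantification over a manifest of fields.

    The manifest CSV lists one multi-channel TIFF per field with columns
    ``device_id, chamber, t_weeks, path``.  Devices failing a stage are
    logged and skipped; others proceed.  Outputs: fragments.csv,
    field_metrics.csv, chamber_summaries.csv, stats.json.
    """
    out, geometry = _prepare(config)
    manifest = _read_manifest(config)
    frag_tables, field_rows, dev_rows = [], [], []
    for (device_id, chamber, t_weeks), group in manifest.groupby(
        ["device_id", "chamber", "t_weeks"]
    ):
        metrics_list = []
        try:
            for _, row in group.iterrows():
                images = read_stack(row["path"])
                by_channel = {im.channel: im for im in np.atleast_1d(images)}
                metrics, fragments = quantify_field(
                    by_channel["psyn"], by_channel["tubulin"], geometry,
                    config.seg_params, tubulin_params=config.tubulin_params,
                    band_um=config.band_um, chamber=chamber,
                )
                metrics_list.append(metrics)
                field_rows.append(
                    {"device_id": device_id, "chamber": chamber, "t_weeks": t_weeks,
                     **dataclasses.asdict(metrics)}
                )
                ft = seg.fragments_to_table(fragments)
                if not ft.empty:
                    ft.insert(0, "device_id", device_id)
                    frag_tables.append(ft)
            summary = q.aggregate_chamber(
                metrics_list, config.grubbs_alpha,
                device_id=str(device_id), chamber=str(chamber),
            )
        except Exception as exc:
            log.error("device %s/%s aborted: %s", device_id, chamber, exc)
            continue
        dev_rows.append(
            {
                "device_id": device_id, "chamber": chamber, "t_weeks": t_weeks,
                "n_fields": summary.n_fields,
                "area_per_qmm2": summary.medians["area_per_qmm2"],
                "frags_per_qmm2": summary.medians["frags_per_qmm2"],
                "pct_neurite": summary.medians["pct_neurite"],
                "excluded_fields": ";".join(
                    sorted({i for ids in summary.excluded.values() for i in ids})
                ),
            }
        )
    summaries = pd.DataFrame(dev_rows)
    _atomic_write_df(summaries, out / "chamber_summaries.csv")
    _atomic_write_df(pd.DataFrame(field_rows), out / "field_metrics.csv")
    _atomic_write_df(
        pd.concat(frag_tables, ignore_index=True) if frag_tables else pd.DataFrame(),
        out / "fragments.csv",
    )
    stats_report = {}
    if len(summaries) >= 3 and summaries["t_weeks"].nunique() > 1:
        trend = q.linear_trend(summaries["t_weeks"], summaries["area_per_qmm2"])
        stats_report["area_trend"] = dataclasses.asdict(trend)
    _atomic_write_text(out / "stats.json", json.dumps(stats_report, indent=2))
    return summaries


def run_cfse(config: RunConfig):
    """File-based CFSE transport-vs-transfer assay (reverse chamber, ≤400 µm)."""
    out, geometry = _prepare(config)
    manifest = _read_manifest(config)
    params = config.seg_params
    cfse_params = config.cfse_params or params
    band = config.band_um if config.band_um != MAIN_BAND_UM else NEAR_BAND_UM
    rows = []
    for device_id, group in manifest.groupby("device_id"):
        pos_area = neg_area = 0.0
        pos_n = neg_n = 0
        roi_mm2 = 0.0
        for _, row in group.iterrows():
            images = read_stack(row["path"])
            by_channel = {im.channel: im for im in np.atleast_1d(images)}
            if "cfse" not in by_channel:
                raise ValueError(f"{row['path']}: missing CFSE channel")
            psyn_mask = seg.threshold_mask(by_channel["psyn"], params)
            tub_mask = seg.threshold_mask(
                by_channel["tubulin"], config.tubulin_params or params
            )
            cfse_mask = seg.threshold_mask(by_channel["cfse"], cfse_params)
            fragments = seg.extract_fragments(
                psyn_mask, tub_mask, geometry, params,
                pixel_size=by_channel["psyn"].pixel_size,
                offset=by_channel["psyn"].offset,
                image_id=str(row["path"]),
                compute_length=False,
            )
            seg.classify_cfse(fragments, cfse_mask, params, band_um=band)
            roi = make_roi_mask(
                geometry, RoiBand(str(row["chamber"]), band), by_channel["psyn"]
            )
            roi_mm2 += roi.sum() * by_channel["psyn"].pixel_size**2 / 1e6
            for frag in fragments:
                if frag.cfse_status == "positive":
                    pos_area += frag.area_um2
                    pos_n += 1
                elif frag.cfse_status == "negative":
                    neg_area += frag.area_um2
                    neg_n += 1
        if roi_mm2 == 0:
            log.warning("device %s: empty ROI, skipped", device_id)
            continue
        scale = 0.25 / roi_mm2
        rows.append(
            {
                "device_id": device_id,
                "cfse_pos_area_per_qmm2": pos_area * scale,
                "cfse_neg_area_per_qmm2": neg_area * scale,
                "cfse_pos_frags_per_qmm2": pos_n * scale,
                "cfse_neg_frags_per_qmm2": neg_n * scale,
            }
        )
    table = pd.DataFrame(rows)
    _atomic_write_df(table, out / "cfse_summary.csv")
    return table


def run_kymo(config: RunConfig):
    """File-based kymograph assay over a manifest of movie TIFFs."""
    out, geometry = _prepare(config)
    if not config.manifest_path:
        raise ValueError("manifest_path required")
    manifest = pd.read_csv(config.manifest_path)
    if "path" not in manifest.columns:
        raise ValueError("manifest missing 'path' column")
    all_rows = []
    for _, row in manifest.iterrows():
        movie = read_stack(row["path"])
        sidecar = json.loads(
            Path(str(row["path"]) + ".json").read_text()
        ) if Path(str(row["path"]) + ".json").exists() else {}
        if "pixel_size" not in sidecar:
            raise ValueError(f"pixel_size required for {row['path']}")
        dt = float(row.get("frame_interval_s", sidecar.get("frame_interval_s", 5.0)))
        traces, kymos = kymo_movie(
            np.asarray(movie),
            geometry,
            frame_interval_s=dt,
            pixel_size=sidecar["pixel_size"],
            offset=tuple(sidecar.get("offset", (0.0, 0.0))),
        )
        traces.insert(0, "movie", Path(str(row["path"])).stem)
        all_rows.append(traces)
        for kymo in kymos:
            tifffile.imwrite(
                out / f"{Path(str(row['path'])).stem}_{kymo.lane_id}_kymograph.tif",
                np.nan_to_num(kymo.data).astype(np.float32),
            )
    table = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    _atomic_write_df(table, out / "traces.csv")
    return table
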