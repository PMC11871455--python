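"""Orchestration: simulate experiments to disk, analyze stacks to tables.

``run_simulate`` writes one multichannel TIFF per field (CTYX axis order)
plus the ground-truth table, the kinase activity traces, a JSON sidecar
with the full configuration, and a manifest recording the config hash and
library versions — enough to reproduce or audit any run.

``run_analyze`` is the measurement pipeline: register each stack on the
marker channel, segment nuclei from the ER rim, derive cytoplasm
compartments, optionally place random ROI-disk pairs, extract per-cell
C/N traces for every KTR channel, and write tidy CSV tables, a JSON stats
report and summary figures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .experiment import ExperimentConfig, run_experiment
from .imaging import ImageStack
from .quantification import extract_traces, register_stack, traces_to_frame
from .segmentation import derive_compartments, place_roi_pairs, segment_nuclei
from .stats import aggregate, response_metrics

__all__ = ["run_simulate", "run_analyze", "load_config", "load_stack"]

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment config from JSON.

    Validation errors from the schema include the offending field paths.
    """
    return ExperimentConfig.model_validate_json(Path(path).read_text())


def _config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_simulate(config: ExperimentConfig, outdir: str | Path) -> dict:
    """Render the configured experiment to ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    (outdir / "fields").mkdir(parents=True, exist_ok=True)
    results, activities = run_experiment(config)

    field_files = []
    gt_frames = []
    for res in results:
        fname = f"field_{res.field_index:02d}.tif"
        tifffile.imwrite(
            outdir / "fields" / fname,
            res.stack.pixels,
            metadata={"axes": "CTYX", "channels": res.stack.channel_names},
        )
        field_files.append(fname)
        gtf = res.ground_truth.to_frame()
        gtf.insert(0, "field", res.field_index)
        gt_frames.append(gtf)
        drift_df = pd.DataFrame(res.ground_truth.drift, columns=["dy", "dx"])
        drift_df.insert(0, "frame", np.arange(len(drift_df)))
        drift_df.insert(0, "field", res.field_index)
        gtf_path = outdir / f"drift_field_{res.field_index:02d}.csv"
        drift_df.to_csv(gtf_path, index=False)
    pd.concat(gt_frames, ignore_index=True).to_csv(outdir / "ground_truth.csv", index=False)

    act_rows = []
    for k, tr in activities.items():
        for ti, ai in zip(tr.t, tr.a):
            act_rows.append({"t_min": ti, "kinase_or_sensor": k, "value": ai})
    pd.DataFrame(act_rows).to_csv(outdir / "activities.csv", index=False)

    (outdir / "config.json").write_text(config.model_dump_json(indent=2))
    manifest = {
        "ktrkit_version": __version__,
        "numpy_version": np.__version__,
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "fields": field_files,
        "channels": results[0].stack.channel_names if results else [],
        "dt_min": config.dt_min,
        "schedule": [json.loads(e.model_dump_json()) for e in config.schedule],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_stack(
    path: str | Path, channel_names: list[str] | None = None, dt_min: float = 1.0
) -> ImageStack:
    """Read a CTYX multichannel TIFF into an :class:`ImageStack`."""
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pixels.ndim == 3:
        pixels = pixels[:, None]  # single frame
    if channel_names is None:
        channel_names = meta.get("channels")
    if channel_names is None:
        raise ValueError(
            f"{path}: no channel names in TIFF metadata; pass channel_names"
        )
    return ImageStack(
        pixels=pixels.astype(np.uint16),
        channel_names=list(channel_names),
        dt_min=dt_min,
    )


def run_analyze(
    indir: str | Path,
    outdir: str | Path,
    *,
    marker_channel: str = "ER_marker",
    ktr_channels: list[str] | None = None,
    background_mode: str | float = "mode",
    roi_mode: str = "masks",
    roi_radius_px: int = 5,
    min_cells: int = 10,
    seed: int = 0,
    guard_px: int = 2,
    max_radius_px: int = 40,
    make_figures: bool = True,
) -> pd.DataFrame:
    """Analyze every field stack under ``indir``; returns the measurement table."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "labels").mkdir(exist_ok=True)

    manifest = {}
    mpath = indir / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    dt_min = float(manifest.get("dt_min", 1.0))
    channels = manifest.get("channels")
    stack_paths = sorted((indir / "fields").glob("*.tif")) or sorted(indir.glob("*.tif"))
    if not stack_paths:
        raise FileNotFoundError(f"no TIFF stacks found under {indir}")

    all_rows = []
    offsets_rows = []
    roi_rows = []
    for fi, spath in enumerate(stack_paths):
        stack = load_stack(spath, channel_names=channels, dt_min=dt_min)
        if marker_channel not in stack.channel_names:
            raise KeyError(
                f"{spath}: marker channel {marker_channel!r} not in "
                f"{stack.channel_names}"
            )
        offsets, corrected = register_stack(stack, marker_channel)
        for f, (dy, dx) in enumerate(offsets):
            offsets_rows.append({"field": fi, "frame": f, "dy": int(dy), "dx": int(dx)})
        marker0 = corrected.channel(marker_channel)[0]
        nuclei = segment_nuclei(marker0, mode="er_rim")
        labels = derive_compartments(
            nuclei, marker0, guard_px=guard_px, max_radius_px=max_radius_px
        )
        tifffile.imwrite(outdir / "labels" / f"{spath.stem}_nuclei.tif",
                         labels.nucleus_labels.astype(np.uint16))
        tifffile.imwrite(outdir / "labels" / f"{spath.stem}_cyto.tif",
                         labels.cytoplasm_labels.astype(np.uint16))
        pairs = None
        if roi_mode == "disks":
            pairs = place_roi_pairs(labels, radius_px=roi_radius_px, rng_seed=seed + fi)
            for p in pairs:
                for comp, disk in (("nucleus", p.nuc_disk), ("cytoplasm", p.cyto_disk)):
                    roi_rows.append({"field": fi, "cell_id": p.cell_id,
                                     "compartment": comp, "cy": disk[0],
                                     "cx": disk[1], "r": disk[2]})
        targets = ktr_channels or [
            ch for ch in stack.channel_names
            if ch != marker_channel and not ch.lower().startswith("gcamp")
        ]
        for ch in targets:
            traces = extract_traces(
                corrected, labels, ch, roi_pairs=pairs,
                background_mode=background_mode, marker_channel=marker_channel,
            )
            df = traces_to_frame(traces, dt_min=dt_min, field=fi)
            if len(df):
                df.insert(1, "channel", ch)
            all_rows.append(df)

    columns = ["field", "channel", "cell_id", "frame", "t_min", "c_mean",
               "n_mean", "cn_ratio", "c_over_total", "valid"]
    non_empty = [d for d in all_rows if len(d)]
    measurements = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty else pd.DataFrame(columns=columns)
    )
    measurements.to_csv(outdir / "measurements.csv", index=False)
    pd.DataFrame(offsets_rows).to_csv(outdir / "registration_offsets.csv", index=False)
    if roi_rows:
        pd.DataFrame(roi_rows).to_csv(outdir / "roi_pairs.csv", index=False)

    report: dict = {"n_fields": len(stack_paths), "channels": {}}
    events = manifest.get("schedule", [])
    first_event_t = min((e["time_min"] for e in events), default=None)
    summary_rows = []
    for ch, chdf in measurements.groupby("channel") if len(measurements) else []:
        summaries = aggregate(chdf, image_by="field", min_cells=min_cells)
        s = summaries[0]
        entry = {"n_images": s.n_units, "mean_cn": s.mean, "sem_cn": s.sem}
        summary_rows.append({"channel": ch, **entry})
        if first_event_t is not None and first_event_t > 0:
            per_field = (
                chdf[chdf["valid"]]
                .groupby(["field", "t_min"])["cn_ratio"].mean().unstack("t_min")
            )
            if per_field.shape[0] >= 1 and per_field.notna().all(None):
                rm = response_metrics(
                    per_field.to_numpy(), per_field.columns.to_numpy(dtype=float),
                    first_event_t,
                )
                entry["response"] = {
                    "baseline_cn": rm.baseline_cn,
                    "plateau_cn": rm.plateau_cn,
                    "plateau_fold": rm.plateau_fold,
                    "t_signif_min": rm.t_signif,
                    "t_half_min": rm.t_half,
                }
        report["channels"][ch] = entry
    pd.DataFrame(summary_rows).to_csv(outdir / "summary.csv", index=False)
    (outdir / "stats_report.json").write_text(json.dumps(report, indent=2))

    if make_figures and len(measurements):
        _figures(measurements, events, outdir)
    return measurements


def _figures(measurements: pd.DataFrame, events: list[dict], outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    (outdir / "figures").mkdir(exist_ok=True)
    valid = measurements[measurements["valid"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    for ch, chdf in valid.groupby("channel"):
        m = chdf.groupby("t_min")["cn_ratio"].mean()
        sem = chdf.groupby("t_min")["cn_ratio"].sem()
        ax.plot(m.index, m.values, label=ch)
        ax.fill_between(m.index, m - sem, m + sem, alpha=0.25)
    for e in events:
        ax.axvline(e["time_min"], color="gray", ls="--", lw=0.8)
        ax.text(e["time_min"], ax.get_ylim()[1], e["agent"], fontsize=7,
                rotation=90, va="top")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("C/N ratio")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "figures" / "cn_traces.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    per_field = valid.groupby(["channel", "field"])["cn_ratio"].mean().reset_index()
    agg = per_field.groupby("channel")["cn_ratio"].agg(["mean", "sem"])
    ax.bar(agg.index, agg["mean"], yerr=agg["sem"], capsize=4, color="#888")
    ax.set_ylabel("C/N ratio (mean over fields ± SEM)")
    fig.tight_layout()
    fig.savefig(outdir / "figures" / "cn_by_channel.png", dpi=150)
    plt.close(fig)
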