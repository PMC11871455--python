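"""Per-cell C/N measurement: registration, intensity extraction, traces.

The readout of a KTR experiment is the cytoplasm-to-nucleus fluorescence
ratio of each cell: background-subtracted mean intensity over the
cytoplasmic region (or a sampled cytoplasmic ROI disk) divided by the same
over the nuclear region. ``c_over_total`` = C/(C+N) is the bounded
alternative, a bijection of C/N (``cn = cot / (1 - cot)``).

Background handling is explicit because it changes ratios: the default
subtracts the per-frame mode of non-cell pixels; ``"none"`` reproduces a
raw-mean analysis. Time-lapse stacks are first registered by integer-pixel
cross-correlation on the marker channel, and each cell's trace carries a
validity flag from comparing its region between the first and last frame
(cells that drift away or detach are flagged and excluded from
aggregation by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .imaging import ImageStack, shift_integer
from .segmentation import LabelMaps, RoiPair, disk_mask

__all__ = [
    "CnMeasurement",
    "CnTrace",
    "register_stack",
    "measure_cn",
    "extract_traces",
    "estimate_background",
    "normalize_stain",
    "traces_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CnMeasurement:
    """One cell's compartment means and ratios in one frame.

    ``valid`` is False when either background-subtracted mean is
    nonpositive, in which case the ratio fields are NaN.
    """

    cell_id: int
    frame: int
    c_mean: float
    n_mean: float

    @property
    def valid(self) -> bool:
        return self.c_mean > 0 and self.n_mean > 0

    @property
    def cn_ratio(self) -> float:
        return self.c_mean / self.n_mean if self.valid else float("nan")

    @property
    def c_over_total(self) -> float:
        if not self.valid:
            return float("nan")
        return self.c_mean / (self.c_mean + self.n_mean)


@dataclass
class CnTrace:
    """One cell's C/N time course plus its first/last-frame validity flag."""

    cell_id: int
    frames: np.ndarray
    c_mean: np.ndarray
    n_mean: np.ndarray
    valid: bool = True

    @property
    def cn_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                (self.n_mean > 0) & (self.c_mean > 0), self.c_mean / self.n_mean, np.nan
            )

    @property
    def c_over_total(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            tot = self.c_mean + self.n_mean
            return np.where(
                (self.n_mean > 0) & (self.c_mean > 0), self.c_mean / tot, np.nan
            )


def register_stack(
    stack: ImageStack, reference_channel: str = "ER_marker"
) -> tuple[np.ndarray, ImageStack]:
    """Estimate and remove rigid per-frame drift.

    Integer-pixel translation per frame is estimated against frame 0 by
    phase cross-correlation on the reference (marker) channel and applied
    identically to all channels. Returns ``(offsets, corrected)`` where
    ``offsets[f]`` is the estimated (dy, dx) displacement of frame ``f``.
    A featureless frame yields a zero offset and a warning.
    """
    ref = stack.channel(reference_channel).astype(float)
    n_frames = stack.n_frames
    if n_frames < 2:
        raise ValueError("registration needs at least two frames")
    offsets = np.zeros((n_frames, 2), dtype=int)
    frame0 = ref[0]
    for f in range(1, n_frames):
        if ref[f].std() == 0 or frame0.std() == 0:
            warnings.warn(f"frame {f}: featureless image, assuming zero drift")
            continue
        shift, _, _ = phase_cross_correlation(frame0, ref[f], upsample_factor=1)
        offsets[f] = np.rint(shift).astype(int) * -1  # displacement of frame f
    corrected = np.empty_like(stack.pixels)
    for f in range(n_frames):
        dy, dx = -offsets[f]
        for c in range(stack.pixels.shape[0]):
            fill = int(np.median(stack.pixels[c, f]))
            corrected[c, f] = shift_integer(stack.pixels[c, f], dy, dx, fill=fill)
    out = ImageStack(
        pixels=corrected,
        channel_names=list(stack.channel_names),
        dt_min=stack.dt_min,
        pixel_size_um=stack.pixel_size_um,
    )
    return offsets, out


def estimate_background(
    frame: np.ndarray, labels: LabelMaps, mode: str | float = "mode"
) -> float:
    """Background level from non-cell pixels of one frame.

    ``"mode"`` (default): most frequent integer count outside all cells;
    ``"median"``: their median; ``"none"``: 0; a number: used as-is.
    """
    if isinstance(mode, (int, float)) and not isinstance(mode, bool):
        return float(mode)
    if mode == "none":
        return 0.0
    bg_px = frame[(labels.nucleus_labels == 0) & (labels.cytoplasm_labels == 0)]
    if bg_px.size == 0:
        warnings.warn("no background pixels; assuming background 0")
        return 0.0
    if mode == "median":
        return float(np.median(bg_px))
    if mode == "mode":
        counts = np.bincount(np.asarray(bg_px, dtype=np.int64).ravel())
        return float(np.argmax(counts))
    raise ValueError(f"unknown background mode {mode!r}")


def measure_cn(
    frame: np.ndarray,
    nuc_mask: np.ndarray,
    cyto_mask: np.ndarray,
    background: float = 0.0,
    *,
    cell_id: int = 0,
    frame_idx: int = 0,
) -> CnMeasurement:
    """Background-subtracted compartment means and C/N for one cell/frame."""
    if background < 0:
        raise ValueError("background must be nonnegative")
    if not nuc_mask.any() or not cyto_mask.any():
        raise ValueError(f"cell {cell_id}: empty compartment ROI")
    c_mean = float(frame[cyto_mask].mean()) - background
    n_mean = float(frame[nuc_mask].mean()) - background
    return CnMeasurement(cell_id=cell_id, frame=frame_idx, c_mean=c_mean, n_mean=n_mean)


def _roi_masks(
    pair: RoiPair, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    nm = disk_mask(shape, pair.nuc_disk[:2], pair.nuc_disk[2])
    cm = disk_mask(shape, pair.cyto_disk[:2], pair.cyto_disk[2])
    return nm, cm


def extract_traces(
    stack: ImageStack,
    labels: LabelMaps,
    channel: str,
    *,
    roi_pairs: list[RoiPair] | None = None,
    background_mode: str | float = "mode",
    marker_channel: str = "ER_marker",
    presence_ratio: float = 0.5,
) -> list[CnTrace]:
    """Per-cell C/N time courses from a registered stack.

    Measurement support is the whole compartment mask per cell, or the
    sampled ROI disks when ``roi_pairs`` is given. A cell is flagged
    invalid when the mean marker signal over its nuclear region at the
    last frame falls below ``presence_ratio`` of its first-frame value
    (the cell left its ROI between the first and last frame), or when its
    ROI disks fall outside their compartments at either endpoint.
    """
    img = stack.channel(channel).astype(float)
    marker = stack.channel(marker_channel).astype(float)
    n_frames = stack.n_frames
    shape = img.shape[-2:]
    pair_by_id = {p.cell_id: p for p in roi_pairs} if roi_pairs is not None else None

    traces: list[CnTrace] = []
    for cid in labels.cell_ids:
        nuc_mask = labels.nucleus_labels == cid
        cyto_mask = labels.cytoplasm_labels == cid
        if pair_by_id is not None:
            if cid not in pair_by_id:
                logger.info("cell %d: no ROI pair, skipped", cid)
                continue
            meas_nuc, meas_cyto = _roi_masks(pair_by_id[cid], shape)
        else:
            meas_nuc, meas_cyto = nuc_mask, cyto_mask
        c_means = np.empty(n_frames)
        n_means = np.empty(n_frames)
        for f in range(n_frames):
            bg = estimate_background(img[f], labels, background_mode)
            m = measure_cn(img[f], meas_nuc, meas_cyto, bg, cell_id=cid, frame_idx=f)
            c_means[f], n_means[f] = m.c_mean, m.n_mean

        # first/last-frame presence check on the marker channel
        bg0 = estimate_background(marker[0], labels, background_mode)
        bgl = estimate_background(marker[-1], labels, background_mode)
        sig0 = marker[0][nuc_mask | cyto_mask].mean() - bg0
        sigl = marker[-1][nuc_mask | cyto_mask].mean() - bgl
        valid = sig0 > 0 and sigl >= presence_ratio * sig0
        if pair_by_id is not None and valid:
            valid = bool(
                (nuc_mask[meas_nuc]).all() and (cyto_mask[meas_cyto]).all()
            )
        if not valid:
            logger.info("cell %d flagged invalid by first/last-frame check", cid)
        traces.append(
            CnTrace(cell_id=cid, frames=np.arange(n_frames), c_mean=c_means, n_mean=n_means, valid=valid)
        )
    return traces


def normalize_stain(intensities: np.ndarray, control_mean: float) -> np.ndarray:
    """Normalise stain intensities to the mean of control cells.

    The control population maps to mean 1.0 by construction.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return np.asarray(intensities, dtype=float) / control_mean


def traces_to_frame(
    traces: list[CnTrace], dt_min: float = 1.0, *, field: str | int | None = None
) -> pd.DataFrame:
    """Tidy long-format table of traces (one row per cell and frame)."""
    rows = []
    for tr in traces:
        cn = tr.cn_ratio
        cot = tr.c_over_total
        for i, f in enumerate(tr.frames):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": int(f),
                    "t_min": float(f) * dt_min,
                    "c_mean": tr.c_mean[i],
                    "n_mean": tr.n_mean[i],
                    "cn_ratio": cn[i],
                    "c_over_total": cot[i],
                    "valid": tr.valid,
                }
            )
    df = pd.DataFrame(rows)
    if field is not None and len(df):
        df.insert(0, "field", field)
    return df
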