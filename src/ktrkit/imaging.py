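"""Synthetic fluorescence microscopy of KTR-expressing cell fields.

Renders the kinetic ground truth (per-cell nuclear/cytoplasmic sensor
concentrations over time) into multichannel 16-bit time-lapse stacks that
emulate adherent HEK293-like cells:

* an ER/nuclear-envelope marker channel: a bright rim around each nucleus
  plus a filamentous tubule texture in the cytoplasm — the single channel
  the segmentation stage uses to delineate both compartments;
* one KTR channel per sensor, nucleus and cytoplasm filled with the true
  concentrations;
* an optional cytoplasmic calcium-indicator (GCaMP) channel.

Pixel formation: expected counts = photon_gain * concentration + background,
then Poisson shot noise, then Gaussian read noise, clipped to the uint16
range. Rigid per-frame drift is applied as an integer-pixel translation
with constant-background padding. Every stack is paired with a
:class:`GroundTruth` carrying the true concentrations, C/N ratios, drift
and label masks, so measurement recovery can be scored exactly.

Pixel convention: 0-based (row, col); label images use 0 = background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .activities import PharmacologyTable, TreatmentEvent, hill
from .kinetics import KinaseActivityTrace

__all__ = [
    "CellGeometry",
    "NoiseModel",
    "ImageStack",
    "GroundTruth",
    "sample_field",
    "render_stack",
    "simulate_calcium",
    "random_walk_drift",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellGeometry:
    """An elliptical cell with an elliptical nucleus strictly inside it."""

    cell_id: int
    center: tuple[float, float]  # (row, col)
    cell_axes: tuple[float, float]  # semi-axes, px
    nucleus_axes: tuple[float, float]
    nucleus_offset: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.cell_id < 1:
            raise ValueError("cell_id must be >= 1")
        if min(self.cell_axes) <= 0 or min(self.nucleus_axes) <= 0:
            raise ValueError("axes must be positive")

    def _ellipse_mask(self, shape, center, axes) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dy = rr - center[0]
        dx = cc - center[1]
        cos, sin = math.cos(self.orientation), math.sin(self.orientation)
        u = dy * cos + dx * sin
        v = -dy * sin + dx * cos
        return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0

    def cell_mask(self, shape) -> np.ndarray:
        return self._ellipse_mask(shape, self.center, self.cell_axes)

    def nucleus_mask(self, shape) -> np.ndarray:
        center = (
            self.center[0] + self.nucleus_offset[0],
            self.center[1] + self.nucleus_offset[1],
        )
        return self._ellipse_mask(shape, center, self.nucleus_axes)


class NoiseModel(BaseModel):
    """Camera/photophysics model for rendering.

    ``photon_gain`` converts concentration units to expected counts;
    ``background`` is a uniform offset; shot noise is Poisson in the
    expected counts, followed by Gaussian read noise of ``read_sigma``
    counts. ``bleach_rate`` dims all fluorophores as exp(-rate * t).
    ``fixation_scale`` multiplies (cytoplasmic, nuclear) concentrations to
    emulate the compartment-asymmetric intensity distortion introduced by
    fixation, which artifactually shifts measured C/N ratios.
    """

    model_config = ConfigDict(frozen=True)

    photon_gain: float = Field(default=2000.0, gt=0)
    read_sigma: float = Field(default=3.0, ge=0)
    background: float = Field(default=100.0, ge=0)
    bleach_rate: float = Field(default=0.0, ge=0)
    poisson: bool = True
    fixation_scale: tuple[float, float] = (1.0, 1.0)


@dataclass
class ImageStack:
    """A multichannel time-lapse stack, CTYX order, unsigned 16-bit."""

    pixels: np.ndarray
    channel_names: list[str]
    dt_min: float = 1.0
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be channels x frames x height x width")
        if self.pixels.dtype != np.uint16:
            raise ValueError("pixels must be uint16")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError("channel_names length must equal channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.pixels[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None


@dataclass
class GroundTruth:
    """True per-cell concentrations, drift and masks paired with a stack.

    ``conc_n``/``conc_c`` are (n_cells, n_frames) arrays of the rendered
    nuclear/cytoplasmic concentrations per sensor channel; ``cn`` is their
    ratio. ``nucleus_labels``/``cyto_labels`` are the undrifted label maps;
    :meth:`labels_at` returns them shifted by the frame's drift.
    """

    cell_ids: list[int]
    conc_n: dict[str, np.ndarray]
    conc_c: dict[str, np.ndarray]
    drift: np.ndarray  # (n_frames, 2) int, (dy, dx)
    nucleus_labels: np.ndarray
    cyto_labels: np.ndarray

    @property
    def cn(self) -> dict[str, np.ndarray]:
        return {
            ch: self.conc_c[ch] / np.where(self.conc_n[ch] > 0, self.conc_n[ch], np.nan)
            for ch in self.conc_n
        }

    def labels_at(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        dy, dx = (int(v) for v in self.drift[frame])
        return (
            shift_integer(self.nucleus_labels, dy, dx, fill=0),
            shift_integer(self.cyto_labels, dy, dx, fill=0),
        )

    def to_frame(self):
        """Tidy per-(channel, cell, frame) table of the true concentrations."""
        import pandas as pd

        rows = []
        for ch in self.conc_n:
            for i, cid in enumerate(self.cell_ids):
                for f in range(self.conc_n[ch].shape[1]):
                    n = self.conc_n[ch][i, f]
                    rows.append(
                        {
                            "channel": ch,
                            "cell_id": cid,
                            "frame": f,
                            "conc_n": n,
                            "conc_c": self.conc_c[ch][i, f],
                            "cn_true": self.conc_c[ch][i, f] / n if n > 0 else np.nan,
                        }
                    )
        return pd.DataFrame(rows)


def shift_integer(img: np.ndarray, dy: int, dx: int, fill=0) -> np.ndarray:
    """Translate an image by whole pixels, padding with ``fill``."""
    out = np.full_like(img, fill)
    h, w = img.shape[-2:]
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[..., ys, xs] = img[..., ys_src, xs_src]
    return out


def random_walk_drift(
    n_frames: int, seed: int, step_sigma: float = 1.0, max_px: int = 10
) -> np.ndarray:
    """Integer random-walk stage drift, clipped to ±max_px, first frame at 0."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sigma, size=(n_frames, 2))
    steps[0] = 0.0
    walk = np.clip(np.cumsum(steps, axis=0), -max_px, max_px)
    return np.rint(walk).astype(int)


def sample_field(
    rng_seed: int,
    n_cells: int,
    field_px: tuple[int, int] = (512, 512),
    *,
    cell_radius_px: tuple[float, float] = (24.0, 34.0),
    nucleus_frac: tuple[float, float] = (0.40, 0.52),
    margin_px: int = 12,
    max_tries: int = 2000,
) -> list[CellGeometry]:
    """Place non-overlapping elliptical cells in a field by rejection sampling.

    Deterministic for a fixed seed. Cells are kept ``margin_px`` away from
    the field border so that moderate stage drift cannot truncate them.

    Raises
    ------
    RuntimeError
        If ``n_cells`` cannot be placed within ``max_tries`` proposals.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = field_px
    occupied = np.zeros((h, w), dtype=bool)
    out: list[CellGeometry] = []
    tries = 0
    while len(out) < n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_cells} cells in a {h}x{w} field "
                f"after {max_tries} proposals (placed {len(out)})"
            )
        tries += 1
        a = rng.uniform(*cell_radius_px)
        b = rng.uniform(0.75, 1.0) * a
        theta = rng.uniform(0, math.pi)
        lim = max(a, b) + margin_px
        if 2 * lim >= min(h, w):
            raise RuntimeError("field too small for the requested cell size")
        cy = rng.uniform(lim, h - lim)
        cx = rng.uniform(lim, w - lim)
        na = rng.uniform(*nucleus_frac) * a
        nb = rng.uniform(*nucleus_frac) * b
        # nucleus offset bounded so the nucleus stays strictly inside the cell
        max_off = 0.25 * (min(a, b) - max(na, nb))
        off = rng.uniform(-max_off, max_off, size=2) if max_off > 0 else np.zeros(2)
        geom = CellGeometry(
            cell_id=len(out) + 1,
            center=(cy, cx),
            cell_axes=(a, b),
            nucleus_axes=(na, nb),
            nucleus_offset=(float(off[0]), float(off[1])),
            orientation=float(theta),
        )
        mask = geom.cell_mask((h, w))
        # 2-px exclusion halo keeps neighbours separable
        from scipy.ndimage import binary_dilation

        halo = binary_dilation(mask, iterations=2)
        if (halo & occupied).any():
            continue
        occupied |= halo
        out.append(geom)
    return out


def _er_texture(shape: tuple[int, int], seed: int) -> np.ndarray:
    """Filamentous band-limited texture in [0, 1] for the ER tubule pattern.

    Cosmetic: thresholded smoothed noise, not an optical model.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.normal(size=shape), sigma=2.0)
    ridges = np.abs(noise) < 0.35 * noise.std()
    return 0.35 + 0.65 * ridges.astype(float)


def _label_maps(
    geometries: list[CellGeometry], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    nuc = np.zeros(shape, dtype=np.uint16)
    cyto = np.zeros(shape, dtype=np.uint16)
    for g in geometries:
        cm = g.cell_mask(shape)
        nm = g.nucleus_mask(shape)
        cyto[cm & ~nm] = g.cell_id
        nuc[nm] = g.cell_id
    return nuc, cyto


def render_stack(
    geometries: list[CellGeometry],
    sensor_traces: dict[str, tuple[np.ndarray, np.ndarray]],
    noise: NoiseModel,
    *,
    field_px: tuple[int, int] = (512, 512),
    dt_min: float = 1.0,
    pixel_size_um: float = 0.5,
    calcium_trace: np.ndarray | None = None,
    drift: np.ndarray | None = None,
    seed: int = 0,
    marker_channel: str = "ER_marker",
    calcium_channel: str = "GCaMP",
    er_rim_conc: float = 1.2,
    er_cyto_conc: float = 0.45,
    gcamp_conc_scale: float = 0.6,
) -> tuple[ImageStack, GroundTruth]:
    """Render geometry plus kinetic traces into a noisy multichannel stack.

    Parameters
    ----------
    sensor_traces
        Mapping channel name -> (conc_n, conc_c), each of shape
        (n_cells, n_frames), giving the true compartment concentration of
        that sensor in each cell at each frame.
    calcium_trace
        Optional per-frame calcium indicator level (whole-cell signal).
    drift
        Optional (n_frames, 2) integer (dy, dx) offsets; default none.

    Returns the stack and its paired :class:`GroundTruth`. Deterministic
    for fixed inputs and seed (same seed -> byte-identical pixels).
    """
    shape = field_px
    n_cells = len(geometries)
    frames = {cn.shape[1] for cn, _ in sensor_traces.values()}
    if len(frames) != 1:
        raise ValueError("all sensor traces must share a frame count")
    n_frames = frames.pop()
    for ch, (cn_, cc_) in sensor_traces.items():
        if cn_.shape != (n_cells, n_frames) or cc_.shape != (n_cells, n_frames):
            raise ValueError(f"trace shape mismatch for channel {ch!r}")
    if drift is None:
        drift = np.zeros((n_frames, 2), dtype=int)
    drift = np.asarray(drift, dtype=int)
    if calcium_trace is not None and len(calcium_trace) != n_frames:
        raise ValueError("calcium trace must be sampled on the frame grid")

    from scipy.ndimage import binary_dilation, binary_erosion

    nuc_labels, cyto_labels = _label_maps(geometries, shape)
    cell_region = (nuc_labels > 0) | (cyto_labels > 0)
    # ER marker: bright nuclear rim + textured cytoplasmic tubules
    nuc_bin = nuc_labels > 0
    rim = binary_dilation(nuc_bin, iterations=2) & ~binary_erosion(nuc_bin, iterations=1)
    er_img = np.zeros(shape, dtype=float)
    er_img[cyto_labels > 0] = er_cyto_conc
    er_img *= _er_texture(shape, seed=seed + 7)
    er_img[rim & cell_region] = er_rim_conc

    scale_c, scale_n = float(noise.fixation_scale[0]), float(noise.fixation_scale[1])

    channel_names = [marker_channel, *sensor_traces.keys()]
    if calcium_trace is not None:
        channel_names.append(calcium_channel)
    pixels = np.zeros((len(channel_names), n_frames, *shape), dtype=np.uint16)
    rng = np.random.default_rng(seed)
    n_saturated = 0
    for f in range(n_frames):
        bleach = math.exp(-noise.bleach_rate * f * dt_min)
        clean_channels = [er_img]
        for ch, (cn_, cc_) in sensor_traces.items():
            ln = np.concatenate([[0.0], cn_[:, f] * scale_n])
            lc = np.concatenate([[0.0], cc_[:, f] * scale_c])
            clean_channels.append(ln[nuc_labels] + lc[cyto_labels])
        if calcium_trace is not None:
            clean_channels.append(
                gcamp_conc_scale * float(calcium_trace[f]) * cell_region.astype(float)
            )
        dy, dx = (int(v) for v in drift[f])
        for c, conc_img in enumerate(clean_channels):
            shifted = shift_integer(conc_img, dy, dx, fill=0.0)
            expected = noise.photon_gain * bleach * shifted + noise.background
            if noise.poisson:
                img = rng.poisson(expected).astype(float)
            else:
                img = expected.copy()
            if noise.read_sigma > 0:
                img += rng.normal(0.0, noise.read_sigma, size=shape)
            n_saturated += int((img > 65535).sum())
            pixels[c, f] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    sat_frac = n_saturated / pixels.size
    if sat_frac > 0.01:
        logger.warning("%.1f%% of pixels saturated the 16-bit range", 100 * sat_frac)

    gt = GroundTruth(
        cell_ids=[g.cell_id for g in geometries],
        conc_n={ch: cn_.copy() for ch, (cn_, _) in sensor_traces.items()},
        conc_c={ch: cc_.copy() for ch, (_, cc_) in sensor_traces.items()},
        drift=drift.copy(),
        nucleus_labels=nuc_labels,
        cyto_labels=cyto_labels,
    )
    stack = ImageStack(
        pixels=pixels,
        channel_names=channel_names,
        dt_min=dt_min,
        pixel_size_um=pixel_size_um,
    )
    return stack, gt


def simulate_calcium(
    schedule: list[TreatmentEvent],
    pharm: PharmacologyTable,
    t_grid: np.ndarray,
    *,
    pka_activity: KinaseActivityTrace | None = None,
    baseline: float = 1.0,
) -> np.ndarray:
    """Cytoplasmic calcium-indicator trace under a treatment schedule.

    Purinergic stimulation (ATP) produces a transient spike that decays
    back to baseline within minutes; an ionophore (A23187) produces a
    sustained plateau. If a PKA activity trace is supplied, the indicator
    response is scaled by ``1 + (gcamp_pka_gain - 1) * a_PKA`` to model the
    PKA-dependent sensitisation of the indicator (default gain 1.5).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    c = np.full(t_grid.shape, float(baseline))
    for e in schedule:
        ph = pharm.lookup(e.agent)
        if ph.target != "calcium":
            continue
        occ = hill(e.dose_nm, ph.ec50_nm, ph.hill)
        dt_ = np.clip(t_grid - e.time_min, 0.0, None)
        active = t_grid >= e.time_min
        rise = 1.0 - np.exp(-dt_ / ph.tau_on)
        if ph.transient:
            shape = rise * np.exp(-dt_ / ph.tau_off)
        else:
            shape = rise
        c += baseline * ph.amplitude * occ * shape * active
    if pka_activity is not None:
        a = np.interp(t_grid, pka_activity.t, pka_activity.a)
        c *= 1.0 + (pharm.gcamp_pka_gain - 1.0) * a
    return np.maximum(c, 0.0)
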