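"""End-to-end synthetic KTR experiments: schedule -> kinetics -> rendered fields.

Builds the per-cell kinetic ground truth for a treatment schedule and
renders it into noisy multichannel fields. Cell-to-cell heterogeneity is
modelled as (i) a lognormal expression scale per cell, which moves
absolute intensities but not the C/N ratio, and (ii) a mild per-cell
scaling of the driving kinase activity, which spreads the C/N response —
the two dominant sources of between-cell variation in reporter imaging.

All randomness derives from the single experiment seed through named
:class:`numpy.random.SeedSequence` substreams, so a seed fully determines
every field, geometry, kinetic jitter and noise draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .activities import PharmacologyTable, TreatmentEvent, simulate_activities
from .imaging import (
    GroundTruth,
    ImageStack,
    NoiseModel,
    random_walk_drift,
    render_stack,
    sample_field,
    simulate_calcium,
)
from .kinetics import (
    KinaseActivityTrace,
    SensorSpec,
    TransportParams,
    leptomycin,
    simulate_cell,
    steady_state,
)

__all__ = ["ExperimentConfig", "FieldResult", "default_sensors", "run_experiment",
           "simulate_sensor_traces"]


def default_sensors() -> list[SensorSpec]:
    """The default dual-reporter pair: a mid-strength PKA sensor and a
    mid-strength ERK sensor, both large (tandem-dimer-sized) fusions."""
    return [
        SensorSpec(name="ePKA-KTR", nls_score=10.5, mw_kda=32.0, copies=2,
                   kinase="PKA", channel="KTR_PKA"),
        SensorSpec(name="eERK-KTR", nls_score=12.5, mw_kda=46.0, copies=1,
                   kinase="ERK", channel="KTR_ERK"),
    ]


class ExperimentConfig(BaseModel):
    """Full description of one synthetic imaging experiment."""

    model_config = ConfigDict(frozen=True)

    seed: int
    sensors: list[SensorSpec] = Field(default_factory=default_sensors)
    params: TransportParams = Field(default_factory=TransportParams)
    pharmacology: PharmacologyTable = Field(default_factory=PharmacologyTable)
    schedule: list[TreatmentEvent] = Field(
        default_factory=lambda: [
            TreatmentEvent(time_min=3.0, agent="Fsk", dose=3.0, dose_unit="uM"),
            TreatmentEvent(time_min=23.0, agent="H89", dose=50.0, dose_unit="uM"),
        ]
    )
    n_fields: int = Field(default=4, ge=1)
    n_cells: int = Field(default=12, ge=0)
    n_frames: int = Field(default=60, ge=1)
    dt_min: float = Field(default=1.0, gt=0)
    field_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    noise: NoiseModel = Field(default_factory=NoiseModel)
    include_calcium: bool = False
    drift_step_sigma: float = Field(default=0.0, ge=0)
    drift_max_px: int = Field(default=10, ge=0)
    expression_cv: float = Field(default=0.25, ge=0)
    activity_jitter: float = Field(default=0.08, ge=0)
    ode_dt_min: float = Field(default=0.05, gt=0)


@dataclass
class FieldResult:
    """One rendered field with its ground truth."""

    field_index: int
    stack: ImageStack
    ground_truth: GroundTruth


def _export_block_times(config: ExperimentConfig) -> list[float]:
    times = []
    for e in config.schedule:
        ph = config.pharmacology.lookup(e.agent)
        if ph.mode == "block_export" and e.dose_nm > 0:
            times.append(e.time_min)
    return sorted(times)


def simulate_sensor_traces(
    sensor: SensorSpec,
    activity: KinaseActivityTrace,
    params: TransportParams,
    *,
    export_block_at: list[float] | None = None,
    ode_dt: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Nuclear/cytoplasmic concentration of one sensor along an activity trace.

    Starts at the pre-treatment steady state. If an export blocker is
    scheduled, integration is split at the block time and continues with
    ``k_out = 0``. Returns (conc_n, conc_c) on the activity grid.
    """
    t = activity.t
    init = steady_state(sensor, float(activity.a[0]), params)
    segments = [0.0, *(export_block_at or []), float(t[-1])]
    conc_n = np.empty_like(t)
    conc_c = np.empty_like(t)
    state = init
    current = params
    for s0, s1 in zip(segments[:-1], segments[1:]):
        if s0 > 0:
            current = leptomycin(current)
        sel = (t >= s0 - 1e-9) & (t <= s1 + 1e-9)
        sub = KinaseActivityTrace(kinase=activity.kinase, t=t[sel], a=activity.a[sel])
        states = simulate_cell(sensor, sub, current, state, dt=ode_dt)
        idx = np.nonzero(sel)[0]
        conc_n[idx] = [st.conc_n for st in states]
        conc_c[idx] = [st.conc_c for st in states]
        state = states[-1]
    return conc_n, conc_c


def run_experiment(config: ExperimentConfig) -> tuple[list[FieldResult], dict[str, KinaseActivityTrace]]:
    """Simulate and render every field of the configured experiment."""
    t_total = (config.n_frames - 1) * config.dt_min
    fine_dt = min(0.1, config.dt_min)
    t_fine = np.round(np.arange(0.0, t_total + fine_dt / 2, fine_dt), 9)
    frame_t = np.arange(config.n_frames) * config.dt_min
    frame_idx = np.searchsorted(t_fine, frame_t - 1e-9)

    activities = simulate_activities(config.schedule, config.pharmacology, t_fine)
    block_times = _export_block_times(config)

    root = np.random.SeedSequence(config.seed)
    field_seeds = root.spawn(config.n_fields)
    results: list[FieldResult] = []
    for fi in range(config.n_fields):
        geom_ss, jitter_ss, render_ss, drift_ss = field_seeds[fi].spawn(4)
        geom_seed = int(geom_ss.generate_state(1)[0] % (2**31))
        geometries = sample_field(geom_seed, config.n_cells, config.field_px)
        jit_rng = np.random.default_rng(jitter_ss)
        n = len(geometries)
        expr = jit_rng.lognormal(mean=0.0, sigma=config.expression_cv, size=n)
        amp = np.clip(jit_rng.normal(1.0, config.activity_jitter, size=n), 0.5, 1.5)

        sensor_traces: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for sensor in config.sensors:
            act = activities[sensor.kinase]
            cn_arr = np.empty((n, config.n_frames))
            cc_arr = np.empty((n, config.n_frames))
            for ci in range(n):
                a_cell = np.clip(act.a * amp[ci], 0.0, 1.0)
                cell_act = KinaseActivityTrace(kinase=act.kinase, t=t_fine, a=a_cell)
                conc_n, conc_c = simulate_sensor_traces(
                    sensor, cell_act, config.params,
                    export_block_at=block_times, ode_dt=config.ode_dt_min,
                )
                cn_arr[ci] = expr[ci] * conc_n[frame_idx]
                cc_arr[ci] = expr[ci] * conc_c[frame_idx]
            sensor_traces[sensor.channel] = (cn_arr, cc_arr)

        calcium = None
        if config.include_calcium:
            calcium = simulate_calcium(
                config.schedule, config.pharmacology, frame_t,
                pka_activity=activities["PKA"],
            )
        drift = None
        if config.drift_step_sigma > 0:
            drift_seed = int(drift_ss.generate_state(1)[0] % (2**31))
            drift = random_walk_drift(
                config.n_frames, drift_seed,
                step_sigma=config.drift_step_sigma, max_px=config.drift_max_px,
            )
        render_seed = int(render_ss.generate_state(1)[0] % (2**31))
        stack, gt = render_stack(
            geometries, sensor_traces, config.noise,
            field_px=config.field_px, dt_min=config.dt_min,
            pixel_size_um=config.pixel_size_um,
            calcium_trace=calcium, drift=drift, seed=render_seed,
        )
        results.append(FieldResult(field_index=fi, stack=stack, ground_truth=gt))
    return results, activities
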