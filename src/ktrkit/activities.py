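"""Kinase activity dynamics driven by pharmacological treatment schedules.

Drugs in a schedule set a per-kinase *target* activity (zero-order hold:
the latest events define the target until overridden); the observed
activity relaxes toward that target with first-order kinetics,

    da/dt = (a_target(t) - a) / tau,

using the triggering agent's ``tau_on`` when rising and ``tau_off`` when
falling. Targets combine a Hill-law drive from each agent's dose with
linear crosstalk between pathways, and are clipped to [0, 1].

The default crosstalk encodes the strongly asymmetric PKA/ERK coupling
seen with these reporters: PKA activation suppresses ERK (negative
PKA->ERK coefficient) while ERK activation weakly induces PKA (small
positive ERK->PKA coefficient).
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .kinetics import KinaseActivityTrace

__all__ = [
    "TreatmentEvent",
    "AgentPharm",
    "PharmacologyTable",
    "hill",
    "simulate_activities",
]

KINASES = ("PKA", "ERK")

_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6}


class TreatmentEvent(BaseModel):
    """One chemical addition: agent and dose at a time point (no washout)."""

    model_config = ConfigDict(frozen=True)

    time_min: float = Field(ge=0)
    agent: str
    dose: float = Field(default=0.0, ge=0)
    dose_unit: Literal["nM", "uM", "µM", "mM"] = "uM"

    @property
    def dose_nm(self) -> float:
        return self.dose * _UNIT_TO_NM[self.dose_unit]


class AgentPharm(BaseModel):
    """Pharmacology of one agent.

    ``target`` is the pathway acted on; ``mode`` distinguishes agonists,
    kinase inhibitors and export blockers. ``ec50_nm``/``hill`` set the
    dose-response; ``tau_on``/``tau_off`` the response and washout/decay
    time constants in minutes. ``transient`` marks agents whose effect is a
    decaying pulse rather than a hold (purinergic calcium release).
    """

    model_config = ConfigDict(frozen=True)

    target: Literal["PKA", "ERK", "calcium", "export"]
    mode: Literal["activate", "inhibit", "block_export"]
    ec50_nm: float = Field(gt=0)
    hill: float = Field(default=1.0, gt=0)
    tau_on: float = Field(default=1.5, gt=0)
    tau_off: float = Field(default=4.0, gt=0)
    transient: bool = False
    amplitude: float = Field(default=1.0, gt=0)


def _default_agents() -> dict[str, AgentPharm]:
    return {
        "Fsk": AgentPharm(target="PKA", mode="activate", ec50_nm=3000.0, hill=1.0, tau_on=1.5, tau_off=4.0),
        "H89": AgentPharm(target="PKA", mode="inhibit", ec50_nm=1000.0, hill=1.0, tau_on=3.0, tau_off=3.0),
        "EGF": AgentPharm(target="ERK", mode="activate", ec50_nm=0.3, hill=1.0, tau_on=1.5, tau_off=10.0),
        "VX11e": AgentPharm(target="ERK", mode="inhibit", ec50_nm=100.0, hill=1.0, tau_on=3.0, tau_off=3.0),
        "PMA": AgentPharm(target="ERK", mode="activate", ec50_nm=50.0, hill=1.0, tau_on=2.0, tau_off=8.0),
        "LMB": AgentPharm(target="export", mode="block_export", ec50_nm=1.0, hill=1.0, tau_on=1.0, tau_off=1.0),
        "ATP": AgentPharm(
            target="calcium", mode="activate", ec50_nm=1e4, hill=1.0,
            tau_on=0.3, tau_off=1.8, transient=True, amplitude=1.5,
        ),
        "A23187": AgentPharm(
            target="calcium", mode="activate", ec50_nm=1000.0, hill=1.0,
            tau_on=0.5, tau_off=5.0, amplitude=2.0,
        ),
        "vehicle": AgentPharm(target="PKA", mode="activate", ec50_nm=1.0, hill=1.0, amplitude=1.0),
    }


class PharmacologyTable(BaseModel):
    """Agents, baseline kinase activities and kinase->kinase crosstalk.

    ``crosstalk[src][dst]`` adds ``coef * (a_src - baseline_src)`` to the
    target activity of ``dst``. The defaults make PKA suppress ERK and ERK
    weakly induce PKA.
    """

    model_config = ConfigDict(frozen=True)

    agents: dict[str, AgentPharm] = Field(default_factory=_default_agents)
    baseline: dict[str, float] = Field(default_factory=lambda: {"PKA": 0.05, "ERK": 0.20})
    crosstalk: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {"PKA": {"ERK": -0.5}, "ERK": {"PKA": 0.15}}
    )
    gcamp_pka_gain: float = Field(default=1.5, gt=0)

    def lookup(self, agent: str) -> AgentPharm:
        try:
            return self.agents[agent]
        except KeyError:
            raise KeyError(
                f"unknown agent {agent!r}; known agents: {sorted(self.agents)}"
            ) from None


def hill(dose_nm: float, ec50_nm: float, n: float) -> float:
    """Hill occupancy in [0, 1)."""
    if dose_nm <= 0:
        return 0.0
    x = (dose_nm / ec50_nm) ** n
    return x / (1.0 + x)


def _validate_schedule(schedule: list[TreatmentEvent], pharm: PharmacologyTable) -> None:
    times = [e.time_min for e in schedule]
    if times != sorted(times):
        raise ValueError("treatment events must be sorted by time")
    for e in schedule:
        pharm.lookup(e.agent)  # raises naming the agent


def simulate_activities(
    schedule: list[TreatmentEvent],
    pharm: PharmacologyTable,
    t_grid: np.ndarray,
) -> dict[str, KinaseActivityTrace]:
    """Simulate PKA and ERK activity traces under a treatment schedule.

    Returns one :class:`~ktrkit.kinetics.KinaseActivityTrace` per kinase on
    the supplied uniform minute grid. An empty schedule yields constant
    baselines. Calcium- and export-directed agents are valid schedule
    entries but do not enter the kinase activities (see
    :func:`ktrkit.imaging.simulate_calcium` and
    :func:`ktrkit.kinetics.leptomycin`).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-D grid with at least two points")
    steps = np.diff(t_grid)
    if not np.allclose(steps, steps[0]):
        raise ValueError("t_grid must be uniform")
    _validate_schedule(schedule, pharm)

    # per kinase: held activating drive, held inhibition, and current tau source
    act_events: dict[str, list[TreatmentEvent]] = {k: [] for k in KINASES}
    for e in schedule:
        ph = pharm.lookup(e.agent)
        if ph.target in KINASES:
            act_events[ph.target].append(e)

    def held(kinase: str, t: float) -> tuple[float, float, AgentPharm | None]:
        """(activating drive, inhibition occupancy, last acting agent) at time t."""
        drive = 0.0
        inhib = 0.0
        last: AgentPharm | None = None
        for e in act_events[kinase]:
            if e.time_min > t:
                break
            if e.agent == "vehicle":
                continue
            ph = pharm.lookup(e.agent)
            occ = hill(e.dose_nm, ph.ec50_nm, ph.hill)
            if ph.mode == "activate":
                drive = occ  # zero-order hold: latest agonist level wins
            else:
                inhib = max(inhib, occ)
            last = ph
        return drive, inhib, last

    dt = float(steps[0])
    a = {k: pharm.baseline.get(k, 0.0) for k in KINASES}
    traces = {k: [a[k]] for k in KINASES}
    nsub = max(1, int(math.ceil(dt / 0.05)))
    h = dt / nsub
    for i in range(t_grid.size - 1):
        for j in range(nsub):
            t = t_grid[i] + j * h
            new = {}
            for k in KINASES:
                drive, inhib, last = held(k, t)
                base = pharm.baseline.get(k, 0.0)
                target = base + drive * (1.0 - base)
                for src, row in pharm.crosstalk.items():
                    if k in row and src in a:
                        target += row[k] * (a[src] - pharm.baseline.get(src, 0.0))
                target *= 1.0 - inhib
                target = min(max(target, 0.0), 1.0)
                if last is None:
                    tau = 2.0
                else:
                    tau = last.tau_on if target > a[k] else last.tau_off
                new[k] = a[k] + (target - a[k]) * (1.0 - math.exp(-h / tau))
                new[k] = min(max(new[k], 0.0), 1.0)
            a = new
        for k in KINASES:
            traces[k].append(a[k])
    return {
        k: KinaseActivityTrace(kinase=k, t=t_grid.copy(), a=np.array(traces[k]))
        for k in KINASES
    }
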