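"""Two-compartment nucleocytoplasmic transport kinetics for KTR sensors.

A kinase translocation reporter (KTR) is a fluorescent fusion protein that
shuttles between nucleus and cytoplasm. Its steady-state distribution is set
by the balance of three fluxes across the nuclear envelope:

* active import, driven by a bipartite nuclear localization signal (bNLS)
  whose effective strength is *weakened* by kinase phosphorylation of the
  sensor domain;
* active, exportin-mediated export via a nuclear export signal (NES),
  which leptomycin B blocks;
* passive diffusion through nuclear pores, fast for small proteins
  (below roughly 40 kDa) and strongly hindered for large ones
  (above roughly 60 kDa).

This module expresses that mechanism as a linear two-compartment ODE in the
nuclear and cytoplasmic concentrations, with logistic maps from bNLS score
to import rate and from effective molecular weight to passive rate.  The
logistic forms are the simplest smooth, saturating choices that reproduce
the qualitative behaviour of bNLS-score series and size series of sensors;
they are a modelling choice of this package, not measured rate laws.

State per cell:

* ``p``     -- phosphorylated fraction of the sensor, in [0, 1]
* ``conc_n`` -- nuclear concentration (arbitrary concentration units)
* ``conc_c`` -- cytoplasmic concentration

with dynamics (``a`` is the driving kinase activity in [0, 1])::

    dp/dt      = k_phos * a * (1 - p) - k_dephos * p
    dN/dt      = (k_in + k_d) * C - (k_out + k_d) * N - deg * N
    dC/dt      = syn + r * (k_out + k_d) * N - r * (k_in + k_d) * C - deg * C

where ``r = vol_ratio`` is the nuclear/cytoplasmic volume ratio; the ``r``
factors make compartment *amounts* balance so a closed system (syn = deg = 0)
conserves total sensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "SensorSpec",
    "TransportParams",
    "CellKineticState",
    "KinaseActivityTrace",
    "import_rate",
    "passive_rate",
    "phospho_steady_state",
    "simulate_cell",
    "steady_state_cn",
    "steady_state",
    "leptomycin",
]


class SensorSpec(BaseModel):
    """A KTR sensor construct.

    Parameters
    ----------
    nls_score
        cNLS-Mapper-style strength score of the (unphosphorylated) bNLS.
    delta_score_phospho
        Score units removed at full phosphorylation; phosphorylation of the
        sensor domain weakens the bNLS, so the effective score at
        phospho-fraction ``p`` is ``nls_score - delta_score_phospho * p``.
    mw_kda
        Molecular weight of one monomer of the fusion protein, kDa.
    copies
        Oligomer copy number of the fluorophore fusion (1 for monomers such
        as mCherry, 2 for tandem dimers such as tdCherry/tdTomato, 4 for
        tetramer-forming cargo such as BCR fusions). Copies multiply the
        effective mass seen by the nuclear pore.
    kinase
        The kinase whose activity the sensor reads out.
    channel
        Imaging channel name the sensor is rendered into.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    nls_score: float = Field(ge=0)
    delta_score_phospho: float = Field(default=4.0, ge=0)
    mw_kda: float = Field(gt=0)
    copies: Literal[1, 2, 4] = 1
    kinase: str = "PKA"
    channel: str = "KTR"
    k_phos_multiplier: float = Field(default=1.0, gt=0)

    @property
    def mw_eff_kda(self) -> float:
        """Effective mass presented to the pore: monomer mass times copies."""
        return self.mw_kda * self.copies


class TransportParams(BaseModel):
    """Rate parameters of the transport model (all first-order rates, 1/min).

    ``k_in_max`` saturating active-import rate; the logistic in the bNLS
    score has midpoint ``s_half`` and width ``s_width`` (score units).
    ``k_out`` is the NES-mediated export rate (zeroed by leptomycin B).
    ``k_diff0`` is the passive-diffusion rate of a vanishingly small
    protein; the logistic in effective mass has midpoint ``mw_half`` and
    width ``mw_width`` (kDa). ``synthesis`` (conc/min, cytoplasm only) and
    ``degradation`` (1/min, both compartments) set turnover; ``k_phos`` and
    ``k_dephos`` set the phospho-cycle. ``vol_ratio`` is nuclear/cytoplasmic
    volume.
    """

    model_config = ConfigDict(frozen=True)

    k_in_max: float = Field(default=1.0, ge=0)
    s_half: float = 10.0
    s_width: float = Field(default=0.6, gt=0)
    k_out: float = Field(default=0.005, ge=0)
    k_diff0: float = Field(default=1.0, ge=0)
    mw_half: float = Field(default=60.0, gt=0)
    mw_width: float = Field(default=8.0, gt=0)
    synthesis: float = Field(default=0.01, ge=0)
    degradation: float = Field(default=0.01, ge=0)
    k_phos: float = Field(default=1.0, ge=0)
    k_dephos: float = Field(default=0.1, ge=0)
    vol_ratio: float = Field(default=0.5, gt=0)


@dataclass(frozen=True)
class CellKineticState:
    """Instantaneous kinetic state of one cell."""

    p: float
    conc_n: float
    conc_c: float
    vol_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValueError(f"phospho fraction p={self.p} outside [0, 1]")
        if self.conc_n < 0 or self.conc_c < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.vol_ratio <= 0:
            raise ValueError("vol_ratio must be positive")

    @property
    def cn_ratio(self) -> float:
        """Cytoplasm-to-nucleus concentration ratio."""
        return self.conc_c / self.conc_n

    @property
    def total_amount(self) -> float:
        """Total sensor amount in units of cytoplasmic volume."""
        return self.conc_c + self.conc_n * self.vol_ratio


@dataclass
class KinaseActivityTrace:
    """A kinase activity time course on a uniform minute grid, values in [0, 1]."""

    kinase: str
    t: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.t.shape != self.a.shape:
            raise ValueError("t and a must have equal length")
        if self.a.size and (self.a.min() < -1e-9 or self.a.max() > 1 + 1e-9):
            raise ValueError("activity outside [0, 1]")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else math.nan

    def at(self, time_min: float) -> float:
        """Activity at an arbitrary time, linearly interpolated."""
        return float(np.interp(time_min, self.t, self.a))


def _logistic(x: float) -> float:
    # numerically safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def import_rate(sensor: SensorSpec, p: float, params: TransportParams) -> float:
    """Active nuclear import rate (1/min) at phospho-fraction ``p``.

    Phosphorylation removes ``delta_score_phospho * p`` score units from the
    bNLS; the remaining effective score is mapped through a logistic with
    midpoint ``s_half``. The rate is monotone increasing in ``nls_score``
    and decreasing in ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"phospho fraction p={p} outside [0, 1]")
    s_eff = sensor.nls_score - sensor.delta_score_phospho * p
    return params.k_in_max * _logistic((s_eff - params.s_half) / params.s_width)


def passive_rate(mw_kda: float, copies: int = 1, *, params: TransportParams) -> float:
    """Passive nuclear-pore diffusion rate (1/min) for a protein of given mass.

    Depends only on the effective mass ``mw_kda * copies``: small proteins
    equilibrate quickly, large ones are strongly hindered.
    """
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    mw_eff = mw_kda * copies
    return params.k_diff0 * _logistic((params.mw_half - mw_eff) / params.mw_width)


def phospho_steady_state(a: float, params: TransportParams, k_phos_multiplier: float = 1.0) -> float:
    """Steady-state phosphorylated fraction at constant kinase activity ``a``."""
    kp = params.k_phos * k_phos_multiplier * a
    denom = kp + params.k_dephos
    if denom == 0:
        return 0.0
    return kp / denom


def leptomycin(params: TransportParams) -> TransportParams:
    """Return parameters with exportin-mediated export blocked (k_out = 0),
    emulating leptomycin B treatment. Everything else is unchanged."""
    return params.model_copy(update={"k_out": 0.0})


def steady_state_cn(sensor: SensorSpec, a: float, params: TransportParams) -> float:
    """Closed-form steady-state C/N concentration ratio at constant activity.

    Setting dN/dt = 0 in the transport ODE gives::

        C/N = (k_out + k_d + degradation) / (k_in(p*) + k_d)

    with ``p* = k_phos*a / (k_phos*a + k_dephos)`` the phospho-cycle fixed
    point and ``k_d`` the passive rate. The formula is the long-time limit
    of :func:`simulate_cell` whenever a steady state exists (turnover
    present, or a closed system where degradation = 0).
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activity a={a} outside [0, 1]")
    p_star = phospho_steady_state(a, params, sensor.k_phos_multiplier)
    k_in = import_rate(sensor, p_star, params)
    k_d = passive_rate(sensor.mw_kda, sensor.copies, params=params)
    denom = k_in + k_d
    num = params.k_out + k_d + params.degradation
    if denom == 0 and num == 0:
        raise ValueError("all transport and turnover rates are zero; C/N undefined")
    if denom == 0:
        raise ValueError("no influx into the nucleus (k_in + k_d = 0); C/N diverges")
    return num / denom


def steady_state(sensor: SensorSpec, a: float, params: TransportParams) -> CellKineticState:
    """Full steady state (p, conc_n, conc_c) at constant activity.

    With synthesis and degradation both positive the absolute concentrations
    are fixed by total production/turnover balance
    ``synthesis = degradation * (C + N * vol_ratio)``; without turnover the
    state is normalised to unit total amount.
    """
    p_star = phospho_steady_state(a, params, sensor.k_phos_multiplier)
    cn = steady_state_cn(sensor, a, params)
    r = params.vol_ratio
    # amounts in cytoplasmic-volume units: total = C + N*r
    if params.degradation > 0 and params.synthesis > 0:
        total = params.synthesis / params.degradation
    else:
        total = 1.0
    conc_n = total / (cn + r)
    conc_c = cn * conc_n
    return CellKineticState(p=p_star, conc_n=conc_n, conc_c=conc_c, vol_ratio=r)


def _derivatives(
    y: np.ndarray,
    a: float,
    k_in_of_p,
    k_d: float,
    params: TransportParams,
    k_phos_multiplier: float,
) -> np.ndarray:
    p, n, c = y
    p = min(max(p, 0.0), 1.0)
    dp = params.k_phos * k_phos_multiplier * a * (1.0 - p) - params.k_dephos * p
    k_in = k_in_of_p(p)
    r = params.vol_ratio
    influx = (k_in + k_d) * c
    efflux = (params.k_out + k_d) * n
    dn = influx - efflux - params.degradation * n
    dc = params.synthesis + r * efflux - r * influx - params.degradation * c
    return np.array([dp, dn, dc])


def simulate_cell(
    sensor: SensorSpec,
    activity: KinaseActivityTrace,
    params: TransportParams,
    init: CellKineticState,
    dt: float = 0.1,
) -> list[CellKineticState]:
    """Integrate one cell's phospho-transport dynamics along an activity trace.

    Fixed-step classical Runge-Kutta (RK4) at step ``dt`` minutes, evaluated
    on the activity grid (sub-stepping when the grid is coarser than ``dt``).
    Deterministic. Returns one state per activity grid point, the first being
    ``init``.

    Raises
    ------
    ValueError
        If ``dt`` is nonpositive or too large for the fastest rate in the
        system (stability guard: ``dt * max_rate`` must stay below 2).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    max_rate = max(
        params.k_in_max + params.k_diff0 + params.k_out + params.degradation,
        params.k_phos * sensor.k_phos_multiplier + params.k_dephos,
        1e-12,
    )
    if dt * max_rate > 2.0:
        raise ValueError(
            f"dt={dt} min is unstable for the fastest rate {max_rate:.3g}/min; "
            f"use dt < {2.0 / max_rate:.3g} min"
        )
    k_d = passive_rate(sensor.mw_kda, sensor.copies, params=params)
    delta = sensor.delta_score_phospho
    score = sensor.nls_score

    def k_in_of_p(p: float) -> float:
        s_eff = score - delta * p
        return params.k_in_max * _logistic((s_eff - params.s_half) / params.s_width)

    t_grid = activity.t
    a_grid = activity.a
    y = np.array([init.p, init.conc_n, init.conc_c], dtype=float)
    r = init.vol_ratio
    out = [init]
    for i in range(len(t_grid) - 1):
        span = float(t_grid[i + 1] - t_grid[i])
        nsub = max(1, int(math.ceil(span / dt - 1e-9)))
        h = span / nsub
        for j in range(nsub):
            # activity interpolated at substep midpoints for the RK stages
            t0 = t_grid[i] + j * h
            a0 = float(np.interp(t0, t_grid, a_grid))
            am = float(np.interp(t0 + h / 2, t_grid, a_grid))
            a1 = float(np.interp(t0 + h, t_grid, a_grid))
            k1 = _derivatives(y, a0, k_in_of_p, k_d, params, sensor.k_phos_multiplier)
            k2 = _derivatives(y + h / 2 * k1, am, k_in_of_p, k_d, params, sensor.k_phos_multiplier)
            k3 = _derivatives(y + h / 2 * k2, am, k_in_of_p, k_d, params, sensor.k_phos_multiplier)
            k4 = _derivatives(y + h * k3, a1, k_in_of_p, k_d, params, sensor.k_phos_multiplier)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            y[0] = min(max(y[0], 0.0), 1.0)
            y[1] = max(y[1], 0.0)
            y[2] = max(y[2], 0.0)
        out.append(CellKineticState(p=float(y[0]), conc_n=float(y[1]), conc_c=float(y[2]), vol_ratio=r))
    return out
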