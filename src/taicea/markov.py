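"""Markov cohort engine for the TAI vs SBC decision model.

Six health states: TAI responder, TAI non-responder, resume-SBC (withdrawn
non-responders), SBC, stoma, and dead.  The cohort is advanced in 6-month
cycles from the start age to an age cutoff; costs and QALYs are accrued per
cycle and discounted at the annual rate.  The engine is an expected-value
cohort model, not a microsimulation.

The public surface follows the Model/Results convention: build a
:class:`CostEffectivenessModel` from a :class:`~taicea.params.ModelParameters`
set, call :meth:`~CostEffectivenessModel.fit`, and read the incremental
results off the returned :class:`CEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Literal

import numpy as np
import pandas as pd

from .params import ModelParameters, default_parameters
from .productivity import nbds_category, productivity_loss_per_cycle

__all__ = [
    "HealthState",
    "CohortTrace",
    "CEResults",
    "CostEffectivenessModel",
    "discount_factor",
    "build_transition_matrix",
    "run_cohort",
    "compute_icer",
]

Arm = Literal["TAI", "SBC"]


class HealthState(IntEnum):
    """Model states; DEAD is absorbing, STOMA exits only to DEAD."""

    TAI_RESPONDER = 0
    TAI_NONRESPONDER = 1
    RESUME_SBC = 2
    SBC = 3
    STOMA = 4
    DEAD = 5


N_STATES = len(HealthState)


def discount_factor(time_years: float | np.ndarray, rate: float) -> float | np.ndarray:
    """Discount factor (1 + rate)^(-t) for time measured in years."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate!r}")
    return (1.0 + rate) ** (-np.asarray(time_years, dtype=float))


def build_transition_matrix(
    params: ModelParameters, arm: Arm, age: float
) -> np.ndarray:
    """One-cycle transition matrix at a given attained age.

    Death is applied first: the sex-weighted cycle death probability
    ``q`` claims its share of every living state and all competing
    transitions are scaled by ``(1 - q)``.  TAI responders persist on
    treatment; non-responders withdraw to resume-SBC; SBC-type states face
    the per-cycle stoma-construction probability; stoma persists.
    """
    s = params.settings
    c = params.clinical
    q = params.mortality.cycle_q(age, s.male_fraction, s.cycle_length_years)
    w = c.nonresponder_withdrawal_per_cycle
    if c.all_nonresponders_withdraw_after_first_cycle:
        w = 1.0
    st = c.stoma_rate_per_cycle

    m = np.zeros((N_STATES, N_STATES))
    m[HealthState.TAI_RESPONDER, HealthState.TAI_RESPONDER] = 1.0 - q
    m[HealthState.TAI_NONRESPONDER, HealthState.RESUME_SBC] = w * (1.0 - q)
    m[HealthState.TAI_NONRESPONDER, HealthState.TAI_NONRESPONDER] = (1.0 - w) * (1.0 - q)
    for state in (HealthState.RESUME_SBC, HealthState.SBC):
        m[state, HealthState.STOMA] = st * (1.0 - q)
        m[state, state] = (1.0 - st) * (1.0 - q)
    m[HealthState.STOMA, HealthState.STOMA] = 1.0 - q
    m[:, HealthState.DEAD] = q
    m[HealthState.DEAD] = 0.0
    m[HealthState.DEAD, HealthState.DEAD] = 1.0

    rows = m.sum(axis=1)
    if np.abs(rows - 1.0).max() > 1e-12:
        raise RuntimeError(f"transition rows deviate from 1: {rows}")
    return m


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted accruals for one arm.

    ``occupancy`` has one row per lived cycle plus the initial row; accruals
    are per cycle, already discounted.  ``stoma_entry`` is the probability
    inflow into the stoma state at each cycle (used for one-off surgery
    costs and stoma-tenure-dependent management costs).
    """

    arm: str
    ages: np.ndarray
    occupancy: np.ndarray
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray
    stoma_entry: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cycle_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.cycle_qaly.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy[:-1],
            columns=[state.name.lower() for state in HealthState],
        )
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        df["disc_cost"] = self.cycle_cost
        df["disc_qaly"] = self.cycle_qaly
        return df


def _state_event_rates(params: ModelParameters) -> dict[int, tuple[float, float, float]]:
    """Per-cycle (UTI rate, hospitalization rate, nursing rate) by state.

    Hospitalization counts are recalled over ``hospitalization_recall_years``
    and divided down to per-cycle rates.  The stoma state keeps SBC-level
    event rates by default (switchable to management-costs-only).
    """
    c = params.clinical
    n_recall = params.hosp_cycles_in_recall
    tai = (
        c.uti_rate_tai_per_cycle,
        (c.hosp_decubitus_tai + c.hosp_other_tai) / n_recall,
        c.nursing_rate_tai,
    )
    sbc = (
        c.uti_rate_sbc_per_cycle,
        (c.hosp_decubitus_sbc + c.hosp_other_sbc) / n_recall,
        c.nursing_rate_sbc,
    )
    stoma = sbc if c.stoma_events_at_sbc_rates else (0.0, 0.0, 0.0)
    return {
        HealthState.TAI_RESPONDER: tai,
        HealthState.TAI_NONRESPONDER: tai,
        HealthState.RESUME_SBC: sbc,
        HealthState.SBC: sbc,
        HealthState.STOMA: stoma,
    }


def _hosp_cost_per_cycle(params: ModelParameters, arm_rates: str) -> float:
    """Expected hospitalization cost per cycle, decubitus and other separated."""
    c = params.clinical
    n_recall = params.hosp_cycles_in_recall
    if arm_rates == "tai":
        dec, oth = c.hosp_decubitus_tai, c.hosp_other_tai
    else:
        dec, oth = c.hosp_decubitus_sbc, c.hosp_other_sbc
    return (
        dec * params.cost.hosp_cost_decubitus + oth * params.cost.hosp_cost_other
    ) / n_recall


def accrue_cycle_cost(
    state: HealthState,
    params: ModelParameters,
    arm: Arm,
    cycle_index: int = 0,
    time_in_stoma_cycles: int = 0,
) -> float:
    """Undiscounted yen accrued by one person spending one cycle in ``state``.

    Stoma surgery one-off costs are charged separately on entry (see
    :func:`run_cohort`); here the stoma state carries management costs by
    tenure plus (by default) SBC-level event costs.
    """
    if state == HealthState.DEAD:
        return 0.0
    s = params.settings
    c = params.cost
    months = s.cycle_length_years * 12.0
    weeks = s.cycle_length_years * 52.0
    uti_cost = params.expected_uti_episode_cost
    rates = _state_event_rates(params)[state]
    uti_rate, _, nursing_rate = rates

    if state in (HealthState.TAI_RESPONDER, HealthState.TAI_NONRESPONDER):
        base = (
            c.device_cost_per_year * s.cycle_length_years
            + s.tai_procedure_fee_per_month * months
        )
        hosp = _hosp_cost_per_cycle(params, "tai")
    elif state in (HealthState.RESUME_SBC, HealthState.SBC):
        base = c.sbc_cost_per_month * months
        hosp = _hosp_cost_per_cycle(params, "sbc")
    else:  # STOMA
        mgmt = (
            c.stoma_mgmt_month_y1
            if time_in_stoma_cycles * s.cycle_length_years < 1.0
            else c.stoma_mgmt_month_after
        )
        base = mgmt * months
        hosp = (
            _hosp_cost_per_cycle(params, "sbc")
            if params.clinical.stoma_events_at_sbc_rates
            else 0.0
        )

    total = (
        base
        + uti_rate * uti_cost
        + hosp
        + nursing_rate * params.weekly_nursing_cost * weeks
    )
    if total < 0:
        raise RuntimeError(f"negative cycle cost for state {state.name}")
    return total


def accrue_cycle_qaly(state: HealthState, params: ModelParameters, arm: Arm) -> float:
    """Undiscounted QALYs accrued by one person over one cycle in ``state``.

    State utility times the cycle length, minus one-off decrements for the
    expected UTI and hospitalization events of the cycle; floored at the
    negative of the cycle length (utility cannot fall below -1).
    """
    if state == HealthState.DEAD:
        return 0.0
    u = params.utility
    state_u = {
        HealthState.TAI_RESPONDER: u.u_responder,
        HealthState.TAI_NONRESPONDER: u.u_nonresponder,
        HealthState.RESUME_SBC: u.u_sbc,
        HealthState.SBC: u.u_sbc,
        HealthState.STOMA: u.u_stoma,
    }[state]
    uti_rate, hosp_rate, _ = _state_event_rates(params)[state]
    q = (
        state_u * params.settings.cycle_length_years
        - uti_rate * u.du_uti_per_event
        - hosp_rate * u.du_hosp_per_event
    )
    return max(q, -params.settings.cycle_length_years)


def _productivity_cost_per_cycle(
    params: ModelParameters, state: HealthState, age: float
) -> float:
    """Productivity loss (yen/cycle) attached to a state at a given age."""
    mode = {
        "societal_absenteeism": "absenteeism",
        "societal_full": "absenteeism_plus_presenteeism",
    }.get(params.settings.perspective)
    if mode is None or state == HealthState.DEAD:
        return 0.0
    c = params.clinical
    state_nbds = {
        HealthState.TAI_RESPONDER: c.nbds_baseline + c.nbds_delta_responder,
        HealthState.TAI_NONRESPONDER: c.nbds_baseline + c.nbds_delta_nonresponder,
        HealthState.RESUME_SBC: c.nbds_baseline,
        HealthState.SBC: c.nbds_baseline,
        HealthState.STOMA: c.nbds_baseline,
    }[state]
    category = nbds_category(state_nbds)
    return productivity_loss_per_cycle(
        age,
        category,
        params.productivity,
        mode=mode,
        cycle_length_years=params.settings.cycle_length_years,
    )


def run_cohort(params: ModelParameters, arm: Arm) -> CohortTrace:
    """Advance the cohort from start age to the age cutoff and accrue.

    The TAI arm starts split 60/40 between responders and non-responders;
    the SBC arm starts entirely in the SBC state.  Transition matrices are
    rebuilt each cycle with the age-specific death probability.  Discounting
    is evaluated at cycle end, or mid-cycle when the half-cycle-correction
    flag is set.
    """
    s = params.settings
    cl = s.cycle_length_years
    n_cycles = int(np.ceil((s.age_cutoff - s.start_age) / cl))

    if arm == "TAI":
        init = np.zeros(N_STATES)
        init[HealthState.TAI_RESPONDER] = params.clinical.responder_fraction
        init[HealthState.TAI_NONRESPONDER] = 1.0 - params.clinical.responder_fraction
    elif arm == "SBC":
        init = np.zeros(N_STATES)
        init[HealthState.SBC] = 1.0
    else:
        raise ValueError(f"arm must be 'TAI' or 'SBC', got {arm!r}")

    occupancy = np.empty((n_cycles + 1, N_STATES))
    occupancy[0] = init
    stoma_entry = np.zeros(n_cycles + 1)
    ages = s.start_age + cl * np.arange(n_cycles)

    for t in range(1, n_cycles + 1):
        m = build_transition_matrix(params, arm, ages[t - 1])
        prev = occupancy[t - 1]
        occupancy[t] = prev @ m
        stoma_entry[t] = (
            prev[HealthState.RESUME_SBC] * m[HealthState.RESUME_SBC, HealthState.STOMA]
            + prev[HealthState.SBC] * m[HealthState.SBC, HealthState.STOMA]
        )

    # Stoma occupancy split by tenure: first-year (tenure < 1y) vs established.
    # mass[k] tracks survivors who entered stoma k cycles ago.
    surv = 1.0 - np.array(
        [params.mortality.cycle_q(a, s.male_fraction, cl) for a in ages]
    )
    cycles_per_year = max(1, int(round(1.0 / cl)))
    stoma_y1 = np.zeros(n_cycles + 1)
    mass = np.zeros(cycles_per_year)  # tenure 0 .. cycles_per_year-1
    for t in range(1, n_cycles + 1):
        mass[1:] = mass[:-1] * surv[t - 1]
        mass[0] = stoma_entry[t]
        stoma_y1[t] = mass.sum()

    # Per-cycle accrual using occupancy rows 0..n_cycles-1 (lived cycles).
    times = cl * (np.arange(n_cycles) + (0.5 if s.half_cycle_correction else 1.0))
    disc = discount_factor(times, s.annual_discount_rate)

    state_cost = np.zeros((n_cycles, N_STATES))
    state_qaly = np.zeros(N_STATES)
    for state in HealthState:
        if state == HealthState.DEAD:
            continue
        state_qaly[state] = accrue_cycle_qaly(state, params, arm)
    for state in (
        HealthState.TAI_RESPONDER,
        HealthState.TAI_NONRESPONDER,
        HealthState.RESUME_SBC,
        HealthState.SBC,
    ):
        state_cost[:, state] = accrue_cycle_cost(state, params, arm)

    # Stoma: tenure-dependent management cost.
    cost_stoma_y1 = accrue_cycle_cost(HealthState.STOMA, params, arm, time_in_stoma_cycles=0)
    cost_stoma_after = accrue_cycle_cost(
        HealthState.STOMA, params, arm, time_in_stoma_cycles=cycles_per_year
    )

    occ = occupancy[:n_cycles]
    stoma_y1_lived = stoma_y1[:n_cycles]
    stoma_after_lived = occ[:, HealthState.STOMA] - stoma_y1_lived

    cycle_cost = (occ * state_cost).sum(axis=1)
    # stoma costs by tenure (state_cost leaves the stoma column at zero)
    cycle_cost += stoma_y1_lived * cost_stoma_y1 + stoma_after_lived * cost_stoma_after
    # one-off surgery + surgical hospitalization charged on the entry cycle
    one_off = params.expected_stoma_surgery_fee + params.expected_stoma_surgery_hospitalization
    cycle_cost += stoma_entry[:n_cycles] * one_off

    if params.settings.perspective != "payer":
        prod = np.zeros((n_cycles, N_STATES))
        for state in HealthState:
            if state == HealthState.DEAD:
                continue
            prod[:, state] = np.array(
                [_productivity_cost_per_cycle(params, state, a) for a in ages]
            )
        cycle_cost += (occ * prod).sum(axis=1)

    cycle_qaly = occ @ state_qaly

    return CohortTrace(
        arm=arm,
        ages=ages,
        occupancy=occupancy,
        cycle_cost=cycle_cost * disc,
        cycle_qaly=cycle_qaly * disc,
        stoma_entry=stoma_entry,
    )


def compute_icer(delta_cost: float, delta_qaly: float) -> float | str:
    """ICER in yen/QALY, or a dominance flag.

    Returns the ratio when both increments are nonzero with the same sign;
    ``"dominant"`` (cheaper, at least as effective), ``"dominated"`` (costlier,
    at most as effective), ``"undefined"`` (no QALY gain, extra cost), or
    ``"indifferent"`` (both increments zero).
    """
    if delta_cost == 0 and delta_qaly == 0:
        return "indifferent"
    if delta_cost <= 0 and delta_qaly >= 0:
        return "dominant"
    if delta_qaly == 0:
        return "undefined"
    if delta_cost >= 0 and delta_qaly < 0:
        return "dominated"
    return delta_cost / delta_qaly


@dataclass
class CEResults:
    """Arm totals and incremental cost-effectiveness of TAI vs SBC."""

    params: ModelParameters
    trace_tai: CohortTrace
    trace_sbc: CohortTrace

    @property
    def cost_tai(self) -> float:
        return self.trace_tai.total_cost

    @property
    def cost_sbc(self) -> float:
        return self.trace_sbc.total_cost

    @property
    def qaly_tai(self) -> float:
        return self.trace_tai.total_qaly

    @property
    def qaly_sbc(self) -> float:
        return self.trace_sbc.total_qaly

    @property
    def delta_cost(self) -> float:
        return self.cost_tai - self.cost_sbc

    @property
    def delta_qaly(self) -> float:
        return self.qaly_tai - self.qaly_sbc

    @property
    def icer(self) -> float | str:
        return compute_icer(self.delta_cost, self.delta_qaly)

    @property
    def icer_value(self) -> float:
        """Numeric ICER for sorting: +inf when dominated/undefined, -inf dominant."""
        icer = self.icer
        if isinstance(icer, float):
            return icer
        return {"dominant": -np.inf, "dominated": np.inf, "undefined": np.inf, "indifferent": 0.0}[icer]

    def to_dict(self) -> dict:
        icer = self.icer
        return {
            "perspective": self.params.settings.perspective,
            "tai_procedure_fee_per_month": self.params.settings.tai_procedure_fee_per_month,
            "cost_tai": round(self.cost_tai),
            "cost_sbc": round(self.cost_sbc),
            "qaly_tai": self.qaly_tai,
            "qaly_sbc": self.qaly_sbc,
            "delta_cost": round(self.delta_cost),
            "delta_qaly": self.delta_qaly,
            "icer": icer if isinstance(icer, str) else icer,
        }

    def summary(self) -> str:
        icer = self.icer
        icer_txt = icer if isinstance(icer, str) else f"{icer:,.0f} yen/QALY"
        lines = [
            "Cost-effectiveness results (TAI vs SBC)",
            "=" * 47,
            f"Perspective:        {self.params.settings.perspective}",
            f"TAI fee/month:      {self.params.settings.tai_procedure_fee_per_month:,.0f} yen",
            f"Discount rate:      {self.params.settings.annual_discount_rate:.1%}/yr",
            "-" * 47,
            f"{'':16}{'Cost (yen)':>15}{'QALYs':>12}",
            f"{'SBC':16}{self.cost_sbc:>15,.0f}{self.qaly_sbc:>12.2f}",
            f"{'TAI':16}{self.cost_tai:>15,.0f}{self.qaly_tai:>12.2f}",
            f"{'Incremental':16}{self.delta_cost:>15,.0f}{self.delta_qaly:>12.2f}",
            "-" * 47,
            f"ICER:               {icer_txt}",
        ]
        return "\n".join(lines)


class CostEffectivenessModel:
    """Markov cohort cost-effectiveness model of TAI versus SBC.

    Parameters
    ----------
    params : ModelParameters, optional
        Calibrated parameter set; defaults to the packaged base case.

    Examples
    --------
    >>> from taicea import CostEffectivenessModel
    >>> res = CostEffectivenessModel().fit()
    >>> res.delta_qaly > 0
    True
    """

    def __init__(self, params: ModelParameters | None = None):
        self.params = params if params is not None else default_parameters()

    @classmethod
    def from_config(cls, source=None, **kwargs) -> "CostEffectivenessModel":
        from .params import load_parameters

        return cls(load_parameters(source, **kwargs))

    def run(self, arm: Arm) -> CohortTrace:
        return run_cohort(self.params, arm)

    def fit(self) -> CEResults:
        """Run both arms and return incremental results."""
        return CEResults(
            params=self.params,
            trace_tai=self.run("TAI"),
            trace_sbc=self.run("SBC"),
        )
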