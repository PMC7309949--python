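"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the model with each parameter at +/-20%
of its base-case value, everything else held fixed, and ranks parameters by
the width of the resulting ICER interval.  Probabilistic sensitivity
analysis draws every parameter jointly - gamma for costs and other
nonnegative quantities, beta for probabilities and utilities, both by
method of moments around the base-case mean with a common coefficient of
variation - runs the model per draw, and summarizes the incremental
cost/QALY cloud as a cost-effectiveness acceptability curve (CEAC) over a
willingness-to-pay grid.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import CEResults, CostEffectivenessModel
from .params import ModelParameters, ParameterError

__all__ = [
    "DEFAULT_TORNADO_PARAMETERS",
    "DEFAULT_PSA_PARAMETERS",
    "get_param",
    "set_param",
    "one_way_sweep",
    "PSASpec",
    "PSAResult",
    "draw_parameters",
    "run_psa",
    "ceac",
]

# Scalar model inputs swept by default.  The Peristeen cost components are
# provenance for device_cost_per_year and are not swept separately.
_CLINICAL = [
    "clinical.responder_fraction",
    "clinical.nonresponder_withdrawal_per_cycle",
    "clinical.uti_rate_sbc_per_cycle",
    "clinical.uti_rate_tai_per_cycle",
    "clinical.hosp_decubitus_sbc",
    "clinical.hosp_decubitus_tai",
    "clinical.hosp_other_sbc",
    "clinical.hosp_other_tai",
    "clinical.nursing_rate_sbc",
    "clinical.nursing_rate_tai",
    "clinical.stoma_rate_per_cycle",
    "clinical.laparoscopic_fraction",
]
_UTILITY = [
    "utility.u_responder",
    "utility.u_nonresponder",
    "utility.u_sbc",
    "utility.u_stoma",
    "utility.du_uti_per_event",
    "utility.du_hosp_per_event",
]
_COST = [
    "cost.device_cost_per_year",
    "cost.sbc_cost_per_month",
    "cost.stoma_fee_laparoscopic",
    "cost.stoma_fee_open",
    "cost.stoma_hosp_laparoscopic",
    "cost.stoma_hosp_open",
    "cost.stoma_mgmt_month_y1",
    "cost.stoma_mgmt_month_after",
    "cost.uti_cost_hospitalized",
    "cost.uti_cost_outpatient",
    "cost.uti_cost_untreated",
    "cost.nursing_cost_per_visit",
    "cost.nursing_premium_per_week",
    "cost.hosp_cost_decubitus",
    "cost.hosp_cost_other",
]
_SETTINGS = ["settings.tai_procedure_fee_per_month"]

DEFAULT_TORNADO_PARAMETERS = _CLINICAL + _UTILITY + _COST + _SETTINGS
DEFAULT_PSA_PARAMETERS = _CLINICAL + _UTILITY + _COST

# fields that are probabilities/fractions and must stay in [0, 1]
_FRACTION_FIELDS = {
    "clinical.responder_fraction",
    "clinical.nonresponder_withdrawal_per_cycle",
    "clinical.uti_rate_sbc_per_cycle",
    "clinical.uti_rate_tai_per_cycle",
    "clinical.nursing_rate_sbc",
    "clinical.nursing_rate_tai",
    "clinical.stoma_rate_per_cycle",
    "clinical.laparoscopic_fraction",
    "utility.u_responder",
    "utility.u_nonresponder",
    "utility.u_sbc",
    "utility.u_stoma",
    "utility.du_uti_per_event",
    "utility.du_hosp_per_event",
}


def get_param(params: ModelParameters, path: str) -> float:
    section, name = path.split(".", 1)
    return float(getattr(getattr(params, section), name))


def set_param(params: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a copy of the parameter set with one scalar replaced."""
    section, name = path.split(".", 1)
    new_section = dataclasses.replace(getattr(params, section), **{name: value})
    return params.replace(**{section: new_section})


def _clamped(path: str, value: float) -> tuple[float, bool]:
    if path in _FRACTION_FIELDS and value > 1.0:
        return 1.0, True
    if value < 0.0:
        return 0.0, True
    return value, False


def _run(params: ModelParameters) -> CEResults:
    return CostEffectivenessModel(params).fit()


def one_way_sweep(
    base: ModelParameters,
    parameters: list[str] | None = None,
    span: float = 0.2,
) -> pd.DataFrame:
    """Tornado table: two full model runs per parameter at (1 +/- span) x base.

    Returns a frame with columns ``parameter``, ``base_value``, ``low``,
    ``high``, ``icer_low``, ``icer_high``, ``range``, ``nmb_range``,
    ``clamped``, sorted by descending ICER range.  A side whose QALY
    increment is non-positive has an infinite numeric ICER (dominated
    direction) and sorts first; ties - in particular ties at infinity - are
    broken by the swing in net monetary benefit at a 5-million-yen
    willingness to pay, which is always finite, so the ordering never
    depends on the listing order of the parameters.
    """
    parameters = parameters if parameters is not None else DEFAULT_TORNADO_PARAMETERS
    wtp_ref = 5_000_000.0
    rows = []
    for path in parameters:
        base_value = get_param(base, path)
        icers = {}
        nmbs = {}
        clamped_any = False
        bounds = {}
        for side, mult in (("low", 1.0 - span), ("high", 1.0 + span)):
            value, clamped = _clamped(path, base_value * mult)
            clamped_any |= clamped
            bounds[side] = value
            res = _run(set_param(base, path, value))
            icers[side] = res.icer_value
            nmbs[side] = wtp_ref * res.delta_qaly - res.delta_cost
        rows.append(
            {
                "parameter": path,
                "base_value": base_value,
                "low": bounds["low"],
                "high": bounds["high"],
                "icer_low": icers["low"],
                "icer_high": icers["high"],
                "range": abs(icers["high"] - icers["low"]),
                "nmb_range": abs(nmbs["high"] - nmbs["low"]),
                "clamped": clamped_any,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["range", "nmb_range"], ascending=False, kind="stable"
    ).reset_index(drop=True)


@dataclass
class PSASpec:
    """Distributional assumptions for the probabilistic sensitivity analysis.

    Gamma (method of moments: shape 1/cv^2, scale mean*cv^2) for
    unbounded nonnegative parameters; beta (method of moments from mean and
    sd = cv * mean) for parameters living in [0, 1].  The common default
    coefficient of variation mirrors the +/-20% deterministic range.
    """

    parameters: list[str] = field(default_factory=lambda: list(DEFAULT_PSA_PARAMETERS))
    cv: float = 0.2
    cv_overrides: dict[str, float] = field(default_factory=dict)
    n_draws: int = 10_000
    seed: int = 0

    def family(self, path: str, mean: float) -> str:
        if path in _FRACTION_FIELDS and 0.0 <= mean <= 1.0:
            return "beta"
        return "gamma"

    def cv_for(self, path: str) -> float:
        return self.cv_overrides.get(path, self.cv)


_BETA_WARNED: set[str] = set()


def _draw_one(rng: np.random.Generator, family: str, mean: float, cv: float, path: str) -> float:
    if cv <= 0 or mean == 0:
        return mean
    if family == "gamma":
        shape = 1.0 / cv**2
        return float(rng.gamma(shape, mean * cv**2))
    # beta by method of moments
    sd = cv * mean
    bound = mean * (1.0 - mean)
    if sd**2 >= bound:
        sd = 0.99 * np.sqrt(bound)
        if path not in _BETA_WARNED:
            warnings.warn(
                f"{path}: beta sd infeasible at cv={cv}; shrunk to the moment bound",
                stacklevel=2,
            )
            _BETA_WARNED.add(path)
    nu = bound / sd**2 - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    return float(rng.beta(a, b))


def draw_parameters(
    base: ModelParameters, spec: PSASpec, k: int
) -> ModelParameters:
    """Parameter set for draw ``k``; reproducible via the (seed, k) stream."""
    rng = np.random.default_rng([int(spec.seed), int(k)])
    params = base
    for path in spec.parameters:
        mean = get_param(base, path)
        value = _draw_one(rng, spec.family(path, mean), mean, spec.cv_for(path), path)
        value, _ = _clamped(path, value)
        try:
            params = set_param(params, path, value)
        except ParameterError:
            # a draw outside the validity region keeps the base value
            continue
    return params


@dataclass
class PSAResult:
    """Incremental cost/QALY per PSA draw, plus the PSASpec that produced them."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    spec: PSASpec

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d_cost": self.delta_cost, "d_qaly": self.delta_qaly})


def run_psa(
    base: ModelParameters,
    spec: PSASpec | None = None,
    n_draws: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Monte Carlo over parameter uncertainty: one model run per draw."""
    spec = spec if spec is not None else PSASpec()
    if n_draws is not None:
        spec = dataclasses.replace(spec, n_draws=n_draws)
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    d_cost = np.empty(spec.n_draws)
    d_qaly = np.empty(spec.n_draws)
    for k in range(spec.n_draws):
        res = _run(draw_parameters(base, spec, k))
        d_cost[k] = res.delta_cost
        d_qaly[k] = res.delta_qaly
    return PSAResult(delta_cost=d_cost, delta_qaly=d_qaly, spec=spec)


DEFAULT_WTP_GRID = np.arange(0, 10_000_001, 100_000)


def ceac(result: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Probability TAI is cost-effective at each willingness-to-pay value.

    A draw counts as cost-effective at WTP ``w`` when its net monetary
    benefit ``w * dQALY - dCost`` is nonnegative.
    """
    grid = np.asarray(DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if result.n_draws < 1:
        raise ValueError("need at least one PSA draw")
    nmb = grid[:, None] * result.delta_qaly[None, :] - result.delta_cost[None, :]
    prob = (nmb >= 0).mean(axis=1)
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": prob})
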