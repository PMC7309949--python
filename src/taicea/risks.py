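"""Derived clinical-risk quantities.

Relative risks between treatment arms, the exponential stoma-incidence rate
estimated from time-to-event survey data, and the logistic regression of the
visiting-nursing indicator on NBD score, age, gender and hand function.

The base-case engine consumes the calibrated nursing rates directly; the
regression path exists to re-derive them from (synthetic) survey data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "relative_risk",
    "exponential_rate_per_cycle",
    "exponential_hazard",
    "NursingVisitModel",
    "NursingVisitResults",
]


def relative_risk(p_treated: float, p_control: float) -> float:
    """Ratio of event rates, treated over control."""
    if p_treated < 0 or p_control < 0:
        raise ValueError("rates must be nonnegative")
    if p_control == 0:
        raise ZeroDivisionError("relative risk undefined for zero control rate")
    return p_treated / p_control


def exponential_hazard(durations, events) -> float:
    """Exponential maximum-likelihood hazard: events per person-year.

    ``durations`` are observed times in years (event or censoring);
    ``events`` are 0/1 indicators.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=float)
    if (durations <= 0).any():
        raise ValueError("durations must be positive")
    total_time = durations.sum()
    if total_time <= 0:
        raise ValueError("total follow-up time must be positive")
    return float(events.sum() / total_time)


def exponential_rate_per_cycle(durations, events, cycle_years: float = 0.5) -> float:
    """Per-cycle event probability 1 - exp(-lambda * cycle) from the MLE hazard."""
    lam = exponential_hazard(durations, events)
    return float(1.0 - np.exp(-lam * cycle_years))


@dataclass
class NursingVisitResults:
    """Fitted logistic model of the visiting-nursing indicator."""

    params: pd.Series
    bse: pd.Series
    converged: bool
    nobs: int
    sm_results: object

    def predict(self, nbds, age, male, hand_impaired) -> np.ndarray:
        """Probability of receiving visiting nursing via the inverse logit."""
        nbds, age, male, hand = np.broadcast_arrays(
            np.atleast_1d(np.asarray(nbds, dtype=float)),
            np.asarray(age, dtype=float),
            np.asarray(male, dtype=float),
            np.asarray(hand_impaired, dtype=float),
        )
        x = np.column_stack([np.ones_like(nbds), nbds, age, male, hand])
        eta = x @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        return str(self.sm_results.summary())


class NursingVisitModel:
    """Logistic regression of nursing-visit use on NBDS, age, gender, hand function.

    Built from a survey table with columns ``nursing_visit``, ``nbds``,
    ``age``, ``male`` (or ``gender``), ``hand_impaired``.
    """

    COLUMNS = ["const", "nbds", "age", "male", "hand_impaired"]

    def __init__(self, endog: np.ndarray, exog: np.ndarray):
        if len(endog) < 50:
            raise ValueError(f"need >= 50 records to fit, got {len(endog)}")
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "NursingVisitModel":
        male = (
            df["male"]
            if "male" in df.columns
            else (df["gender"].astype(str).str.lower() == "male").astype(float)
        )
        exog = np.column_stack(
            [
                np.ones(len(df)),
                df["nbds"].to_numpy(float),
                df["age"].to_numpy(float),
                np.asarray(male, dtype=float),
                df["hand_impaired"].to_numpy(float),
            ]
        )
        return cls(df["nursing_visit"].to_numpy(float), exog)

    def fit(self) -> NursingVisitResults:
        y = self.endog
        if y.min() == y.max():
            raise RuntimeError(
                "nursing-visit outcome is constant; logistic fit is separated"
            )
        model = sm.Logit(y, self.exog)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation raises in statsmodels
            raise RuntimeError(f"nursing logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("nursing logistic fit did not converge")
        params = pd.Series(res.params, index=self.COLUMNS)
        bse = pd.Series(res.bse, index=self.COLUMNS)
        return NursingVisitResults(
            params=params,
            bse=bse,
            converged=True,
            nobs=int(res.nobs),
            sm_results=res,
        )
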