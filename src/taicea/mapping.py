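"""Mapping NBD score to EQ-5D-5L utility.

Per-dimension multinomial-logit models of the five EQ-5D-5L levels on NBD
score, age and gender are fitted to survey data; expected utility at each
integer NBD score (0-47) is then estimated by Monte Carlo: for every trial
one uniform draw per dimension picks a level through the cumulative level
probabilities, the five levels form a profile, and a value set converts the
profile to a utility.  The exact expectation over all 5^5 = 3125 profiles is
also available and serves as a cross-check for the simulation.

The packaged value set is a stylized additive tariff (full health = 1.0,
nonnegative per-dimension level decrements); a country tariff with the same
CSV layout can be dropped in without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import UtilityParams

__all__ = [
    "DIMENSIONS",
    "SURVEY_LEVEL_COLUMNS",
    "ValueSet",
    "assign_level",
    "EQ5DMapping",
    "EQ5DMappingResults",
    "UtilityCurve",
    "state_utilities_from_curve",
]

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)
# survey CSV column names, in dimension order
SURVEY_LEVEL_COLUMNS = ("eq5d_mo", "eq5d_sc", "eq5d_ua", "eq5d_pd", "eq5d_ad")
N_LEVELS = 5
COVARIATES = ("const", "nbds", "age", "male")


class ValueSet:
    """Additive EQ-5D-5L tariff: utility = 1 - sum of level decrements.

    ``decrements`` is a (5 dimensions x 5 levels) array with level-1
    decrements equal to zero, so the full-health profile (1,1,1,1,1) maps
    to exactly 1.0 and no profile exceeds 1.0.
    """

    def __init__(self, decrements: np.ndarray):
        decrements = np.asarray(decrements, dtype=float)
        if decrements.shape != (len(DIMENSIONS), N_LEVELS):
            raise ValueError("decrements must be a 5x5 array")
        if (decrements < 0).any():
            raise ValueError("decrements must be nonnegative")
        if not np.allclose(decrements[:, 0], 0.0):
            raise ValueError("level-1 decrements must be 0 (full-health anchor)")
        self.decrements = decrements

    @classmethod
    def from_csv(cls, path: str | Path) -> "ValueSet":
        df = pd.read_csv(path)
        dec = np.zeros((len(DIMENSIONS), N_LEVELS))
        for d, name in enumerate(DIMENSIONS):
            sub = df[df["dimension"] == name].set_index("level")["decrement"]
            dec[d] = [sub[k] for k in range(1, N_LEVELS + 1)]
        return cls(dec)

    @classmethod
    def packaged(cls) -> "ValueSet":
        with resources.as_file(
            resources.files("taicea.data") / "value_set_stylized.csv"
        ) as p:
            return cls.from_csv(p)

    def utility(self, profile) -> float | np.ndarray:
        """Utility of one profile (5 levels, each 1-5) or an array of profiles."""
        profile = np.asarray(profile, dtype=int)
        if profile.min() < 1 or profile.max() > N_LEVELS:
            raise ValueError("levels must be in 1..5")
        idx = profile - 1
        dims = np.arange(len(DIMENSIONS))
        return 1.0 - self.decrements[dims, idx].sum(axis=-1)


def assign_level(u: float, cum_probs) -> int:
    """Invert cumulative level probabilities at a uniform draw.

    Returns the smallest level k with ``u <= P(level <= k)``: level 1 when
    ``u`` is at most the level-1 probability, level 5 when ``u`` exceeds the
    cumulative probability of the first four levels.
    """
    cum = np.asarray(cum_probs, dtype=float)
    if cum.ndim != 1 or len(cum) != N_LEVELS:
        raise ValueError("cum_probs must have 5 entries")
    if (np.diff(cum) < -1e-12).any():
        raise ValueError("cum_probs must be non-decreasing")
    if abs(cum[-1] - 1.0) > 1e-9:
        raise ValueError(f"cum_probs must end at 1, got {cum[-1]!r}")
    return int(np.searchsorted(cum, u, side="left")) + 1


@dataclass
class _DimensionFit:
    """MNLogit coefficients for one dimension.

    ``coef`` has shape (5 levels x 4 covariates) relative to level 1;
    unobserved levels are masked out and receive probability zero.
    """

    coef: np.ndarray
    present: np.ndarray  # bool mask over levels 1..5
    converged: bool = True

    def level_probs(self, x: np.ndarray) -> np.ndarray:
        eta = np.where(self.present, self.coef @ x, -np.inf)
        eta = eta - eta.max()
        w = np.exp(eta)
        return w / w.sum()


@dataclass
class UtilityCurve:
    """Expected utility per integer NBD score with Monte Carlo standard errors."""

    nbds: np.ndarray
    utility: np.ndarray
    mc_se: np.ndarray
    trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"nbds": self.nbds, "utility": self.utility, "mc_se": self.mc_se}
        )

    def lookup(self, score: float) -> float:
        """Utility at a (rounded half-up) NBD score, clamped to [0, 47]."""
        rounded = int(np.floor(score + 0.5))
        if rounded < 0 or rounded > 47:
            warnings.warn(
                f"NBDS {score!r} outside [0, 47]; clamping", stacklevel=2
            )
            rounded = min(max(rounded, 0), 47)
        return float(self.utility[np.searchsorted(self.nbds, rounded)])


class EQ5DMappingResults:
    """Fitted per-dimension multinomial-logit level models."""

    def __init__(self, fits: dict[str, _DimensionFit], nobs: int = 0):
        self.fits = fits
        self.nobs = nobs

    @classmethod
    def from_coefficients(cls, coefs: dict[str, np.ndarray]) -> "EQ5DMappingResults":
        """Build directly from known (5 x 4) coefficient arrays per dimension."""
        fits = {
            dim: _DimensionFit(
                coef=np.asarray(c, dtype=float), present=np.ones(N_LEVELS, bool)
            )
            for dim, c in coefs.items()
        }
        return cls(fits)

    def _x(self, nbds: float, age: float, male: float) -> np.ndarray:
        return np.array([1.0, float(nbds), float(age), float(male)])

    def level_probs(self, dimension: str, nbds: float, age: float, male: float) -> np.ndarray:
        """P(level = 1..5) for one dimension at the given covariates."""
        return self.fits[dimension].level_probs(self._x(nbds, age, male))

    def profile_prob_matrix(self, nbds: float, age: float, male: float) -> np.ndarray:
        """(5 dimensions x 5 levels) matrix of level probabilities."""
        x = self._x(nbds, age, male)
        return np.vstack([self.fits[d].level_probs(x) for d in DIMENSIONS])

    def nbds_slope(self, dimension: str) -> np.ndarray:
        """Fitted NBDS coefficients for levels 2..5 relative to level 1."""
        return self.fits[dimension].coef[1:, COVARIATES.index("nbds")]

    # --- Monte Carlo and exact expectations ----------------------------
    def simulate_expected_utility(
        self,
        nbds: int,
        value_set: ValueSet,
        trials: int = 10_000,
        seed: int = 0,
        age: float = 51.46,
        male: float = 1.0,
    ) -> tuple[float, float]:
        """Monte Carlo expected utility at one NBD score.

        One independent uniform per dimension per trial inverts the
        cumulative level probabilities; the resulting profile is valued by
        the tariff.  The RNG stream is keyed by (seed, nbds) so every score
        is reproducible in isolation.
        """
        if trials < 1:
            raise ValueError("trials must be >= 1")
        probs = self.profile_prob_matrix(nbds, age, male)
        cum = np.cumsum(probs, axis=1)
        cum[:, -1] = 1.0
        rng = np.random.default_rng([int(seed), int(nbds)])
        u = rng.random((trials, len(DIMENSIONS)))
        # vectorized cumulative inversion, identical to assign_level per cell
        levels = (u[:, :, None] > cum[None, :, :]).sum(axis=2) + 1
        dims = np.arange(len(DIMENSIONS))
        utilities = 1.0 - value_set.decrements[dims, levels - 1].sum(axis=1)
        mean = float(utilities.mean())
        se = float(utilities.std(ddof=1) / np.sqrt(trials)) if trials > 1 else float("nan")
        return mean, se

    def exact_expected_utility(
        self,
        nbds: int,
        value_set: ValueSet,
        age: float = 51.46,
        male: float = 1.0,
    ) -> float:
        """Exact expectation by enumeration of all 3125 profiles."""
        probs = self.profile_prob_matrix(nbds, age, male)
        total = 0.0
        for profile in product(range(1, N_LEVELS + 1), repeat=len(DIMENSIONS)):
            p = 1.0
            for d, lvl in enumerate(profile):
                p *= probs[d, lvl - 1]
            total += p * value_set.utility(profile)
        return total

    def utility_curve(
        self,
        value_set: ValueSet,
        trials: int = 10_000,
        seed: int = 0,
        age: float = 51.46,
        male: float = 1.0,
        scores=range(0, 48),
    ) -> UtilityCurve:
        """Expected utility at every integer NBD score (default 0-47)."""
        means, ses = [], []
        for j in scores:
            m, s = self.simulate_expected_utility(
                j, value_set, trials=trials, seed=seed, age=age, male=male
            )
            means.append(m)
            ses.append(s)
        return UtilityCurve(
            nbds=np.asarray(list(scores)),
            utility=np.asarray(means),
            mc_se=np.asarray(ses),
            trials=trials,
        )


class EQ5DMapping:
    """Multinomial-logit mapping of EQ-5D-5L levels on NBDS, age and gender.

    Built from a survey table with columns ``nbds``, ``age``, ``male`` (or
    ``gender``) and the five level columns ``eq5d_mo`` .. ``eq5d_ad``.
    """

    def __init__(self, levels: np.ndarray, exog: np.ndarray):
        levels = np.asarray(levels, dtype=int)
        if levels.shape[1] != len(DIMENSIONS):
            raise ValueError("levels must have one column per dimension")
        if levels.min() < 1 or levels.max() > N_LEVELS:
            raise ValueError("levels must be in 1..5")
        if len(levels) < 50:
            raise ValueError(f"need >= 50 records to fit, got {len(levels)}")
        self.levels = levels
        self.exog = np.asarray(exog, dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EQ5DMapping":
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
            ]
        )
        levels = df[list(SURVEY_LEVEL_COLUMNS)].to_numpy(int)
        return cls(levels, exog)

    def fit(self) -> EQ5DMappingResults:
        """Maximum-likelihood MNLogit per dimension (reference: lowest level).

        A dimension observed at a single level yields a degenerate model
        predicting that level with probability one.  Non-convergence raises
        with the dimension named.
        """
        fits: dict[str, _DimensionFit] = {}
        for d, dim in enumerate(DIMENSIONS):
            y = self.levels[:, d]
            observed = np.unique(y)
            coef = np.zeros((N_LEVELS, len(COVARIATES)))
            present = np.zeros(N_LEVELS, dtype=bool)
            present[observed - 1] = True
            if len(observed) == 1:
                fits[dim] = _DimensionFit(coef=coef, present=present)
                continue
            # recode to 0..k-1 for statsmodels; reference = lowest observed
            recode = {lvl: i for i, lvl in enumerate(observed)}
            y_rec = np.array([recode[v] for v in y])
            model = sm.MNLogit(y_rec, self.exog)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(disp=0, maxiter=500, method="newton")
                except Exception:
                    res = None
            if res is None or not res.mle_retvals.get("converged", False):
                # fall back to BFGS before declaring failure
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        res = model.fit(disp=0, maxiter=2000, method="bfgs")
                    except Exception as exc:
                        raise RuntimeError(f"{dim}: MNLogit fit failed: {exc}") from exc
                if not res.mle_retvals.get("converged", False):
                    raise RuntimeError(f"{dim}: MNLogit fit did not converge")
            # res.params: (n_cov x n_levels-1), columns are non-reference levels
            beta = np.asarray(res.params)
            for j, lvl in enumerate(observed[1:]):
                coef[lvl - 1] = beta[:, j]
            fits[dim] = _DimensionFit(coef=coef, present=present)
        return EQ5DMappingResults(fits, nobs=len(self.levels))


def state_utilities_from_curve(
    curve: UtilityCurve,
    nbds_baseline: float = 16.74,
    delta_responder: float = -6.0,
    delta_nonresponder: float = 1.0,
    u_stoma: float = 0.564,
    du_uti_per_event: float = 0.060,
    du_hosp_per_event: float = 0.010,
) -> UtilityParams:
    """Derive state utilities from a mapped utility curve.

    Looks up the curve at the (rounded) baseline score for the SBC state and
    at baseline plus the responder / non-responder NBDS shifts.  The stoma
    utility and event decrements are not NBDS-based and pass through.
    """
    return UtilityParams(
        u_responder=curve.lookup(nbds_baseline + delta_responder),
        u_nonresponder=curve.lookup(nbds_baseline + delta_nonresponder),
        u_sbc=curve.lookup(nbds_baseline),
        u_stoma=u_stoma,
        du_uti_per_event=du_uti_per_event,
        du_hosp_per_event=du_hosp_per_event,
    )
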