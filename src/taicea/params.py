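"""Parameter containers for the TAI vs SBC cost-effectiveness model.

The base case describes a Japanese spinal-cord-injury cohort with neurogenic
bowel dysfunction (NBD) choosing between transanal irrigation (TAI, the
Peristeen system) and standard bowel care (SBC).  All monetary quantities are
yen; event rates are per 6-month model cycle unless a field name says
otherwise.  The packaged defaults live in ``data/defaults.yaml`` and are the
calibrated base case; :func:`load_parameters` reads that file and applies
user overrides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterError",
    "EconSettings",
    "ClinicalParams",
    "UtilityParams",
    "CostParams",
    "ProductivityParams",
    "MortalityTable",
    "ModelParameters",
    "load_parameters",
    "default_parameters",
]

_PERSPECTIVES = ("payer", "societal_absenteeism", "societal_full")


class ParameterError(ValueError):
    """A parameter failed validation; the message names the offending field."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ParameterError(f"{field_name}: {message}")


def _check_fraction(value: float, name: str) -> None:
    _require(0.0 <= value <= 1.0, name, f"must be in [0, 1], got {value!r}")


def _check_nonneg(value: float, name: str) -> None:
    _require(value >= 0.0, name, f"must be >= 0, got {value!r}")


@dataclass
class EconSettings:
    """Time horizon, discounting, perspective and fee settings."""

    cycle_length_years: float = 0.5
    annual_discount_rate: float = 0.02
    age_cutoff: float = 110.0
    start_age: float = 51.46
    male_fraction: float = 0.783
    perspective: str = "payer"
    tai_procedure_fee_per_month: float = 18000.0
    half_cycle_correction: bool = False
    smr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.cycle_length_years > 0, "cycle_length_years", "must be > 0")
        _require(
            0.0 <= self.annual_discount_rate < 1.0,
            "annual_discount_rate",
            f"must be in [0, 1), got {self.annual_discount_rate!r}",
        )
        _require(self.age_cutoff > self.start_age, "age_cutoff", "must exceed start_age")
        _check_fraction(self.male_fraction, "male_fraction")
        _require(
            self.perspective in _PERSPECTIVES,
            "perspective",
            f"must be one of {_PERSPECTIVES}, got {self.perspective!r}",
        )
        _require(self.tai_procedure_fee_per_month > 0, "tai_procedure_fee_per_month", "must be > 0")
        _require(self.smr > 0, "smr", "must be > 0")


@dataclass
class ClinicalParams:
    """Event rates and treatment-response parameters (per 6-month cycle)."""

    responder_fraction: float = 0.60
    nonresponder_withdrawal_per_cycle: float = 0.60
    all_nonresponders_withdraw_after_first_cycle: bool = False
    nbds_baseline: float = 16.74
    nbds_delta_responder: float = -6.0
    nbds_delta_nonresponder: float = 1.0
    uti_rate_sbc_per_cycle: float = 0.512
    uti_rate_tai_per_cycle: float = 0.195
    hosp_decubitus_sbc: float = 0.31
    hosp_decubitus_tai: float = 0.14
    hosp_other_sbc: float = 1.73
    hosp_other_tai: float = 0.77
    hospitalization_recall_years: float = 8.5
    nursing_rate_sbc: float = 0.318
    nursing_rate_tai: float = 0.1941
    nursing_visits_per_week: float = 2.0
    stoma_rate_per_cycle: float = 0.00033
    laparoscopic_fraction: float = 0.575
    uti_split_hospitalized: float = 0.086
    uti_split_outpatient: float = 0.811
    uti_split_untreated: float = 0.103
    stoma_events_at_sbc_rates: bool = True

    def __post_init__(self) -> None:
        for name in (
            "responder_fraction",
            "nonresponder_withdrawal_per_cycle",
            "nursing_rate_sbc",
            "nursing_rate_tai",
            "stoma_rate_per_cycle",
            "laparoscopic_fraction",
            "uti_split_hospitalized",
            "uti_split_outpatient",
            "uti_split_untreated",
        ):
            _check_fraction(getattr(self, name), name)
        for name in (
            "uti_rate_sbc_per_cycle",
            "uti_rate_tai_per_cycle",
            "hosp_decubitus_sbc",
            "hosp_decubitus_tai",
            "hosp_other_sbc",
            "hosp_other_tai",
            "nursing_visits_per_week",
        ):
            _check_nonneg(getattr(self, name), name)
        _require(
            self.hospitalization_recall_years > 0,
            "hospitalization_recall_years",
            "must be > 0",
        )
        split = (
            self.uti_split_hospitalized
            + self.uti_split_outpatient
            + self.uti_split_untreated
        )
        _require(
            abs(split - 1.0) <= 1e-9,
            "uti_split",
            f"hospitalized + outpatient + untreated must sum to 1, got {split!r}",
        )

    @property
    def uti_treatment_split(self) -> tuple[float, float, float]:
        return (
            self.uti_split_hospitalized,
            self.uti_split_outpatient,
            self.uti_split_untreated,
        )


@dataclass
class UtilityParams:
    """State utilities and per-event utility decrements (Table-style base case)."""

    u_responder: float = 0.533
    u_nonresponder: float = 0.470
    u_sbc: float = 0.479
    u_stoma: float = 0.564
    du_uti_per_event: float = 0.060
    du_hosp_per_event: float = 0.010

    def __post_init__(self) -> None:
        for name in ("u_responder", "u_nonresponder", "u_sbc", "u_stoma"):
            value = getattr(self, name)
            _require(-1.0 <= value <= 1.0, name, f"state utility must be in [-1, 1], got {value!r}")
        _check_nonneg(self.du_uti_per_event, "du_uti_per_event")
        _check_nonneg(self.du_hosp_per_event, "du_hosp_per_event")


@dataclass
class CostParams:
    """Unit costs in yen (medical fee schedule, specialist survey, MDV claims)."""

    device_cost_per_year: float = 280945.0
    peristeen_system_cost_per_set: float = 12095.0
    peristeen_system_sets_per_year: float = 2.0
    peristeen_accessory_cost_per_year: float = 256755.0
    sbc_cost_per_month: float = 4151.0
    stoma_fee_laparoscopic: float = 139200.0
    stoma_fee_open: float = 79800.0
    stoma_hosp_laparoscopic: float = 236311.0
    stoma_hosp_open: float = 242686.0
    stoma_mgmt_month_y1: float = 4131.0
    stoma_mgmt_month_after: float = 1621.0
    uti_cost_hospitalized: float = 163113.0
    uti_cost_outpatient: float = 14126.0
    uti_cost_untreated: float = 10293.0
    nursing_cost_per_visit: float = 5800.0
    nursing_premium_per_week: float = 5200.0
    hosp_cost_decubitus: float = 1512630.0
    hosp_cost_other: float = 630960.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_nonneg(getattr(self, f.name), f.name)


@dataclass
class ProductivityParams:
    """Human-capital productivity-loss inputs for the societal scenario."""

    employment_rate: float = 0.488
    absenteeism_minor: float = 0.0
    absenteeism_moderate: float = 0.0221
    absenteeism_severe: float = 0.0701
    presenteeism_minor: float = 0.17
    presenteeism_moderate: float = 0.3636
    presenteeism_severe: float = 0.3971
    wage_per_month_50_54: float = 364163.0
    wage_per_month_55_59: float = 350789.0
    wage_per_month_60_64: float = 262659.0
    wage_per_month_65_69: float = 244283.0
    wage_per_month_70_plus: float = 248227.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name.startswith("wage_"):
                _check_nonneg(value, f.name)
            else:
                _check_fraction(value, f.name)

    def wage_per_month(self, age: float) -> float:
        """Monthly scheduled wage (yen) for the age band containing ``age``.

        Ages below 50 fall back to the 50-54 band: the cohort starts above 50,
        so this only matters for user-modified configurations.
        """
        if age < 55:
            return self.wage_per_month_50_54
        if age < 60:
            return self.wage_per_month_55_59
        if age < 65:
            return self.wage_per_month_60_64
        if age < 70:
            return self.wage_per_month_65_69
        return self.wage_per_month_70_plus

    def absenteeism(self, category: str) -> float:
        return {
            "below_minor": 0.0,
            "minor": self.absenteeism_minor,
            "moderate": self.absenteeism_moderate,
            "severe": self.absenteeism_severe,
        }[category]

    def presenteeism(self, category: str) -> float:
        return {
            "below_minor": self.presenteeism_minor,
            "minor": self.presenteeism_minor,
            "moderate": self.presenteeism_moderate,
            "severe": self.presenteeism_severe,
        }[category]


class MortalityTable:
    """Annual death probabilities by age and sex.

    The packaged fixture ``data/life_table_stylized.csv`` is a stylized
    Gompertz-Makeham table approximating recent Japanese all-cause mortality;
    it is synthetic, user-replaceable data, not an official life table.  An
    optional standardized-mortality multiplier scales every probability.
    """

    def __init__(self, table: pd.DataFrame, smr: float = 1.0):
        required = {"age", "qx_male", "qx_female"}
        if not required.issubset(table.columns):
            raise ParameterError(f"life table must have columns {sorted(required)}")
        table = table.sort_values("age").reset_index(drop=True)
        ages = table["age"].to_numpy()
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
            raise ParameterError("life table ages must be consecutive integers")
        for col in ("qx_male", "qx_female"):
            q = table[col].to_numpy(float)
            if ((q < 0) | (q > 1)).any():
                raise ParameterError(f"{col}: probabilities must be in [0, 1]")
        self._min_age = int(ages[0])
        self._max_age = int(ages[-1])
        self._qm = table["qx_male"].to_numpy(float)
        self._qf = table["qx_female"].to_numpy(float)
        self.smr = float(smr)

    @classmethod
    def from_csv(cls, path: str | Path, smr: float = 1.0) -> "MortalityTable":
        return cls(pd.read_csv(path), smr=smr)

    @classmethod
    def packaged(cls, smr: float = 1.0) -> "MortalityTable":
        with resources.as_file(
            resources.files("taicea.data") / "life_table_stylized.csv"
        ) as p:
            return cls.from_csv(p, smr=smr)

    @property
    def max_age(self) -> int:
        return self._max_age

    def annual_q(self, age: float, male_fraction: float) -> float:
        """Sex-weighted annual death probability at integer age ``floor(age)``."""
        idx = int(np.floor(age)) - self._min_age
        idx = min(max(idx, 0), len(self._qm) - 1)
        q = male_fraction * self._qm[idx] + (1.0 - male_fraction) * self._qf[idx]
        return float(min(1.0, self.smr * q))

    def cycle_q(self, age: float, male_fraction: float, cycle_years: float) -> float:
        """Death probability over one cycle, from the annual probability."""
        qa = self.annual_q(age, male_fraction)
        return float(1.0 - (1.0 - qa) ** cycle_years)


@dataclass
class ModelParameters:
    """The complete calibrated parameter set consumed by the Markov engine."""

    settings: EconSettings = field(default_factory=EconSettings)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    utility: UtilityParams = field(default_factory=UtilityParams)
    cost: CostParams = field(default_factory=CostParams)
    productivity: ProductivityParams = field(default_factory=ProductivityParams)
    mortality: MortalityTable = field(default_factory=MortalityTable.packaged)

    # --- derived quantities used throughout the engine ------------------
    @property
    def expected_uti_episode_cost(self) -> float:
        """Treatment-split-weighted mean cost of one UTI episode (yen)."""
        c = self.cost
        s = self.clinical
        return (
            s.uti_split_hospitalized * c.uti_cost_hospitalized
            + s.uti_split_outpatient * c.uti_cost_outpatient
            + s.uti_split_untreated * c.uti_cost_untreated
        )

    @property
    def expected_stoma_surgery_fee(self) -> float:
        """Laparoscopic-share-weighted colostomy fee (yen)."""
        f = self.clinical.laparoscopic_fraction
        return f * self.cost.stoma_fee_laparoscopic + (1 - f) * self.cost.stoma_fee_open

    @property
    def expected_stoma_surgery_hospitalization(self) -> float:
        """Laparoscopic-share-weighted hospitalization cost at stoma surgery (yen)."""
        f = self.clinical.laparoscopic_fraction
        return f * self.cost.stoma_hosp_laparoscopic + (1 - f) * self.cost.stoma_hosp_open

    @property
    def weekly_nursing_cost(self) -> float:
        """Cost of one week of visiting nursing for a user of the service."""
        return (
            self.clinical.nursing_visits_per_week * self.cost.nursing_cost_per_visit
            + self.cost.nursing_premium_per_week
        )

    @property
    def hosp_cycles_in_recall(self) -> float:
        """Number of model cycles spanned by the hospitalization recall period."""
        return self.clinical.hospitalization_recall_years / self.settings.cycle_length_years

    def replace(self, **sections: Any) -> "ModelParameters":
        """Return a copy with whole sections replaced (``dataclasses.replace``)."""
        return dataclasses.replace(self, **sections)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in ("settings", "clinical", "utility", "cost", "productivity"):
            out[name] = dataclasses.asdict(getattr(self, name))
        return out


_SECTION_TYPES = {
    "settings": EconSettings,
    "clinical": ClinicalParams,
    "utility": UtilityParams,
    "cost": CostParams,
    "productivity": ProductivityParams,
}


def _packaged_defaults() -> dict[str, Any]:
    text = (resources.files("taicea.data") / "defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    merged = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def load_parameters(
    source: str | Path | Mapping | None = None,
    life_table: str | Path | None = None,
) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from defaults plus overrides.

    ``source`` may be a YAML file path, a nested mapping of overrides, or
    ``None`` for the packaged base case.  Unknown sections or fields raise
    :class:`ParameterError` naming the offender.
    """
    defaults = _packaged_defaults()
    if source is None:
        merged = defaults
    elif isinstance(source, Mapping):
        merged = _deep_merge(defaults, source)
    else:
        with open(source) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ParameterError(f"config file {source} must contain a mapping")
        merged = _deep_merge(defaults, loaded)

    sections: dict[str, Any] = {}
    for key, value in merged.items():
        if key not in _SECTION_TYPES:
            raise ParameterError(f"{key}: unknown configuration section")
        cls = _SECTION_TYPES[key]
        known = {f.name for f in fields(cls)}
        unknown = set(value) - known
        if unknown:
            raise ParameterError(f"{key}.{sorted(unknown)[0]}: unknown field")
        try:
            sections[key] = cls(**value)
        except TypeError as exc:  # wrong type signature
            raise ParameterError(f"{key}: {exc}") from exc

    settings = sections["settings"]
    if life_table is not None:
        mortality = MortalityTable.from_csv(life_table, smr=settings.smr)
    else:
        mortality = MortalityTable.packaged(smr=settings.smr)
    return ModelParameters(mortality=mortality, **sections)


def default_parameters() -> ModelParameters:
    """The packaged base case."""
    return load_parameters(None)
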