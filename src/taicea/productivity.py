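"""Societal-perspective productivity losses by NBD severity.

Human-capital costing: employment rate x age-band monthly wage x months per
cycle x a loss fraction.  The loss fraction is absenteeism alone, or
absenteeism plus presenteeism capped at 1, by NBD severity category.
"""

from __future__ import annotations

from .params import ProductivityParams

__all__ = ["NBDS_CATEGORIES", "nbds_category", "productivity_loss_per_cycle"]

# Severity bands on the 0-47 NBD score: minor 7-9, moderate 10-13, severe >=14.
NBDS_CATEGORIES = ("below_minor", "minor", "moderate", "severe")


def nbds_category(score: float) -> str:
    """Bin a (possibly fractional) NBD score into its severity category.

    Fractional scores are rounded half-up to the nearest integer first, so
    e.g. a responder at baseline 16.74 - 6 = 10.74 rounds to 11 (moderate).
    """
    if not 0.0 <= score <= 47.0:
        raise ValueError(f"NBDS must be in [0, 47], got {score!r}")
    rounded = int(score + 0.5)  # round half up on the nonnegative support
    if rounded < 7:
        return "below_minor"
    if rounded <= 9:
        return "minor"
    if rounded <= 13:
        return "moderate"
    return "severe"


def productivity_loss_per_cycle(
    age: float,
    category: str,
    params: ProductivityParams,
    mode: str = "absenteeism",
    cycle_length_years: float = 0.5,
) -> float:
    """Expected productivity loss in yen for one person-cycle.

    ``mode`` is ``"absenteeism"`` or ``"absenteeism_plus_presenteeism"``;
    in the combined mode the two fractions are added and capped at 1.
    """
    if category not in NBDS_CATEGORIES:
        raise ValueError(f"unknown NBDS category {category!r}")
    if mode == "absenteeism":
        loss = params.absenteeism(category)
    elif mode == "absenteeism_plus_presenteeism":
        loss = min(1.0, params.absenteeism(category) + params.presenteeism(category))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    months = cycle_length_years * 12.0
    return params.employment_rate * params.wage_per_month(age) * months * loss
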