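"""Trait-by-environment proportion tables (habitat, oxygen requirement).

For each category of an environmental factor the table reports how many
organisms carry a feature (the Mo trait, a transporter, an enzyme family,
or molybdoprotein richness), the percentage at two decimals, and an
exact (Clopper-Pearson) binomial 95% confidence interval.  Organisms
with an unknown factor value are excluded from denominators; by default
the analysis runs on bacteria only, since archaeal habitat/oxygen
sampling is heavily skewed.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Mapping, Sequence

import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

from .iocore import HABITATS, OXYGEN_REQS, OrganismMetadata
from .profiler import round_half_up
from .registry import ENZYME_FAMILIES, TRANSPORTER_SYSTEMS
from .traitcall import TraitCall

log = logging.getLogger(__name__)

FACTORS: dict[str, tuple[str, ...]] = {
    "habitat": HABITATS,
    "oxygen_req": OXYGEN_REQS,
}

FeatureSelector = Callable[[TraitCall], bool]


def feature_selector(name: str) -> FeatureSelector:
    """Resolve a feature name to a predicate on trait calls.

    Accepted names: ``mo_trait``, ``rich``, any transporter system
    (ModABC, WtpABC, TupABC, MOT1, MOT2) and any enzyme family
    (SO, XO, DMSOR, AOR, MOSC) or ``nif``.
    """
    if name == "mo_trait":
        return lambda c: c.mo_utilizing
    if name == "rich":
        return lambda c: c.rich
    if name == "nif":
        return lambda c: c.nitrogenase
    if name in TRANSPORTER_SYSTEMS:
        return lambda c: name in c.transporters
    if name in ENZYME_FAMILIES:
        raise ValueError(
            f"enzyme-family selector {name!r} needs profiles; "
            "pass a callable to trait_by_factor instead"
        )
    raise ValueError(f"unknown feature selector {name!r}")


def trait_by_factor(
    calls: Sequence[TraitCall],
    metadata: Mapping[str, OrganismMetadata],
    factor: str,
    feature: str | FeatureSelector = "mo_trait",
    kingdoms: tuple[str, ...] = ("bacteria",),
    decimals: int = 2,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-category feature proportions with exact binomial CIs.

    ``factor`` is ``habitat`` or ``oxygen_req``; organisms whose value
    is unknown are excluded.  ``kingdoms`` restricts the denominator
    (bacteria only by default; add "archaea" to include it).
    """
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {sorted(FACTORS)}")
    selector = feature_selector(feature) if isinstance(feature, str) else feature
    rows = []
    known_total = 0
    for category in FACTORS[factor]:
        members = [
            c
            for c in calls
            if c.organism_id in metadata
            and metadata[c.organism_id].kingdom in kingdoms
            and getattr(metadata[c.organism_id], factor) == category
        ]
        n_total = len(members)
        known_total += n_total
        n_with = sum(1 for c in members if selector(c))
        if n_total:
            low, high = proportion_confint(
                n_with, n_total, alpha=1 - confidence, method="beta"
            )
            row = {
                "category": category,
                "n_total": n_total,
                "n_with_feature": n_with,
                "percent": round_half_up(100 * n_with / n_total, decimals),
                "ci_low": round_half_up(100 * low, decimals),
                "ci_high": round_half_up(100 * high, decimals),
            }
        else:
            row = {
                "category": category,
                "n_total": 0,
                "n_with_feature": 0,
                "percent": float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
            }
        rows.append(row)
    if known_total == 0:
        log.warning("no organism with known %s in the selected kingdoms", factor)
    return pd.DataFrame(
        rows,
        columns=["category", "n_total", "n_with_feature", "percent", "ci_low", "ci_high"],
    )


def rank_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Stable descending sort by percent (NaN categories last)."""
    if table.empty:
        raise ValueError("cannot rank an empty factor table")
    return table.sort_values(
        "percent", ascending=False, kind="stable", na_position="last"
    ).reset_index(drop=True)


def describe_extremes(table: pd.DataFrame) -> str:
    """One-line statement of the highest/lowest-proportion categories."""
    ranked = rank_categories(table)
    ranked = ranked[ranked["n_total"] > 0]
    if ranked.empty:
        return "no populated categories"
    top, bottom = ranked.iloc[0], ranked.iloc[-1]
    return (
        f"highest in {top['category']} ({top['percent']:.2f}%), "
        f"lowest in {bottom['category']} ({bottom['percent']:.2f}%)"
    )


def two_proportion_test(
    table: pd.DataFrame, category_a: str, category_b: str
) -> dict[str, float]:
    """Optional extension (not part of the published analysis): two-sided
    chi-square comparison of feature proportions between two categories."""
    rows = table.set_index("category")
    a, b = rows.loc[category_a], rows.loc[category_b]
    contingency = [
        [a["n_with_feature"], a["n_total"] - a["n_with_feature"]],
        [b["n_with_feature"], b["n_total"] - b["n_with_feature"]],
    ]
    stat, pvalue, dof, _ = chi2_contingency(contingency)
    return {"chi2": float(stat), "p_value": float(pvalue), "dof": int(dof)}
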