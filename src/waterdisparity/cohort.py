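"""Cohort assembly: PWSID join, inclusion rules, size classification.

Systems enter the analysis only when present in both the water-quality
and the service-area (attribution) datasets, joined on the public water
system identifier (PWSID). Three exclusion rules are then applied in a
fixed order so the exclusion ledger is deterministic:

1. wholesale — a reported served population of zero marks a system that
   sells finished water to other systems rather than serving customers;
2. population floor — systems serving 500 people or fewer, for which
   tract-based attribution is unreliable;
3. agreement — the tract-assigned population must lie within ±50% of the
   reported population (inclusive bounds).

Every excluded system appears in the ledger with its *first* failing
rule; ledger counts plus the included count always reconcile to the
matched count.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SIZE_CLASSES",
    "classify_size",
    "match_datasets",
    "apply_inclusion",
    "build_cohort",
    "POPULATION_FLOOR",
]

POPULATION_FLOOR = 500

# (class name, inclusive upper bound on reported population)
SIZE_CLASSES = [
    ("very_small", 500),
    ("small", 3300),
    ("medium", 10_000),
    ("large", 100_000),
    ("very_large", float("inf")),
]


def classify_size(reported_population: float) -> str:
    """US regulatory size classes by reported served population.

    very_small ≤500 < small ≤3300 < medium ≤10,000 < large ≤100,000 <
    very_large.
    """
    if reported_population < 0:
        raise ValueError(f"negative reported population: {reported_population}")
    for name, upper in SIZE_CLASSES:
        if reported_population <= upper:
            return name
    raise AssertionError("unreachable")


def match_datasets(
    risk: pd.DataFrame, attribution: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inner join on pwsid; report systems present in only one source.

    Raises on duplicate PWSIDs within either source (they would silently
    multiply rows in the join).
    """
    for name, df in (("risk", risk), ("attribution", attribution)):
        dup = df["pwsid"][df["pwsid"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate pwsid in {name} data: {dup.iloc[0]}")
    merged = risk.merge(attribution, on="pwsid", how="inner")
    counts = {
        "matched": len(merged),
        "risk_only": int((~risk["pwsid"].isin(attribution["pwsid"])).sum()),
        "gis_only": int((~attribution["pwsid"].isin(risk["pwsid"])).sum()),
    }
    return merged, counts


def apply_inclusion(
    profiles: pd.DataFrame, population_floor: int = POPULATION_FLOOR
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the ordered exclusion rules; return (cohort, exclusion ledger).

    ``profiles`` needs columns ``pwsid, reported_population,
    agreement_pass``. The returned cohort carries flag columns
    (non_wholesale, pop_gt_floor, agreement_pass, included) and
    ``size_class``; the ledger has one row per excluded system with its
    first failing rule. Idempotent: re-applying to the included cohort
    excludes nothing.
    """
    df = profiles.copy()
    df["non_wholesale"] = df["reported_population"] > 0
    df["pop_gt_floor"] = df["reported_population"] > population_floor
    df["agreement_pass"] = df["agreement_pass"].fillna(False).astype(bool)
    df["size_class"] = df["reported_population"].map(classify_size)
    df["included"] = df["non_wholesale"] & df["pop_gt_floor"] & df["agreement_pass"]

    rules = [
        ("wholesale", ~df["non_wholesale"]),
        ("population_floor", ~df["pop_gt_floor"]),
        ("agreement", ~df["agreement_pass"]),
    ]
    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    for name, failing in rules:
        reason = reason.where(~(reason.isna() & failing), name)
    ledger = (
        df.loc[~df["included"], ["pwsid"]]
        .assign(rule=reason[~df["included"]])
        .reset_index(drop=True)
    )
    cohort = df[df["included"]].reset_index(drop=True)
    assert len(cohort) + len(ledger) == len(df)  # no system lost silently
    return cohort, ledger


def build_cohort(
    risk: pd.DataFrame,
    attribution: pd.DataFrame,
    population_floor: int = POPULATION_FLOOR,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """match → classify → filter; returns (cohort, exclusions, match counts)."""
    merged, counts = match_datasets(risk, attribution)
    cohort, ledger = apply_inclusion(merged, population_floor)
    counts = {**counts, "excluded": len(ledger), "included": len(cohort)}
    return cohort, ledger, counts
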