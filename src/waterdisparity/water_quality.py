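"""Per-system concentration means and the cumulative cancer-risk statistic.

The quality metric is a hazard-style sum over carcinogenic contaminants,

    rho = Σ_i C_i / B_i ,

where C_i is a community water system's long-term arithmetic-mean
concentration of contaminant i over the study window (non-detects counted
as zero) and B_i is the concentration corresponding to 10⁻⁶ lifetime
cancer risk. rho is therefore dimensionless and expressed in units of
10⁻⁶ lifetime risk; the lifetime risk itself is rho × 10⁻⁶.

Two substantive rules are implemented here:

* **Non-detects are zeros.** A result below the reporting limit enters the
  arithmetic mean as 0, pulling long-term averages toward zero rather
  than dropping the sample.
* **HAA9 supersedes HAA5.** The nine-haloacetic-acid group contains the
  regulated five, so when a system has both group means, only HAA9
  contributes to the risk sum; double-counting the shared species would
  inflate rho.

A contaminant with no samples in the window is *absent* from the system's
profile, never imputed as zero: absence of testing is not evidence of
absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmarks import BenchmarkTable
from .units import convert

__all__ = [
    "ConcentrationProfile",
    "RiskResult",
    "mean_concentration",
    "build_profiles",
    "resolve_haa",
    "cumulative_risk",
    "risk_table",
    "occurrence_summary",
    "DEFAULT_WINDOW",
]

log = logging.getLogger(__name__)

#: Default study window (inclusive on both ends).
DEFAULT_WINDOW = (pd.Timestamp("2014-01-01"), pd.Timestamp("2019-12-31"))

TEST_COLUMNS = ["pwsid", "contaminant_id", "sample_date", "value", "unit", "nondetect"]


@dataclass
class ConcentrationProfile:
    """One system's long-term mean concentrations, in benchmark units."""

    pwsid: str
    concentrations: dict[str, float]  # contaminant_id -> C_i
    n_tests: dict[str, int] = field(default_factory=dict)
    detected: dict[str, bool] = field(default_factory=dict)
    #: ids excluded from the risk sum by a group-supersession rule
    superseded: set[str] = field(default_factory=set)
    haa_rule: str | None = None

    @property
    def risk_eligible(self) -> dict[str, float]:
        return {k: v for k, v in self.concentrations.items() if k not in self.superseded}


@dataclass
class RiskResult:
    """Cumulative cancer risk for one system.

    ``rho`` is in units of 10⁻⁶ lifetime risk; ``lifetime_risk`` is the
    probability itself (rho × 10⁻⁶). ``contributions`` holds the per-
    contaminant hazard quotients C_i/B_i, which sum to rho.
    """

    pwsid: str
    rho: float
    contributions: dict[str, float]
    skipped: list[str] = field(default_factory=list)  # no benchmark available

    @property
    def lifetime_risk(self) -> float:
        return self.rho * 1e-6

    @property
    def n_contaminants(self) -> int:
        return len(self.contributions)


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    values = pd.to_numeric(df["value"], errors="coerce")
    nd = df["nondetect"].astype(bool)
    has_value = values.notna()
    bad = has_value == nd  # value present XOR nondetect must hold
    if bad.any():
        i = df.index[bad][0]
        raise ValueError(
            f"record {i}: value must be present exactly when nondetect is 0 "
            f"(value={df.loc[i, 'value']!r}, nondetect={df.loc[i, 'nondetect']!r})"
        )
    if (values < 0).any():
        i = df.index[values < 0][0]
        raise ValueError(f"record {i}: negative concentration {values[i]}")
    out = df.copy()
    out["value"] = values
    out["nondetect"] = nd
    out["sample_date"] = pd.to_datetime(out["sample_date"])
    return out


def mean_concentration(
    records: pd.DataFrame,
    target_unit: str,
    window: tuple[pd.Timestamp, pd.Timestamp] = DEFAULT_WINDOW,
) -> tuple[float, int, bool] | None:
    """Arithmetic-mean concentration for one system+contaminant.

    All in-window results are averaged with non-detects counted as zero,
    after conversion to ``target_unit`` (the benchmark's unit). Returns
    ``(mean, n_tests, detected)``, or ``None`` when no record falls in the
    window — the contaminant is then absent from the profile, not zero.
    """
    df = _validate_records(records)
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    df = df[(df["sample_date"] >= lo) & (df["sample_date"] <= hi)]
    if df.empty:
        return None
    vals = np.array(
        [
            0.0 if nd else convert(v, u, target_unit)
            for v, u, nd in zip(df["value"], df["unit"], df["nondetect"])
        ]
    )
    return float(vals.mean()), len(vals), bool((vals > 0).any())


def build_profiles(
    tests: pd.DataFrame,
    benchmarks: BenchmarkTable,
    window: tuple[pd.Timestamp, pd.Timestamp] = DEFAULT_WINDOW,
) -> list[ConcentrationProfile]:
    """Aggregate raw monitoring records into per-system profiles.

    Contaminant ids are passed through the benchmark table's alias map
    first (so, e.g., combined nitrate+nitrite results feed the nitrate
    stream). Contaminants without a benchmark entry are retained in the
    profile in their reported unit and skipped later, with a log line, by
    :func:`cumulative_risk`.
    """
    df = _validate_records(tests[TEST_COLUMNS])
    df = df.assign(contaminant_id=df["contaminant_id"].map(benchmarks.resolve_alias))
    profiles = []
    for pwsid, sys_df in df.groupby("pwsid", sort=True):
        prof = ConcentrationProfile(pwsid=str(pwsid), concentrations={})
        for cid, cdf in sys_df.groupby("contaminant_id", sort=True):
            unit = benchmarks[cid].unit if cid in benchmarks else cdf["unit"].iloc[0]
            res = mean_concentration(cdf, unit, window)
            if res is None:
                continue
            prof.concentrations[cid], prof.n_tests[cid], prof.detected[cid] = res
        if prof.concentrations:
            profiles.append(prof)
    return profiles


def resolve_haa(
    profile: ConcentrationProfile, benchmarks: BenchmarkTable
) -> ConcentrationProfile:
    """Apply group-supersession rules (HAA9 over HAA5) to one profile.

    When both the superseding and superseded group means are present, the
    superseded one is flagged ineligible for the risk sum (it stays in the
    profile for occurrence reporting). The profile records which rule
    fired.
    """
    for winner, loser in benchmarks.supersedes.items():
        if winner in profile.concentrations and loser in profile.concentrations:
            profile.superseded.add(loser)
            profile.haa_rule = f"{winner} supersedes {loser}"
        elif loser in profile.concentrations:
            profile.haa_rule = f"{loser} only"
    return profile


def cumulative_risk(
    profile: ConcentrationProfile, benchmarks: BenchmarkTable
) -> RiskResult:
    """Hazard sum rho = Σ C_i/B_i over the risk-eligible contaminants.

    Assumes :func:`resolve_haa` has been applied. Contaminants lacking a
    benchmark are skipped and logged — never silently treated as zero
    risk.
    """
    contributions: dict[str, float] = {}
    skipped: list[str] = []
    for cid, conc in profile.risk_eligible.items():
        if cid not in benchmarks:
            skipped.append(cid)
            log.warning("system %s: no benchmark for %s; skipped from risk sum",
                        profile.pwsid, cid)
            continue
        b = benchmarks[cid].benchmark
        if b <= 0:
            raise ValueError(f"benchmark for {cid} must be positive")
        contributions[cid] = conc / b
    return RiskResult(
        pwsid=profile.pwsid,
        rho=float(sum(contributions.values())),
        contributions=contributions,
        skipped=skipped,
    )


def risk_table(
    tests: pd.DataFrame,
    benchmarks: BenchmarkTable,
    window: tuple[pd.Timestamp, pd.Timestamp] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """End-to-end convenience: records → per-system risk DataFrame."""
    rows = []
    for prof in build_profiles(tests, benchmarks, window):
        res = cumulative_risk(resolve_haa(prof, benchmarks), benchmarks)
        rows.append(
            {
                "pwsid": res.pwsid,
                "rho": res.rho,
                "lifetime_risk": res.lifetime_risk,
                "n_contaminants": res.n_contaminants,
            }
        )
    return pd.DataFrame(rows, columns=["pwsid", "rho", "lifetime_risk", "n_contaminants"])


def occurrence_summary(
    profiles: list[ConcentrationProfile],
    populations: dict[str, float],
) -> pd.DataFrame:
    """Per-contaminant occurrence statistics across systems.

    For each contaminant: number of systems with a detection, total
    population served by those systems, the simple average of C_i over all
    systems *with data*, and the population-weighted average
    Σ(C_i·pop_i)/Σpop_i over systems with data. Systems lacking a
    population figure are excluded from the weighted average (logged).
    """
    rows = []
    by_contaminant: dict[str, list[ConcentrationProfile]] = {}
    for p in profiles:
        for cid in p.concentrations:
            by_contaminant.setdefault(cid, []).append(p)
    for cid in sorted(by_contaminant):
        profs = by_contaminant[cid]
        concs = np.array([p.concentrations[cid] for p in profs])
        detected = np.array([p.detected[cid] for p in profs])
        pops = np.array([populations.get(p.pwsid, np.nan) for p in profs])
        has_pop = ~np.isnan(pops)
        if not has_pop.all():
            log.info("contaminant %s: %d systems lack population; excluded from "
                     "weighted average", cid, int((~has_pop).sum()))
        weighted = (
            float((concs[has_pop] * pops[has_pop]).sum() / pops[has_pop].sum())
            if has_pop.any() and pops[has_pop].sum() > 0
            else np.nan
        )
        rows.append(
            {
                "contaminant_id": cid,
                "n_systems_with_data": len(profs),
                "n_systems_with_detections": int(detected.sum()),
                "population_with_detections": float(pops[detected & has_pop].sum()),
                "simple_average": float(concs.mean()),
                "population_weighted_average": weighted,
            }
        )
    return pd.DataFrame(rows)
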