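"""Tercile disparity analysis with the Jonckheere–Terpstra trend test.

Systems are ordered by a demographic percentage (e.g. percent of the
served population belonging to a census subgroup) and split into three
equal-count terciles T1 < T2 < T3. For each tercile we report the number
of systems, the total reported population, and the median cumulative
cancer risk; a Jonckheere–Terpstra (JT) test then asks whether risk
shifts monotonically across the ordered terciles.

The JT statistic is the sum of pairwise Mann–Whitney counts over ordered
group pairs,

    J = Σ_{k<l} U_kl ,   U_kl = #{x ∈ G_k, y ∈ G_l : x < y} + ½·#{x = y},

with null moments

    E₀[J]   = (n² − Σ n_k²) / 4
    Var₀[J] = tie-corrected form (reduces to
              [n²(2n+3) − Σ n_k²(2n_k+3)] / 72 without ties).

p-values come from the normal approximation, from exact enumeration of
all equally likely assignments of the pooled values to groups (small n),
or from a seeded Monte-Carlo permutation of group labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "JTResult",
    "TercileRow",
    "TercileReport",
    "tercile_split",
    "tercile_summary",
    "jonckheere_terpstra",
    "run_disparity",
    "MIN_STRATUM_SIZE",
]

#: Strata with fewer systems than this get their summary reported but the
#: trend test skipped (three terciles of <2 carry no usable ordering).
MIN_STRATUM_SIZE = 6

EXACT_MAX_N = 10
_ALTERNATIVES = ("increasing", "decreasing", "two-sided")


@dataclass
class JTResult:
    J: float
    mu0: float
    var0: float
    z: float
    p: float
    method: str  # asymptotic | exact | permutation
    alternative: str
    group_sizes: tuple[int, ...]


def _pair_count(x: np.ndarray, y: np.ndarray) -> float:
    """U_kl = #{x<y} + ½#{x=y} via sorted rank arithmetic."""
    xs = np.sort(x)
    lt = np.searchsorted(xs, y, side="left")   # per y: #x < y
    le = np.searchsorted(xs, y, side="right")  # per y: #x <= y
    return float(lt.sum() + 0.5 * (le - lt).sum())


def _jt_statistic(groups: list[np.ndarray]) -> float:
    return sum(
        _pair_count(groups[k], groups[l])
        for k in range(len(groups))
        for l in range(k + 1, len(groups))
    )


def _null_moments(pooled: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    n = int(sizes.sum())
    mu0 = (n * n - float((sizes**2).sum())) / 4.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    ni = sizes.astype(float)
    d1 = (
        n * (n - 1) * (2 * n + 5)
        - float((ni * (ni - 1) * (2 * ni + 5)).sum())
        - float((t * (t - 1) * (2 * t + 5)).sum())
    )
    var0 = d1 / 72.0
    if n > 2:
        var0 += (
            float((ni * (ni - 1) * (ni - 2)).sum())
            * float((t * (t - 1) * (t - 2)).sum())
            / (36.0 * n * (n - 1) * (n - 2))
        )
    var0 += (
        float((ni * (ni - 1)).sum())
        * float((t * (t - 1)).sum())
        / (8.0 * n * (n - 1))
    )
    return mu0, max(var0, 0.0)


def _tail_p(stat: float, null_stats: np.ndarray, alternative: str) -> float:
    """Tail probability of ``stat`` under an enumerated/sampled null."""
    tol = 1e-9
    p_ge = float((null_stats >= stat - tol).mean())
    p_le = float((null_stats <= stat + tol).mean())
    if alternative == "increasing":
        return p_ge
    if alternative == "decreasing":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def _exact_null(pooled: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """J over every equally likely assignment of pooled values to groups.

    Enumerates index combinations (choose n₁ of n for G₁, then n₂ of the
    rest, ...): each is equally probable under the null regardless of
    ties among values.
    """
    n = len(pooled)
    stats: list[float] = []

    def recurse(remaining: tuple[int, ...], level: int, chosen: list[np.ndarray]):
        if level == len(sizes):
            stats.append(_jt_statistic(chosen))
            return
        for combo in itertools.combinations(remaining, int(sizes[level])):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, level + 1, chosen + [pooled[list(combo)]])

    recurse(tuple(range(n)), 0, [])
    return np.array(stats)


def jonckheere_terpstra(
    groups: list,
    alternative: str = "two-sided",
    method: str = "auto",
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> JTResult:
    """JT test for a monotone location trend across ordered groups.

    ``groups`` is the ordered list of samples (T1, T2, T3, ...); the
    ordering is part of the hypothesis. ``method`` is ``asymptotic``
    (normal approximation, no continuity correction), ``exact`` (full
    enumeration; total n ≤ 10), ``permutation`` (seeded Monte-Carlo), or
    ``auto`` (exact when n ≤ 10, else asymptotic). With all pooled values
    identical the statistic is degenerate: z = 0 and p = 1.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    if len(groups) < 2:
        raise ValueError("need at least 2 ordered groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    sizes = np.array([len(a) for a in arrays])
    pooled = np.concatenate(arrays)
    n = int(sizes.sum())

    J = _jt_statistic(arrays)
    mu0, var0 = _null_moments(pooled, sizes)

    if method == "auto":
        method = "exact" if n <= EXACT_MAX_N else "asymptotic"
    if method == "exact" and n > EXACT_MAX_N:
        raise ValueError(f"exact enumeration limited to n <= {EXACT_MAX_N}, got {n}")

    if var0 == 0.0:  # all pooled values identical
        return JTResult(J, mu0, var0, 0.0, 1.0, method, alternative, tuple(sizes))

    z = (J - mu0) / math.sqrt(var0)
    if method == "asymptotic":
        if alternative == "increasing":
            p = float(norm.sf(z))
        elif alternative == "decreasing":
            p = float(norm.cdf(z))
        else:
            p = float(min(1.0, 2.0 * min(norm.sf(z), norm.cdf(z))))
    elif method == "exact":
        p = _tail_p(J, _exact_null(pooled, sizes), alternative)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        stats = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(pooled)
            stats[b] = _jt_statistic(
                [perm[offsets[i]: offsets[i + 1]] for i in range(len(sizes))]
            )
        p = _tail_p(J, stats, alternative)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return JTResult(J, mu0, var0, z, p, method, alternative, tuple(sizes))


def tercile_split(
    values, ids, n_groups: int = 3
) -> tuple[pd.Series, list[tuple[float, float]]]:
    """Assign T1..T3 labels by ascending value, ties broken by id.

    Group sizes differ by at most one; when n is not divisible by 3 the
    extra systems go to the lowest tercile(s) first. Returns labels
    (indexed like ``ids``) and per-tercile (min, max) value boundaries.
    """
    values = np.asarray(values, dtype=float)
    ids = list(ids)
    n = len(values)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} systems, got {n}")
    order = sorted(range(n), key=lambda i: (values[i], ids[i]))
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    labels = np.empty(n, dtype=object)
    boundaries = []
    start = 0
    for g, size in enumerate(sizes):
        members = order[start: start + size]
        for i in members:
            labels[i] = f"T{g + 1}"
        boundaries.append((float(values[members[0]]), float(values[members[-1]])))
        start += size
    return pd.Series(labels, index=ids, name="tercile"), boundaries


@dataclass
class TercileRow:
    label: str
    n: int
    pct_min: float
    pct_max: float
    total_population: float
    median_risk: float


@dataclass
class TercileReport:
    subgroup: str
    size_class: str | None  # None = all sizes pooled
    terciles: list[TercileRow]
    jt: JTResult | None
    jt_skip_reason: str | None = None
    sidedness: str = "two-sided"
    extra: dict = field(default_factory=dict)


def tercile_summary(
    labels: pd.Series, profiles: pd.DataFrame, boundaries
) -> list[TercileRow]:
    """Per-tercile n, total reported population, and median lifetime risk."""
    rows = []
    by_id = profiles.set_index("pwsid")
    for g, (lo, hi) in enumerate(boundaries, start=1):
        members = labels.index[labels == f"T{g}"]
        sub = by_id.loc[members]
        rows.append(
            TercileRow(
                label=f"T{g}",
                n=len(sub),
                pct_min=lo,
                pct_max=hi,
                total_population=float(sub["reported_population"].sum()),
                median_risk=float(sub["lifetime_risk"].median()),
            )
        )
    return rows


def _analyze_stratum(
    profiles: pd.DataFrame,
    subgroup_col: str,
    subgroup: str,
    size_class: str | None,
    alternative: str,
    method: str,
    n_permutations: int,
    seed: int | None,
) -> TercileReport:
    if len(profiles) < MIN_STRATUM_SIZE:
        return TercileReport(
            subgroup=subgroup,
            size_class=size_class,
            terciles=[],
            jt=None,
            jt_skip_reason=f"insufficient n ({len(profiles)} < {MIN_STRATUM_SIZE})",
            sidedness=alternative,
        )
    labels, boundaries = tercile_split(profiles[subgroup_col], profiles["pwsid"])
    terciles = tercile_summary(labels, profiles, boundaries)
    risk_by_id = profiles.set_index("pwsid")["lifetime_risk"]
    groups = [
        risk_by_id.loc[labels.index[labels == f"T{g}"]].to_numpy()
        for g in (1, 2, 3)
    ]
    jt = jonckheere_terpstra(
        groups, alternative=alternative, method=method,
        n_permutations=n_permutations, seed=seed,
    )
    return TercileReport(
        subgroup=subgroup, size_class=size_class, terciles=terciles,
        jt=jt, sidedness=alternative,
    )


def run_disparity(
    cohort: pd.DataFrame,
    subgroups: list[str],
    stratify_by_size: bool = False,
    alternative: str = "two-sided",
    method: str = "auto",
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> list[TercileReport]:
    """Tercile reports per subgroup, optionally per size class.

    ``subgroups`` name percentage columns of the cohort (``pct_*``).
    Terciles and their boundaries are computed *within* each analysis
    stratum. When stratifying, the very_small class is normally absent
    (removed by the population floor); any stratum with fewer than
    :data:`MIN_STRATUM_SIZE` systems is reported with the trend test
    skipped and a reason. The number of trend tests performed is up to
    the caller to account for in any multiplicity adjustment; none is
    applied here.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    reports = []
    for sub_col in subgroups:
        name = sub_col.removeprefix("pct_")
        reports.append(
            _analyze_stratum(cohort, sub_col, name, None, alternative, method,
                             n_permutations, seed)
        )
        if stratify_by_size:
            for size_class in ("small", "medium", "large", "very_large"):
                stratum = cohort[cohort["size_class"] == size_class]
                if stratum.empty:
                    continue
                reports.append(
                    _analyze_stratum(stratum, sub_col, name, size_class,
                                     alternative, method, n_permutations, seed)
                )
    return reports


def reports_to_frames(reports: list[TercileReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten reports into (terciles, trend_tests) DataFrames."""
    trows, jrows = [], []
    for r in reports:
        stratum = r.size_class or "all"
        for t in r.terciles:
            trows.append(
                {
                    "subgroup": r.subgroup, "size_class": stratum,
                    "tercile": t.label, "n_systems": t.n,
                    "pct_min": t.pct_min, "pct_max": t.pct_max,
                    "total_population": t.total_population,
                    "median_lifetime_risk": t.median_risk,
                }
            )
        jrows.append(
            {
                "subgroup": r.subgroup, "size_class": stratum,
                "J": r.jt.J if r.jt else float("nan"),
                "z": r.jt.z if r.jt else float("nan"),
                "p_value": r.jt.p if r.jt else float("nan"),
                "method": r.jt.method if r.jt else "",
                "sidedness": r.sidedness,
                "skip_reason": r.jt_skip_reason or "",
            }
        )
    tcols = ["subgroup", "size_class", "tercile", "n_systems", "pct_min",
             "pct_max", "total_population", "median_lifetime_risk"]
    jcols = ["subgroup", "size_class", "J", "z", "p_value", "method",
             "sidedness", "skip_reason"]
    return pd.DataFrame(trows, columns=tcols), pd.DataFrame(jrows, columns=jcols)
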