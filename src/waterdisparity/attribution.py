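"""Areal interpolation of census-tract demographics onto service areas.

A community water system's service polygon rarely aligns with census
geography. Under the standard uniform-density assumption — population
spread evenly within each tract — tract attributes are apportioned to a
system in proportion to the fraction of the *tract's* area the system
covers:

    assigned count = Σ_t  frac_t × count_t ,   frac_t = area(tract ∩ system) / area(tract)

Counts (population, subgroup populations) are apportioned and summed, and
subgroup percentages derived from the apportioned counts; this is the
only mode that conserves total population when systems tile the grid. A
literal percent mode — an area-fraction-weighted average of the tracts'
own percentages — is available for sensitivity analysis.

Geometries must arrive valid and in a shared planar equal-area coordinate
system; the module validates but never reprojects or repairs (silent
repair changes areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

__all__ = [
    "TractRecord",
    "ServiceArea",
    "AttributionResult",
    "overlap_fractions",
    "assign_demographics",
    "population_agreement",
    "attribute_all",
    "SLIVER_EPS",
]

#: Overlap fractions below this (relative to tract area) are sliver noise.
SLIVER_EPS = 1e-9


@dataclass
class TractRecord:
    tract_id: str
    polygon: BaseGeometry
    population: float
    subgroup_counts: dict[str, float]

    def validate(self) -> None:
        _check_geometry(self.polygon, f"tract {self.tract_id}")
        for name, cnt in self.subgroup_counts.items():
            if not 0 <= cnt <= self.population:
                raise ValueError(
                    f"tract {self.tract_id}: subgroup {name} count {cnt} outside "
                    f"[0, population={self.population}]"
                )


@dataclass
class ServiceArea:
    pwsid: str
    polygon: BaseGeometry
    reported_population: float  # the regulator-reported served population

    def validate(self) -> None:
        _check_geometry(self.polygon, f"system {self.pwsid}")
        if self.reported_population < 0:
            raise ValueError(f"system {self.pwsid}: negative reported population")


@dataclass
class AttributionResult:
    pwsid: str
    tract_overlaps: list[tuple[str, float]]
    assigned_population: float
    subgroup_percentages: dict[str, float]
    n_tracts: int
    no_population: bool = False
    agreement_ratio: float | None = None
    agreement_pass: bool | None = None
    subgroup_counts: dict[str, float] = field(default_factory=dict)


def _check_geometry(geom: BaseGeometry, label: str) -> None:
    if geom is None or geom.is_empty:
        raise ValueError(f"{label}: empty geometry")
    if not geom.is_valid:
        raise ValueError(f"{label}: invalid geometry (not auto-repaired)")


def overlap_fractions(
    system: ServiceArea,
    tracts: list[TractRecord],
    eps: float = SLIVER_EPS,
    tree: STRtree | None = None,
) -> list[tuple[str, float]]:
    """Fraction of each tract's area covered by the system polygon.

    Tracts whose fraction falls below ``eps`` are omitted as
    floating-point slivers. Fractions are clipped to 1 to absorb area
    round-off on exact covers.
    """
    system.validate()
    if tree is None:
        candidates = range(len(tracts))
    else:
        candidates = sorted(tree.query(system.polygon))
    out = []
    for i in candidates:
        tract = tracts[i]
        tract.validate()
        inter = system.polygon.intersection(tract.polygon)
        if inter.is_empty:
            continue
        frac = inter.area / tract.polygon.area
        if frac < eps:
            continue
        out.append((tract.tract_id, min(frac, 1.0)))
    return out


def assign_demographics(
    system: ServiceArea,
    tracts: list[TractRecord],
    overlaps: list[tuple[str, float]] | None = None,
    mode: str = "counts",
    tree: STRtree | None = None,
) -> AttributionResult:
    """Apportion tract population and subgroup counts to one system.

    ``mode="counts"`` (default) apportions counts then derives percent;
    ``mode="percent"`` takes the area-fraction-weighted average of the
    tracts' own percentages. A system overlapping no populated tract is
    flagged ``no_population`` (percentages undefined) and excluded
    downstream.
    """
    if mode not in ("counts", "percent"):
        raise ValueError(f"unknown attribution mode: {mode!r}")
    if overlaps is None:
        overlaps = overlap_fractions(system, tracts, tree=tree)
    by_id = {t.tract_id: t for t in tracts}
    subgroups: set[str] = set()
    for t in tracts:
        subgroups.update(t.subgroup_counts)

    assigned_pop = 0.0
    counts = {s: 0.0 for s in sorted(subgroups)}
    pct_num = {s: 0.0 for s in sorted(subgroups)}
    frac_sum = 0.0
    for tract_id, frac in overlaps:
        t = by_id[tract_id]
        assigned_pop += frac * t.population
        frac_sum += frac
        for s in counts:
            c = t.subgroup_counts.get(s, 0.0)
            counts[s] += frac * c
            if t.population > 0:
                pct_num[s] += frac * (100.0 * c / t.population)

    if assigned_pop <= 0:
        return AttributionResult(
            pwsid=system.pwsid,
            tract_overlaps=overlaps,
            assigned_population=assigned_pop,
            subgroup_percentages={},
            n_tracts=len(overlaps),
            no_population=True,
        )
    if mode == "counts":
        pct = {s: 100.0 * counts[s] / assigned_pop for s in counts}
    else:
        pct = {s: pct_num[s] / frac_sum for s in counts}
    return AttributionResult(
        pwsid=system.pwsid,
        tract_overlaps=overlaps,
        assigned_population=assigned_pop,
        subgroup_percentages=pct,
        n_tracts=len(overlaps),
        subgroup_counts=counts,
    )


def population_agreement(
    result: AttributionResult, system: ServiceArea
) -> tuple[float, bool]:
    """Tract-assigned vs regulator-reported population agreement.

    Returns ``(ratio, pass)`` with ratio = assigned/reported; the check
    passes when the assigned figure is within ±50% of the reported one,
    bounds inclusive (0.5 ≤ ratio ≤ 1.5). Systems with a reported
    population of zero are wholesale systems handled upstream, not here.
    """
    if system.reported_population <= 0:
        raise ValueError(
            f"system {system.pwsid}: agreement undefined for reported population 0 "
            "(wholesale exclusion happens upstream)"
        )
    ratio = result.assigned_population / system.reported_population
    return ratio, 0.5 <= ratio <= 1.5


def attribute_all(
    systems: list[ServiceArea],
    tracts: list[TractRecord],
    mode: str = "counts",
    eps: float = SLIVER_EPS,
) -> pd.DataFrame:
    """Attribution table for all systems (one row per system).

    Columns: pwsid, reported_population, assigned_population, n_tracts,
    pct_<subgroup>..., agreement_ratio, agreement_pass, no_population.
    Agreement fields are NaN for wholesale systems (reported population
    zero) and no-population systems.
    """
    tree = STRtree([t.polygon for t in tracts])
    subgroups = sorted({s for t in tracts for s in t.subgroup_counts})
    rows = []
    for system in sorted(systems, key=lambda s: s.pwsid):
        overlaps = overlap_fractions(system, tracts, eps=eps, tree=tree)
        res = assign_demographics(system, tracts, overlaps, mode=mode)
        row = {
            "pwsid": system.pwsid,
            "reported_population": system.reported_population,
            "assigned_population": res.assigned_population,
            "n_tracts": res.n_tracts,
            "no_population": res.no_population,
        }
        for s in subgroups:
            row[f"pct_{s}"] = res.subgroup_percentages.get(s, float("nan"))
        if system.reported_population > 0 and not res.no_population:
            ratio, ok = population_agreement(res, system)
            row["agreement_ratio"], row["agreement_pass"] = ratio, ok
        else:
            row["agreement_ratio"], row["agreement_pass"] = float("nan"), False
        rows.append(row)
    cols = (
        ["pwsid", "reported_population", "assigned_population", "n_tracts", "no_population"]
        + [f"pct_{s}" for s in subgroups]
        + ["agreement_ratio", "agreement_pass"]
    )
    return pd.DataFrame(rows, columns=cols)
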