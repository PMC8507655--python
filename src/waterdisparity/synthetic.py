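"""Synthetic study universe: tract grids, service areas, monitoring data.

Real analyses of drinking-water disparity join three data sources that
cannot be shipped with a package: state monitoring portals, regulator
GIS layers of service boundaries, and census demographic estimates. This
module generates structurally faithful stand-ins:

* a rectangular grid of square census tracts, each with a total
  population and a demographic subgroup count whose fraction is drawn
  from a Beta distribution;
* service areas built from contiguous runs of whole and/or half tract
  cells, so tract↔system overlap fractions include values strictly
  between 0 and 1, plus a noisy "regulator-reported" served population;
* monitoring records with lognormal concentrations — non-negative and
  right-skewed, the standard shape for environmental concentrations —
  left-censored at a per-contaminant detection limit to produce
  non-detects.

The demographic→contamination link is a single log-scale shift: a
system whose service area has subgroup fraction ``f`` draws contaminant
concentrations from LogNormal(μ + β·f, σ). β = 0 gives the null (no
association); β > 0 makes expected log concentration increase
monotonically with subgroup share, which is what the downstream trend
test should detect.

Everything is deterministic under a fixed seed; the three generation
stages use independent child streams of the seed so each stage is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box

from .attribution import ServiceArea, TractRecord, assign_demographics
from .benchmarks import BenchmarkTable, Contaminant

__all__ = [
    "SimContaminant",
    "SimulationConfig",
    "generate_tracts",
    "generate_systems",
    "generate_tests",
    "system_subgroup_fractions",
    "simulate_cohort",
    "benchmark_table",
    "DEFAULT_CONTAMINANTS",
]


@dataclass(frozen=True)
class SimContaminant:
    """One simulated contaminant stream.

    ``benchmark`` is the 10⁻⁶-risk concentration in ``unit``; ``log_mean``
    / ``log_sd`` parameterize the baseline LogNormal in the same unit;
    ``detection_limit`` left-censors draws below it into non-detects;
    ``availability`` is the fraction of systems that test for this
    contaminant at all (emulating, e.g., the limited coverage of
    unregulated-contaminant monitoring among smaller systems).
    """

    id: str
    benchmark: float
    unit: str
    log_mean: float
    log_sd: float
    detection_limit: float = 0.0
    availability: float = 1.0


# Illustrative parameter set shaped like common US drinking-water
# carcinogens (disinfection byproducts, arsenic, nitrate, radium).
# Benchmarks are NOT authoritative regulatory values.
DEFAULT_CONTAMINANTS: tuple[SimContaminant, ...] = (
    SimContaminant("THM4", 0.15, "µg/L", np.log(12.0), 0.6, 1.0, 1.0),
    SimContaminant("HAA5", 0.10, "µg/L", np.log(7.0), 0.6, 1.0, 1.0),
    SimContaminant("HAA9", 0.06, "µg/L", np.log(18.0), 0.6, 1.0, 0.3),
    SimContaminant("ARSENIC", 0.004, "µg/L", np.log(0.5), 1.0, 0.2, 1.0),
    SimContaminant("NITRATE", 0.14, "mg/L", np.log(0.8), 0.9, 0.1, 1.0),
    SimContaminant("RADIUM", 0.05, "pCi/L", np.log(0.3), 0.8, 0.1, 0.8),
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_tracts_x: int = 15
    n_tracts_y: int = 12
    tract_side: float = 1000.0  # planar projected units
    n_systems: int = 50
    tracts_per_system_range: tuple[int, int] = (1, 3)
    half_cell_prob: float = 0.5  # chance a system's end cell is halved
    population_range: tuple[int, int] = (1200, 8000)  # typical tract sizes
    subgroup_alpha: float = 2.0
    subgroup_beta: float = 2.0
    subgroup_name: str = "subgroup"
    contaminants: tuple[SimContaminant, ...] = DEFAULT_CONTAMINANTS
    effect_size: float = 1.0  # β: log-mean shift per unit subgroup fraction
    tests_per_system_range: tuple[int, int] = (4, 12)
    population_noise_sd: float = 0.1  # relative reported-vs-true noise
    start_date: str = "2014-01-01"
    end_date: str = "2019-12-31"

    def validate(self) -> None:
        def _range_ok(r):
            return len(r) == 2 and 0 < r[0] <= r[1]

        if self.n_tracts_x <= 0 or self.n_tracts_y <= 0 or self.tract_side <= 0:
            raise ValueError("grid dimensions and tract_side must be positive")
        if self.n_systems <= 0:
            raise ValueError("n_systems must be positive")
        for name in ("tracts_per_system_range", "population_range",
                     "tests_per_system_range"):
            if not _range_ok(getattr(self, name)):
                raise ValueError(f"{name} must be a non-empty positive (lo, hi) pair")
        if self.tracts_per_system_range[1] > self.n_tracts_x:
            raise ValueError("tracts_per_system_range exceeds grid row length")
        if self.subgroup_alpha <= 0 or self.subgroup_beta <= 0:
            raise ValueError("Beta shape parameters must be > 0")
        if not 0 <= self.half_cell_prob <= 1:
            raise ValueError("half_cell_prob must be in [0, 1]")
        if self.population_noise_sd < 0:
            raise ValueError("population_noise_sd must be >= 0")
        for c in self.contaminants:
            if c.log_sd < 0 or c.detection_limit < 0 or c.benchmark <= 0:
                raise ValueError(f"invalid contaminant parameters for {c.id}")
            if not 0 <= c.availability <= 1:
                raise ValueError(f"availability for {c.id} must be in [0, 1]")

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimulationConfig":
        cfg = dict(cfg)
        if "contaminants" in cfg:
            cfg["contaminants"] = tuple(
                SimContaminant(**c) if isinstance(c, dict) else c
                for c in cfg["contaminants"]
            )
        for key in ("tracts_per_system_range", "population_range",
                    "tests_per_system_range"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        out = cls(**cfg)
        out.validate()
        return out

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    )


def generate_tracts(config: SimulationConfig) -> list[TractRecord]:
    """Square tracts tiling an n_x × n_y rectangle, row-major ids."""
    config.validate()
    rng = _stage_rng(config, 0)
    side = config.tract_side
    lo, hi = config.population_range
    tracts = []
    for j in range(config.n_tracts_y):
        for i in range(config.n_tracts_x):
            pop = int(rng.integers(lo, hi + 1))
            frac = rng.beta(config.subgroup_alpha, config.subgroup_beta)
            tracts.append(
                TractRecord(
                    tract_id=f"T{j * config.n_tracts_x + i:05d}",
                    polygon=box(i * side, j * side, (i + 1) * side, (j + 1) * side),
                    population=pop,
                    subgroup_counts={config.subgroup_name: round(pop * frac)},
                )
            )
    return tracts


def generate_systems(
    config: SimulationConfig, tracts: list[TractRecord]
) -> list[ServiceArea]:
    """Service areas as contiguous row-wise runs of tract cells.

    Each system occupies ``k`` consecutive cells within one grid row
    (k drawn from ``tracts_per_system_range``); with probability
    ``half_cell_prob`` one end cell is halved, so the overlap fraction
    with that tract is exactly 0.5. Systems never overlap each other.
    The reported population is the true covered population perturbed by
    multiplicative Gaussian noise, rounded and floored at zero.
    """
    config.validate()
    rng = _stage_rng(config, 1)
    side = config.tract_side
    nx, ny = config.n_tracts_x, config.n_tracts_y
    lo, hi = config.tracts_per_system_range

    systems = []
    row, cursor = 0, 0
    for s in range(config.n_systems):
        k = int(rng.integers(lo, hi + 1))
        if cursor + k > nx:  # run does not fit; skip to next row
            row, cursor = row + 1, 0
        if row >= ny:
            raise ValueError(
                f"grid of {nx}x{ny} tracts cannot host {config.n_systems} systems "
                f"with up to {hi} tracts each without duplicating blocks"
            )
        x0, x1 = cursor, cursor + k  # cells [x0, x1)
        cursor += k
        trim_left = trim_right = 0.0
        if rng.random() < config.half_cell_prob:
            if rng.random() < 0.5:
                trim_left = side / 2  # keep inner (right) half of first cell
            else:
                trim_right = side / 2  # keep inner (left) half of last cell
        poly = box(
            x0 * side + trim_left,
            row * side,
            x1 * side - trim_right,
            (row + 1) * side,
        )
        true_pop = 0.0
        for x in range(x0, x1):
            frac = 1.0
            if x == x0 and trim_left > 0:
                frac -= 0.5
            if x == x1 - 1 and trim_right > 0:
                frac -= 0.5
            true_pop += frac * tracts[row * nx + x].population
        noise = rng.normal(0.0, config.population_noise_sd) if config.population_noise_sd > 0 else 0.0
        reported = max(0, round(true_pop * (1.0 + noise)))
        systems.append(
            ServiceArea(pwsid=f"SY{s:07d}", polygon=poly, reported_population=reported)
        )
    return systems


def system_subgroup_fractions(
    systems: list[ServiceArea],
    tracts: list[TractRecord],
    subgroup: str,
) -> dict[str, float]:
    """True subgroup fraction per system by exact areal attribution."""
    out = {}
    for system in systems:
        res = assign_demographics(system, tracts, mode="counts")
        if res.no_population:
            out[system.pwsid] = float("nan")
        else:
            out[system.pwsid] = res.subgroup_percentages[subgroup] / 100.0
    return out


def generate_tests(
    config: SimulationConfig,
    systems: list[ServiceArea],
    tracts: list[TractRecord],
) -> pd.DataFrame:
    """Monitoring records for every system×contaminant stream.

    For each system with subgroup fraction ``f`` and each available
    contaminant, draws k ~ Uniform(tests_per_system_range) concentrations
    from LogNormal(μ + β·f, σ); draws below the detection limit become
    non-detect rows (empty value, flag set). Sample dates are uniform
    over the study window.
    """
    config.validate()
    rng = _stage_rng(config, 2)
    fractions = system_subgroup_fractions(systems, tracts, config.subgroup_name)
    start = pd.Timestamp(config.start_date)
    n_days = (pd.Timestamp(config.end_date) - start).days
    lo, hi = config.tests_per_system_range

    rows = []
    for system in systems:
        f = fractions[system.pwsid]
        for c in config.contaminants:
            if c.availability < 1.0 and rng.random() >= c.availability:
                continue
            k = int(rng.integers(lo, hi + 1))
            dates = start + pd.to_timedelta(rng.integers(0, n_days + 1, size=k), "D")
            mu = c.log_mean + config.effect_size * f
            values = np.exp(mu + c.log_sd * rng.standard_normal(k)) if c.log_sd > 0 \
                else np.full(k, np.exp(mu))
            for d, v in zip(dates, values):
                nd = v < c.detection_limit
                rows.append(
                    {
                        "pwsid": system.pwsid,
                        "contaminant_id": c.id,
                        "sample_date": d.strftime("%Y-%m-%d"),
                        "value": np.nan if nd else float(v),
                        "unit": c.unit,
                        "nondetect": int(nd),
                    }
                )
    return pd.DataFrame(
        rows, columns=["pwsid", "contaminant_id", "sample_date", "value", "unit", "nondetect"]
    )


def benchmark_table(config: SimulationConfig) -> BenchmarkTable:
    """Benchmark table matching the simulated contaminant streams."""
    return BenchmarkTable(
        contaminants={
            c.id: Contaminant(id=c.id, benchmark=c.benchmark, unit=c.unit)
            for c in config.contaminants
        }
    )


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Distribution-level cohort draw for statistical calibration.

    Draws each system's subgroup fraction directly from the configured
    Beta distribution and its monitoring results from the same lognormal/
    censoring model as :func:`generate_tests`, then computes the hazard-sum
    risk — skipping polygon construction, which does not change the joint
    law of (subgroup fraction, risk). Used to measure type-I error and
    power of the trend test over many replicate cohorts at speed.

    Returns columns ``pwsid, subgroup_pct, rho, lifetime_risk,
    reported_population``.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed if seed is None else seed,
                               spawn_key=(3,))
    )
    n = config.n_systems
    f = rng.beta(config.subgroup_alpha, config.subgroup_beta, size=n)
    lo, hi = config.tests_per_system_range
    hazard: dict[str, np.ndarray] = {}
    availability: dict[str, np.ndarray] = {}
    for c in config.contaminants:
        avail = rng.random(n) < c.availability if c.availability < 1.0 else np.ones(n, bool)
        k = rng.integers(lo, hi + 1, size=n)
        kmax = int(k.max())
        mu = c.log_mean + config.effect_size * f
        draws = np.exp(mu[:, None] + c.log_sd * rng.standard_normal((n, kmax)))
        draws[draws < c.detection_limit] = 0.0  # non-detects enter the mean as zero
        mask = np.arange(kmax)[None, :] < k[:, None]
        means = (draws * mask).sum(axis=1) / k
        hazard[c.id] = np.where(avail, means / c.benchmark, 0.0)
        availability[c.id] = avail
    # group supersession, as in the full pipeline (HAA9 replaces HAA5)
    table = benchmark_table(config)
    for winner, loser in table.supersedes.items():
        if winner in hazard and loser in hazard:
            hazard[loser] = np.where(availability[winner], 0.0, hazard[loser])
    rho = np.sum(list(hazard.values()), axis=0)
    plo, phi = config.population_range
    t_lo, t_hi = config.tracts_per_system_range
    pop = rng.integers(plo * t_lo, phi * t_hi + 1, size=n)
    return pd.DataFrame(
        {
            "pwsid": [f"SY{i:07d}" for i in range(n)],
            "subgroup_pct": 100.0 * f,
            "rho": rho,
            "lifetime_risk": rho * 1e-6,
            "reported_population": pop,
        }
    )
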