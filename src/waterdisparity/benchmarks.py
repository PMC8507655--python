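"""Cancer-risk benchmark configuration.

Each contaminant carries a benchmark concentration B_i: the level
corresponding to one-in-a-million (10⁻⁶) lifetime cancer risk. The
benchmark table is user-supplied configuration (YAML or a plain dict);
the package ships an illustrative example but hard-codes no values.

Grouped disinfection-byproduct parameters (THM4, HAA5, HAA9) are treated
as single contaminants with group benchmarks. A ``supersedes`` rule
records containment between groups — by default HAA9 (nine haloacetic
acids) supersedes HAA5 (the regulated five it contains), so a system with
both contributes only the HAA9 term to the risk sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .units import canonical_unit

__all__ = ["Contaminant", "BenchmarkTable"]


@dataclass(frozen=True)
class Contaminant:
    id: str
    benchmark: float  # concentration at 10⁻⁶ lifetime risk, in `unit`
    unit: str
    mcl: float | None = None  # context only; not used in the risk statistic
    group: str | None = None  # e.g. "DBP" for disinfection byproducts

    def __post_init__(self) -> None:
        if self.benchmark <= 0:
            raise ValueError(f"benchmark for {self.id} must be > 0, got {self.benchmark}")
        object.__setattr__(self, "unit", canonical_unit(self.unit))


@dataclass
class BenchmarkTable:
    """Per-contaminant benchmarks plus group-supersession rules and aliases.

    ``supersedes`` maps a superseding contaminant id to the id it replaces
    (default: HAA9 → HAA5). ``aliases`` maps reported contaminant ids onto
    the stream they feed (e.g. a combined nitrate+nitrite result recorded
    under the nitrate stream).
    """

    contaminants: dict[str, Contaminant]
    supersedes: dict[str, str] = field(default_factory=lambda: {"HAA9": "HAA5"})
    aliases: dict[str, str] = field(default_factory=dict)

    def __contains__(self, contaminant_id: str) -> bool:
        return contaminant_id in self.contaminants

    def __getitem__(self, contaminant_id: str) -> Contaminant:
        return self.contaminants[contaminant_id]

    def resolve_alias(self, contaminant_id: str) -> str:
        return self.aliases.get(contaminant_id, contaminant_id)

    @classmethod
    def from_dict(cls, cfg: dict) -> "BenchmarkTable":
        contaminants = {}
        for entry in cfg["contaminants"]:
            c = Contaminant(
                id=entry["id"],
                benchmark=float(entry["benchmark"]),
                unit=entry["unit"],
                mcl=entry.get("mcl"),
                group=entry.get("group"),
            )
            if c.id in contaminants:
                raise ValueError(f"duplicate contaminant id in benchmark config: {c.id}")
            contaminants[c.id] = c
        rules = cfg.get("group_rules", {}) or {}
        supersedes = dict(rules.get("supersedes", {}))
        if "haa9_supersedes" in rules:  # shorthand form
            supersedes["HAA9"] = rules["haa9_supersedes"]
        if not supersedes:
            supersedes = {"HAA9": "HAA5"}
        return cls(
            contaminants=contaminants,
            supersedes=supersedes,
            aliases=dict(cfg.get("aliases", {}) or {}),
        )

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
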