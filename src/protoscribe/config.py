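"""Delineation thresholds and the environment vocabulary.

The defaults are the published decision boundaries this tool codifies:
16S rRNA identity of 98.7/94.5/86.5 % for species/genus/family, ANI >95 %
for species, POCP <50 % for genus separation, a 1 percentage-point G+C
window, and the quality gates (16S completeness <80 %, genome completeness
<95 %, contamination >3 %).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

# The 19 amplicon-survey environments used for habitat preference.
ENVIRONMENTS: tuple[str, ...] = (
    "activated sludge",
    "bovine gut",
    "chicken gut",
    "coral",
    "freshwater",
    "human gut",
    "human lung",
    "human oral",
    "human skin",
    "human vagina",
    "insect gut",
    "marine",
    "marine sediment",
    "mouse gut",
    "pig gut",
    "plant",
    "rhizosphere",
    "soil",
    "wastewater",
)


class ConfigError(ValueError):
    pass


@dataclass
class ThresholdConfig:
    s16_species: float = 98.7       # % identity, same species above this
    s16_genus: float = 94.5         # % identity, same genus above this
    s16_family: float = 86.5        # % identity, same family above this
    ani_species: float = 95.0       # % ANI, same species above this
    pocp_genus: float = 50.0        # % POCP, different genus strictly below this
    gc_species_delta: float = 1.0   # percentage points, advisory
    candidate_identity_min: float = 60.0
    candidate_coverage_min: float = 80.0
    candidate_cap: int = 50
    s16_completeness_min: float = 80.0
    genome_completeness_min: float = 95.0
    contamination_max: float = 3.0
    otu_identity_min: float = 97.0
    otu_coverage_min: float = 80.0
    mash_distance_max: float = 0.05

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "candidate_cap":
                if v < 1:
                    raise ConfigError("candidate_cap must be >= 1")
            elif f.name == "mash_distance_max":
                if not 0.0 <= v <= 1.0:
                    raise ConfigError("mash_distance_max must be in [0, 1]")
            elif not 0.0 <= v <= 100.0:
                raise ConfigError(f"{f.name} must be a percentage in [0, 100]")
        if not self.s16_species > self.s16_genus > self.s16_family:
            raise ConfigError(
                "16S thresholds must be ordered species > genus > family"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "ThresholdConfig":
        """Load overrides from a key=value text file ('#' comments allowed)."""
        known = {f.name: f for f in fields(cls)}
        overrides: dict[str, float | int] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                caster = int if key == "candidate_cap" else float
                try:
                    overrides[key] = caster(value.strip())
                except ValueError as exc:
                    raise ConfigError(f"{path}:{lineno}: bad value for {key}") from exc
        return cls(**overrides)
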