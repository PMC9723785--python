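"""Habitat preference from OTU hit tables and MAG sketch matches.

A query's 16S gene is searched against per-environment amplicon OTU
collections upstream; this module consumes the hit table (sample,
environment, OTU, identity, coverage, relative abundance), applies the
identity/coverage qualification (defaults 97 % / 80 %, inclusive), and
computes per-environment prevalence, mean relative abundance in positive
samples, and the habitat score = prevalence x mean relative abundance —
the quantity that later picks the naming environment.  MAG matches are
genome sketch distances filtered at d < 0.05 (strict, as the distance
threshold is an upper bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import ENVIRONMENTS, ThresholdConfig

OTU_COLUMNS = (
    "sample_id",
    "environment",
    "otu_id",
    "identity",
    "coverage",
    "relative_abundance",
)


class EcologyError(ValueError):
    pass


@dataclass
class EnvironmentStats:
    environment: str
    n_samples: int
    n_positive: int
    prevalence: float                 # %
    mean_relabund_positive: float     # %, 0 when no positive samples
    habitat_score: float              # prevalence * mean_relabund_positive


@dataclass
class OccurrenceStats:
    per_environment: dict[str, EnvironmentStats]

    def top_environments(self, n: int = 3) -> list[EnvironmentStats]:
        ranked = sorted(
            self.per_environment.values(),
            key=lambda s: (-s.habitat_score, -s.prevalence, s.environment),
        )
        return ranked[:n]


def read_otu_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(OTU_COLUMNS) - set(df.columns)
    if missing:
        raise EcologyError(f"OTU table missing columns: {sorted(missing)}")
    bad = df[(df["relative_abundance"] < 0) | (df["relative_abundance"] > 1)]
    if len(bad):
        raise EcologyError("relative_abundance must be a fraction in [0, 1]")
    unknown = set(df["environment"].unique()) - set(ENVIRONMENTS)
    if unknown:
        raise EcologyError(f"unknown environment labels: {sorted(unknown)}")
    return df


def qualify_hits(table: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    """Keep rows meeting the identity and coverage floors (inclusive)."""
    missing = set(OTU_COLUMNS) - set(table.columns)
    if missing:
        raise EcologyError(f"OTU table missing columns: {sorted(missing)}")
    mask = (table["identity"] >= cfg.otu_identity_min) & (
        table["coverage"] >= cfg.otu_coverage_min
    )
    return table[mask].reset_index(drop=True)


def occurrence(
    table: pd.DataFrame, samples_per_env: Mapping[str, int]
) -> OccurrenceStats:
    """Per-environment occurrence statistics over a qualified hit table.

    A sample's relative abundance is the sum over its qualifying hits, so
    splitting one hit across several OTU rows does not change the result.
    Environments with no positive samples report prevalence 0 and mean 0.
    """
    unknown = set(table["environment"].unique()) - set(samples_per_env)
    if unknown:
        raise EcologyError(
            f"environments missing from samples_per_env: {sorted(unknown)}"
        )
    stats: dict[str, EnvironmentStats] = {}
    grouped = (
        table.groupby(["environment", "sample_id"])["relative_abundance"]
        .sum()
        .reset_index()
        if len(table)
        else pd.DataFrame(columns=["environment", "sample_id", "relative_abundance"])
    )
    for env, n_samples in samples_per_env.items():
        if n_samples < 1:
            raise EcologyError(f"environment {env!r}: n_samples must be >= 1")
        env_rows = grouped[grouped["environment"] == env]
        n_positive = int(len(env_rows))
        if n_positive > n_samples:
            raise EcologyError(
                f"environment {env!r}: {n_positive} positive samples exceed "
                f"configured total {n_samples}"
            )
        prevalence = 100.0 * n_positive / n_samples
        mean_ra = (
            100.0 * float(env_rows["relative_abundance"].mean()) if n_positive else 0.0
        )
        stats[env] = EnvironmentStats(
            environment=env,
            n_samples=n_samples,
            n_positive=n_positive,
            prevalence=prevalence,
            mean_relabund_positive=mean_ra,
            habitat_score=prevalence * mean_ra,
        )
    return OccurrenceStats(per_environment=stats)


def read_mag_distances(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"mag_id", "environment", "distance"} - set(df.columns)
    if missing:
        raise EcologyError(f"MAG distance table missing columns: {sorted(missing)}")
    if (df["distance"] < 0).any():
        raise EcologyError("MAG distances must be non-negative")
    return df


def mag_matches(
    distances: pd.DataFrame, cfg: ThresholdConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter MAG sketch distances at d < threshold (strict) and group counts."""
    if (distances["distance"] < 0).any():
        raise EcologyError("MAG distances must be non-negative")
    kept = distances[distances["distance"] < cfg.mash_distance_max].reset_index(
        drop=True
    )
    counts = kept.groupby("environment")["mag_id"].count().to_dict()
    return kept, {str(k): int(v) for k, v in counts.items()}
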