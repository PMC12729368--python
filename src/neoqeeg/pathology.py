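"""Neuropathology scoring: ordinal neocortical injury scores and percent
damaged neurons.

Neocortical regions are examined in 40 non-overlapping visual fields whose
injury pattern is graded none < scattered < grouped/laminar < panlaminar.
A region's 0-9 score combines the worst severity observed with how many
fields show it: score = 3*(s-1) + t for worst severity rank s in {1,2,3}
and frequency tertile t in {1,2,3} of the field count at that severity
(0 when all fields are intact). The mapping is monotone in both worst
severity and its frequency and is replaceable by a user-supplied lookup.
Subcortical and hippocampal regions are summarized as the percentage of
damaged neurons out of the total counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import NEOCORTEX_REGIONS, SEVERITY_LEVELS

SEVERITY_RANK = {name: rank for rank, name in enumerate(SEVERITY_LEVELS)}


@dataclass(frozen=True)
class RegionScore:
    region: str
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 9:
            raise ValueError(f"score {self.score} outside 0-9")


@dataclass(frozen=True)
class NeuronCounts:
    """Damaged/total neuron counts with the derived percentage."""

    region: str
    damaged: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"total neuron count must be positive in {self.region}")
        if not 0 <= self.damaged <= self.total:
            raise ValueError(f"damaged count {self.damaged} outside [0, {self.total}]")

    @property
    def percent_damaged(self) -> float:
        return 100.0 * self.damaged / self.total


def severity_tertile_score(worst_rank: int, count_at_worst: int, n_fields: int) -> int:
    """The default severity-by-frequency mapping onto 0-9."""
    if worst_rank == 0:
        return 0
    thirds = n_fields / 3.0
    if count_at_worst <= thirds:
        tertile = 1
    elif count_at_worst <= 2 * thirds:
        tertile = 2
    else:
        tertile = 3
    return 3 * (worst_rank - 1) + tertile


def score_region(
    severities: Sequence[str | int],
    region: str = "",
    n_fields: int = 40,
    mapping: Callable[[int, int, int], int] = severity_tertile_score,
) -> RegionScore:
    """Score one neocortical region from its per-field severities.

    Expects exactly ``n_fields`` observations, each a severity name or rank.
    Permutation-invariant and monotone: upgrading any field's severity never
    lowers the score.
    """
    ranks = []
    for s in severities:
        if isinstance(s, str):
            if s not in SEVERITY_RANK:
                raise ValueError(f"unknown severity {s!r}; expected one of {SEVERITY_LEVELS}")
            ranks.append(SEVERITY_RANK[s])
        else:
            if not 0 <= int(s) < len(SEVERITY_LEVELS):
                raise ValueError(f"severity rank {s} outside 0-{len(SEVERITY_LEVELS) - 1}")
            ranks.append(int(s))
    if len(ranks) != n_fields:
        raise ValueError(f"region {region or '?'}: expected {n_fields} fields, got {len(ranks)}")
    worst = max(ranks)
    count = sum(r == worst for r in ranks)
    return RegionScore(region=region, score=mapping(worst, count, n_fields))


def sum_cortical_scores(
    scores: dict[str, int | RegionScore],
    regions: Iterable[str] = NEOCORTEX_REGIONS,
) -> int:
    """Sum the per-region scores over the configured cortical regions."""
    regions = tuple(regions)
    missing = [r for r in regions if r not in scores]
    if missing:
        raise KeyError(f"missing cortical region scores: {', '.join(missing)}")
    return int(
        sum(s.score if isinstance(s, RegionScore) else int(s) for r, s in scores.items() if r in regions)
    )


def percent_damaged(region: str, damaged: int, total: int) -> NeuronCounts:
    """Package damaged/total counts; ``percent_damaged`` is derived."""
    return NeuronCounts(region=region, damaged=damaged, total=total)


def score_cohort(fields: pd.DataFrame, n_fields: int = 40) -> pd.DataFrame:
    """Per-animal region scores and their cortical sum from a field table.

    ``fields`` columns: animal, group, region, field_index, severity.
    Returns one row per animal with per-region score columns and
    ``cortical_sum``.
    """
    rows = []
    for (animal, group), sub in fields.groupby(["animal", "group"], sort=False):
        scores = {
            region: score_region(rsub["severity"].tolist(), region, n_fields).score
            for region, rsub in sub.groupby("region", sort=False)
        }
        rows.append(
            {
                "animal": animal,
                "group": group,
                **{f"score_{r}": scores.get(r, np.nan) for r in NEOCORTEX_REGIONS},
                "cortical_sum": sum_cortical_scores(scores),
            }
        )
    return pd.DataFrame(rows)


def percent_cohort(counts: pd.DataFrame) -> pd.DataFrame:
    """Add the percent-damaged column to a counts table.

    ``counts`` columns: animal, group, region, damaged, total. Idempotent.
    """
    out = counts.copy()
    bad = out["total"] <= 0
    if bad.any():
        raise ValueError(f"nonpositive neuron totals for rows {out.index[bad].tolist()}")
    out["percent_damaged"] = 100.0 * out["damaged"] / out["total"]
    return out
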