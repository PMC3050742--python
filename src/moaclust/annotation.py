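"""Per-cluster interaction-label profiles and predominance summaries.

A cluster is *predominant* for a label when at least a given fraction
(level: 50%, 66.6% or 75%) of its member compounds carry that label.
Profiles can be computed including compounds with unknown interactions in
the denominator or omitting them; multi-label compounds increment every
one of their labels, so fractions can sum to more than 1.

Two related notions are kept deliberately distinct:

* :func:`predominant_label` — the single label transferred to query
  compounds; it must be the *unique* maximal label and reach the level
  (ties or a missed level give ``None``).
* :func:`predominance_summary` — the share of clusters where *some* label
  reaches the level; ties still count, since such a cluster does have
  "at least X% of members with the same interaction".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem_io import CompoundRecord, InteractionLabel
from .clustering import ClusterSet

#: Absolute tolerance for level comparisons, so that a fraction of 2/3
#: passes the "66.6%" level however the level was entered.
LEVEL_TOLERANCE = 1e-9

#: The three predominance levels (the middle one is exactly two thirds).
DEFAULT_LEVELS = (0.5, 2.0 / 3.0, 0.75)

DEFAULT_MIN_SIZES = (1, 2, 3, 4, 5)


@dataclass
class PredominanceProfile:
    """Label make-up of one cluster under one unknown-handling mode."""

    cluster_index: int
    size_total: int
    size_known: int
    label_counts: dict[InteractionLabel, int]
    include_unknown: bool

    @property
    def unknown_count(self) -> int:
        return self.size_total - self.size_known

    @property
    def denominator(self) -> int:
        return self.size_total if self.include_unknown else self.size_known

    @property
    def fractions(self) -> dict[InteractionLabel, float]:
        d = self.denominator
        if d == 0:
            return {}
        return {label: c / d for label, c in self.label_counts.items()}

    @property
    def unknown_fraction(self) -> float:
        return self.unknown_count / self.size_total if self.size_total else 0.0


def label_profile(
    members: Sequence[str],
    records: Mapping[str, CompoundRecord],
    include_unknown: bool = True,
    cluster_index: int = 0,
) -> PredominanceProfile:
    """Count member labels; multi-label compounds count toward each label."""
    if not members:
        raise ValueError("empty cluster")
    counts: dict[InteractionLabel, int] = {}
    known = 0
    for cid in members:
        try:
            rec = records[cid]
        except KeyError:
            raise KeyError(f"cluster member {cid!r} absent from records") from None
        if rec.labels:
            known += 1
            for label in rec.labels:
                counts[label] = counts.get(label, 0) + 1
    return PredominanceProfile(
        cluster_index=cluster_index,
        size_total=len(members),
        size_known=known,
        label_counts=counts,
        include_unknown=include_unknown,
    )


def predominant_label(
    profile: PredominanceProfile, level: float
) -> InteractionLabel | None:
    """The unique maximal label reaching ``level``, else ``None``.

    ``None`` when the cluster has no labelled members under the active
    mode, when the top fraction misses the level, or when two labels tie
    for the maximum.
    """
    fractions = profile.fractions
    if not fractions:
        return None
    top = max(fractions.values())
    if top < level - LEVEL_TOLERANCE:
        return None
    winners = [
        label
        for label, f in fractions.items()
        if math.isclose(f, top, rel_tol=0.0, abs_tol=LEVEL_TOLERANCE)
    ]
    if len(winners) != 1:
        return None
    return winners[0]


def has_predominant_label(profile: PredominanceProfile, level: float) -> bool:
    """Whether *some* label reaches the level (ties allowed)."""
    return any(f >= level - LEVEL_TOLERANCE for f in profile.fractions.values())


def cluster_profiles(
    cs: ClusterSet,
    records: Mapping[str, CompoundRecord],
    include_unknown: bool = True,
) -> list[PredominanceProfile]:
    return [
        label_profile(members, records, include_unknown, cluster_index=k)
        for k, members in enumerate(cs.clusters())
    ]


def profile_size(profile: PredominanceProfile) -> int:
    """Cluster size under the active mode (used by min-size filters)."""
    return profile.size_total if profile.include_unknown else profile.size_known


def predominance_summary(
    cs: ClusterSet,
    records: Mapping[str, CompoundRecord],
    levels: Sequence[float] = DEFAULT_LEVELS,
    min_sizes: Sequence[int] = DEFAULT_MIN_SIZES,
    include_unknown: bool = True,
) -> pd.DataFrame:
    """Percentage of clusters with a predominant interaction.

    One row per (level, min_size): among clusters whose size (per mode)
    is at least ``min_size``, the percentage whose profile has some label
    at a fraction ≥ level.  When no cluster passes the size filter the
    percentage is NaN (undefined), never 0.
    """
    profiles = cluster_profiles(cs, records, include_unknown)
    rows = []
    for level in levels:
        for min_size in min_sizes:
            eligible = [p for p in profiles if profile_size(p) >= min_size]
            if not eligible:
                pct = float("nan")
            else:
                hits = sum(has_predominant_label(p, level) for p in eligible)
                pct = 100.0 * hits / len(eligible)
            rows.append(
                {
                    "level": level,
                    "min_size": min_size,
                    "include_unknown": include_unknown,
                    "pct_clusters_predominant": pct,
                    "n_clusters_eligible": len(eligible),
                }
            )
    return pd.DataFrame(rows)
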