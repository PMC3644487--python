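"""The weighted seven-parameter, 1000-point primer score.

Each parameter earns up to 100 raw points at its optimal value and is
weighted: GC content x2, nucleotide mismatches x3, and Tm, 3'-GC content,
3'-dG, 5'-dG and repeats x1 each (weights sum to 10, so a perfect primer
scores 1000 points = 100%).

Mismatches are tiered: 1-2 changes cost nothing, 3-4 cost fifty raw
points, 5-6 cost eighty, and seven or more score zero — with the 3x weight
this wipes 30% off a primer's total. Continuous parameters inside their
optimal range score 100; outside, points fall off in documented steps of
the distance from the range (the step schedules are package defaults and
user-configurable; they are not uniquely determined by published totals).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .thermo import PrimerMetrics

logger = logging.getLogger(__name__)

__all__ = ["ScoringConfig", "ScoreBreakdown", "score_mismatch_param",
           "score_range_param", "score_primer"]

#: A step schedule: ordered (max_distance, score) pairs; the first entry whose
#: max_distance covers the observed distance from the optimal range gives the
#: raw score, 0 beyond the last entry. Inside the range the score is 100.
Schedule = list[tuple[float, int]]

DEFAULT_WEIGHTS = {
    "gc": 2, "n_changes": 3, "tm": 1, "gc3": 1, "dg3": 1, "dg5": 1,
    "repeats": 1,
}

DEFAULT_RANGES = {
    "tm": (66.0, 74.0),
    "gc": (40.0, 60.0),
    "gc3": (50.0, 50.0),
    "dg3": (-5.62, -4.74),
    "dg5": (-13.50, -12.62),
}

DEFAULT_SCHEDULES: dict[str, Schedule] = {
    "tm": [(1.0, 80), (2.0, 60), (4.0, 40), (8.0, 20)],
    "gc": [(2.5, 80), (5.0, 60), (10.0, 40), (20.0, 20)],
    "gc3": [(25.0, 50)],
    "dg3": [(0.5, 80), (1.0, 60), (2.0, 40), (4.0, 20)],
    "dg5": [(2.0, 80), (4.0, 60), (6.0, 40), (8.0, 20)],
    # distance here is the combined count of runs + repeat tracts
    "repeats": [(1.0, 50), (2.0, 20)],
}

#: Raw score per mismatch-count tier; >= 7 scores 0 ("more than seven" is
#: read as the terminal tier starting at 7 — the published tiers leave
#: exactly 7 unstated; the alternative reading would give it 20).
MISMATCH_TIERS: list[tuple[int, int, int]] = [
    (1, 2, 100), (3, 4, 50), (5, 6, 20),
]


def _validate_schedule(name: str, schedule: Schedule) -> None:
    last_d, last_s = -1.0, 101
    for d, s in schedule:
        if d <= last_d or s >= last_s or not 0 <= s <= 100:
            raise ValueError(f"schedule for {name!r} must be strictly "
                             "increasing in distance and decreasing in score")
        last_d, last_s = d, s


@dataclass
class ScoringConfig:
    """Weights, optimal ranges and deduction schedules; serializable."""

    weights: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))
    schedules: dict[str, Schedule] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SCHEDULES.items()})
    mismatch_tiers: list[tuple[int, int, int]] = field(
        default_factory=lambda: list(MISMATCH_TIERS))

    def __post_init__(self) -> None:
        if sum(self.weights.values()) != 10:
            raise ValueError("parameter weights must sum to 10 "
                             "(maximum score 1000 points)")
        for name, sched in self.schedules.items():
            _validate_schedule(name, sched)

    @property
    def max_points(self) -> int:
        return 100 * sum(self.weights.values())

    def to_dict(self) -> dict:
        return {
            "weights": self.weights,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "schedules": {k: [list(p) for p in v]
                          for k, v in self.schedules.items()},
            "mismatch_tiers": [list(t) for t in self.mismatch_tiers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringConfig":
        return cls(
            weights=dict(d["weights"]),
            ranges={k: tuple(v) for k, v in d["ranges"].items()},
            schedules={k: [tuple(p) for p in v]
                       for k, v in d["schedules"].items()},
            mismatch_tiers=[tuple(t) for t in d["mismatch_tiers"]],
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ScoringConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-parameter raw scores and the weighted 1000-point total."""

    raw: dict[str, int]
    weights: dict[str, int]

    @property
    def weighted(self) -> dict[str, int]:
        return {k: self.weights[k] * v for k, v in self.raw.items()}

    @property
    def total_points(self) -> int:
        return sum(self.weighted.values())

    @property
    def percent(self) -> float:
        return self.total_points / 10.0

    @property
    def percent_int(self) -> int:
        """Percent rounded to the integer printed in reports."""
        return round(self.percent)


def score_mismatch_param(n_changes: int,
                         tiers: list[tuple[int, int, int]] | None = None) -> int:
    """Raw score for the mismatch count (tiered, see module docstring).

    Zero changes is scored 100 with a warning: a mutagenic primer is
    expected to carry at least two changes, but an edge window can
    legitimately produce an unchanged oligo.
    """
    if n_changes < 0:
        raise ValueError("mismatch count cannot be negative")
    if n_changes == 0:
        logger.warning("primer carries no changes; the stated optimum is a "
                       "minimum of 2 nucleotide changes")
        return 100
    for lo, hi, score in (tiers if tiers is not None else MISMATCH_TIERS):
        if lo <= n_changes <= hi:
            return score
    return 0


def score_range_param(value: float, optimal_range: tuple[float, float],
                      schedule: Schedule) -> int:
    """Raw score for a continuous parameter: 100 inside the closed optimal
    range, stepped down with distance outside, floored at 0."""
    lo, hi = optimal_range
    if lo <= value <= hi:
        return 100
    dist = lo - value if value < lo else value - hi
    for max_dist, score in schedule:
        if dist <= max_dist:
            return score
    return 0


def score_primer(metrics: PrimerMetrics,
                 config: ScoringConfig | None = None) -> ScoreBreakdown:
    """Score one primer's metric panel under the weighted scheme."""
    cfg = config if config is not None else ScoringConfig()
    raw = {
        "gc": score_range_param(metrics.gc_pct, cfg.ranges["gc"],
                                cfg.schedules["gc"]),
        "n_changes": score_mismatch_param(metrics.n_changes, cfg.mismatch_tiers),
        "tm": score_range_param(metrics.tm_c, cfg.ranges["tm"],
                                cfg.schedules["tm"]),
        "gc3": score_range_param(metrics.gc3_pct, cfg.ranges["gc3"],
                                 cfg.schedules["gc3"]),
        "dg3": score_range_param(metrics.dg3_kcal, cfg.ranges["dg3"],
                                 cfg.schedules["dg3"]),
        "dg5": score_range_param(metrics.dg5_kcal, cfg.ranges["dg5"],
                                 cfg.schedules["dg5"]),
        # runs and repeat tracts jointly form the seventh parameter
        "repeats": (100 if metrics.runs + metrics.repeats == 0 else
                    score_range_param(float(metrics.runs + metrics.repeats),
                                      (0.0, 0.0), cfg.schedules["repeats"])),
    }
    return ScoreBreakdown(raw=raw, weights=dict(cfg.weights))
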