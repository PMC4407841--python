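"""Trial design: treatment-set schedule, period-order randomization, MCID.

Each N-of-1 trial consists of 1-4 *treatment sets*.  A set holds two
treatment periods (one mexiletine, one placebo, order randomized per set),
separated by a washout week and followed by an analysis window:

    4 weeks period 1 | 1 week washout | 4 weeks period 2 | 2 weeks analysis

i.e. 11 weeks per set, so a full trial spans 11-44 weeks.  Daily diary
(IVR) severity scores from the last two weeks of each period feed the
statistical analysis; by default 10 usable observations per arm per set are
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ACTIVE_FIRST = "active_first"
PLACEBO_FIRST = "placebo_first"


class InvalidDesignError(ValueError):
    """Design parameters violate the trial structure."""


@dataclass(frozen=True)
class DesignSpec:
    """Structural parameters of the N-of-1 series design.

    Defaults encode the mexiletine/NDM protocol: 30 patients stratified into
    15 chloride-channel and 15 sodium-channel mutation carriers, up to 4
    treatment sets of 4+1+4+2 weeks, 14 diary days per period of which 10
    observations per arm per set are modelled.
    """

    n_patients: int = 30
    subgroup_split: tuple[tuple[str, int], ...] = (("chloride", 15), ("sodium", 15))
    max_sets: int = 4
    period_weeks: int = 4
    washout_weeks: int = 1
    analysis_weeks: int = 2
    diary_days_per_period: int = 14
    obs_per_arm_per_pair: int = 10

    def __post_init__(self) -> None:
        counts = [
            self.n_patients,
            self.max_sets,
            self.period_weeks,
            self.washout_weeks,
            self.analysis_weeks,
            self.diary_days_per_period,
            self.obs_per_arm_per_pair,
        ]
        if any(int(c) != c or c <= 0 for c in counts):
            raise InvalidDesignError("all counts and durations must be positive integers")
        split = dict(self.subgroup_split)
        if any(v <= 0 for v in split.values()):
            raise InvalidDesignError("subgroup counts must be positive")
        if sum(split.values()) != self.n_patients:
            raise InvalidDesignError(
                f"subgroup split {split} does not sum to n_patients={self.n_patients}"
            )

    @property
    def set_weeks(self) -> int:
        """Weeks per treatment set (11 with protocol defaults)."""
        return 2 * self.period_weeks + self.washout_weeks + self.analysis_weeks

    def subgroup_labels(self) -> list[str]:
        """Per-patient subgroup labels in design order."""
        out: list[str] = []
        for name, count in self.subgroup_split:
            out.extend([name] * count)
        return out


@dataclass(frozen=True)
class SetSchedule:
    index: int
    period1_weeks: tuple[int, int]  # inclusive 1-based week range
    washout_weeks: tuple[int, int]
    period2_weeks: tuple[int, int]
    analysis_weeks: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "set": self.index,
            "period1_weeks": list(self.period1_weeks),
            "washout_weeks": list(self.washout_weeks),
            "period2_weeks": list(self.period2_weeks),
            "analysis_weeks": list(self.analysis_weeks),
        }


@dataclass(frozen=True)
class Schedule:
    sets: tuple[SetSchedule, ...]
    total_weeks: int

    def to_dict(self) -> dict:
        return {"total_weeks": self.total_weeks, "sets": [s.to_dict() for s in self.sets]}


@dataclass(frozen=True)
class PeriodOrder:
    """Randomized per-set period order for one patient."""

    labels: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if any(lab not in (ACTIVE_FIRST, PLACEBO_FIRST) for lab in self.labels):
            raise ValueError("labels must be 'active_first' or 'placebo_first'")

    def arm_of(self, set_index: int, period: int) -> str:
        """Arm ('active'/'placebo') for 1-based set and period (1 or 2)."""
        first_active = self.labels[set_index - 1] == ACTIVE_FIRST
        return "active" if (period == 1) == first_active else "placebo"


def build_schedule(n_sets: int, design: DesignSpec | None = None) -> Schedule:
    """Lay out the 1-based week calendar for ``n_sets`` treatment sets.

    Raises :class:`InvalidDesignError` unless ``1 <= n_sets <= design.max_sets``.
    """
    design = design or DesignSpec()
    if int(n_sets) != n_sets or not 1 <= n_sets <= design.max_sets:
        raise InvalidDesignError(
            f"n_sets must be an integer in [1, {design.max_sets}], got {n_sets!r}"
        )
    sets = []
    week = 1
    for k in range(1, n_sets + 1):
        p1 = (week, week + design.period_weeks - 1)
        week = p1[1] + 1
        wash = (week, week + design.washout_weeks - 1)
        week = wash[1] + 1
        p2 = (week, week + design.period_weeks - 1)
        week = p2[1] + 1
        ana = (week, week + design.analysis_weeks - 1)
        week = ana[1] + 1
        sets.append(SetSchedule(k, p1, wash, p2, ana))
    return Schedule(sets=tuple(sets), total_weeks=week - 1)


def randomize_orders(n_sets: int, seed: int) -> PeriodOrder:
    """Block-randomize the period order independently for each set.

    Within a set the block is (active, placebo) in one of the two orders,
    each with probability 1/2.  Reproducible under a fixed seed.
    """
    if int(n_sets) != n_sets or n_sets < 1:
        raise InvalidDesignError(f"n_sets must be a positive integer, got {n_sets!r}")
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=n_sets)
    labels = tuple(ACTIVE_FIRST if f else PLACEBO_FIRST for f in flips)
    return PeriodOrder(labels=labels, seed=int(seed))


def mcid_half_sd(within_subject_sd: float) -> float:
    """Distribution-based MCID: half the within-subject standard deviation.

    With the IVR stiffness scale's reported within-subject SD of 1.5 this
    yields the protocol's MCID of 0.75 points.
    """
    if within_subject_sd < 0:
        raise ValueError("within-subject SD must be non-negative")
    return within_subject_sd / 2.0
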