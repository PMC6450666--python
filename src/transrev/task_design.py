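"""Transreinforcer-reversal trial schedules.

Two conditioned stimuli (CS) each predict one of four food odors (US) drawn
from a 2x2 category structure (two sweet, two savory). Each CS carries its
own independent US sequence: the associated odor changes without warning
after 4-6 presentations of the current CS-US pair, either to the other odor
of the same category (within-category reversal) or to one of the two odors
of the other category (between-category reversal). The two per-CS sequences
are interleaved into a single balanced trial order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SWEET = "sweet"
SAVORY = "savory"

REVERSAL_NONE = "none"
REVERSAL_WITHIN = "within"
REVERSAL_BETWEEN = "between"


@dataclass(frozen=True)
class OdorSet:
    """Four odor USs, two per perceptual category, with pleasantness ratings.

    Pleasantness is on the -10 ("most disliked sensation imaginable") to
    +10 ("most liked") visual-analog scale; the screening procedure selects
    odors rated > 5 and within two units of each other, so matched sets
    hover around 6.
    """

    odor_ids: tuple[int, ...] = (0, 1, 2, 3)
    category: dict[int, str] = field(
        default_factory=lambda: {0: SWEET, 1: SWEET, 2: SAVORY, 3: SAVORY}
    )
    pleasantness: dict[int, float] = field(
        default_factory=lambda: {0: 6.0, 1: 6.0, 2: 6.0, 3: 6.0}
    )

    def __post_init__(self) -> None:
        if len(self.odor_ids) != 4 or len(set(self.odor_ids)) != 4:
            raise ValueError("OdorSet requires exactly 4 distinct odors")
        cats = [self.category[o] for o in self.odor_ids]
        if cats.count(SWEET) != 2 or cats.count(SAVORY) != 2:
            raise ValueError("OdorSet requires exactly 2 odors per category")
        for o in self.odor_ids:
            if not -10.0 <= self.pleasantness[o] <= 10.0:
                raise ValueError(f"pleasantness of odor {o} outside [-10, 10]")

    @property
    def labels(self) -> dict[int, str]:
        out, counts = {}, {SWEET: 0, SAVORY: 0}
        for o in self.odor_ids:
            cat = self.category[o]
            counts[cat] += 1
            out[o] = ("SW" if cat == SWEET else "SA") + str(counts[cat])
        return out

    def same_category(self, a: int, b: int) -> bool:
        return self.category[a] == self.category[b]

    def within_alternative(self, odor: int) -> int:
        """The single other odor of `odor`'s category."""
        return next(
            o for o in self.odor_ids if o != odor and self.same_category(o, odor)
        )

    def other_category(self, odor: int) -> list[int]:
        return [o for o in self.odor_ids if not self.same_category(o, odor)]

    def pleasantness_vector(self) -> np.ndarray:
        return np.array([self.pleasantness[o] for o in self.odor_ids], float)

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels
        return pd.DataFrame(
            {
                "odor_id": list(self.odor_ids),
                "label": [labels[o] for o in self.odor_ids],
                "category": [self.category[o] for o in self.odor_ids],
                "pleasantness": [self.pleasantness[o] for o in self.odor_ids],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OdorSet":
        return cls(
            odor_ids=tuple(int(o) for o in df["odor_id"]),
            category={int(r.odor_id): str(r.category) for r in df.itertuples()},
            pleasantness={
                int(r.odor_id): float(r.pleasantness) for r in df.itertuples()
            },
        )


@dataclass(frozen=True)
class TaskDesign:
    """Design parameters of a single 128-trial run."""

    n_trials: int = 128
    n_cs: int = 2
    run_length_range: tuple[int, int] = (4, 6)
    reversal_type_prob: float = 0.5  # probability a reversal is between-category
    max_consecutive_cs: int = 3
    allow_shared_us: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cs != 2:
            raise ValueError("the task uses exactly 2 CS")
        if self.n_trials % self.n_cs != 0:
            raise ValueError("n_trials must be divisible by n_cs")
        lo, hi = self.run_length_range
        if lo < 1 or lo > hi:
            raise ValueError("run_length_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.reversal_type_prob <= 1.0:
            raise ValueError("reversal_type_prob must lie in [0, 1]")
        if self.max_consecutive_cs < 1:
            raise ValueError("max_consecutive_cs must be >= 1")


@dataclass
class TrialSchedule:
    """Per-trial CS, delivered US, and reversal annotation for one run."""

    cs: np.ndarray  # (T,) int, 0/1
    us: np.ndarray  # (T,) int odor ids
    is_reversal: np.ndarray  # (T,) bool
    reversal_type: list[str]  # (T,) none|within|between

    @property
    def n_trials(self) -> int:
        return len(self.cs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "cs": self.cs.astype(int),
                "us": self.us.astype(int),
                "is_reversal": self.is_reversal.astype(int),
                "reversal_type": self.reversal_type,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSchedule":
        return cls(
            cs=df["cs"].to_numpy(int),
            us=df["us"].to_numpy(int),
            is_reversal=df["is_reversal"].to_numpy(bool),
            reversal_type=[str(x) for x in df["reversal_type"]],
        )


def _interleave_cs(design: TaskDesign, rng: np.random.Generator) -> np.ndarray:
    """Balanced random CS order with a cap on consecutive same-CS trials.

    Sequential sampling proportional to remaining counts, forcing a switch
    at the cap; rare dead ends (one CS left in a block longer than the cap)
    restart the draw.
    """
    per_cs = design.n_trials // 2
    cap = design.max_consecutive_cs
    while True:
        remaining = [per_cs, per_cs]
        order = np.empty(design.n_trials, dtype=int)
        run_cs, run_len = -1, 0
        ok = True
        for t in range(design.n_trials):
            options = [c for c in (0, 1) if remaining[c] > 0]
            if run_len >= cap and run_cs in options and len(options) > 1:
                options.remove(run_cs)
            elif run_len >= cap and options == [run_cs]:
                ok = False
                break
            weights = np.array([remaining[c] for c in options], float)
            c = int(rng.choice(options, p=weights / weights.sum()))
            order[t] = c
            remaining[c] -= 1
            run_len = run_len + 1 if c == run_cs else 1
            run_cs = c
        if ok:
            return order


def generate_schedule(
    design: TaskDesign,
    odors: OdorSet,
    seed: int | None = None,
) -> TrialSchedule:
    """Generate one transreinforcer-reversal run.

    Per-CS run lengths are drawn uniformly from ``design.run_length_range``
    (the final run per CS may be truncated by the trial budget). At each
    reversal the US changes: with probability ``reversal_type_prob`` to an
    other-category odor (uniform over the two), otherwise to the single
    same-category alternative. Unless ``allow_shared_us``, the two CS never
    predict the same odor simultaneously; when the constraint rules out
    every candidate of the drawn reversal type, the other type is used.
    Deterministic for a given seed.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    per_cs = design.n_trials // 2
    lo, hi = design.run_length_range
    if lo > per_cs:
        raise ValueError("run_length_range infeasible for this trial budget")

    order = _interleave_cs(design, rng)

    # reversal points in per-CS presentation index space
    revert_at: list[set[int]] = []
    for _ in range(2):
        points, pos = set(), 0
        while True:
            pos += int(rng.integers(lo, hi + 1))
            if pos >= per_cs:
                break
            points.add(pos)
        revert_at.append(points)

    # initial US per CS
    current = [int(rng.choice(odors.odor_ids)), -1]
    second_choices = [
        o
        for o in odors.odor_ids
        if design.allow_shared_us or o != current[0]
    ]
    current[1] = int(rng.choice(second_choices))

    us = np.empty(design.n_trials, dtype=int)
    is_rev = np.zeros(design.n_trials, dtype=bool)
    rtype = [REVERSAL_NONE] * design.n_trials
    seen = [0, 0]  # presentations so far per CS

    for t in range(design.n_trials):
        c = int(order[t])
        k = seen[c]
        if k in revert_at[c]:
            old = current[c]
            blocked = None if design.allow_shared_us else current[1 - c]
            within_target = odors.within_alternative(old)
            within_feasible = within_target != blocked
            p_within = 1.0 - design.reversal_type_prob
            if design.allow_shared_us:
                q_within = p_within
            elif within_feasible:
                # the no-sharing constraint makes within moves infeasible
                # whenever the other CS holds this CS's category alternative
                # (which happens after every between reversal); drawing
                # within with q = 2p/(1+p) where it is feasible restores the
                # configured marginal within fraction p over the run
                q_within = 2.0 * p_within / (1.0 + p_within)
            else:
                q_within = 0.0
            if rng.random() < q_within:
                cands = [within_target]
            else:
                # at most one of the two other-category odors can be blocked
                cands = [o for o in odors.other_category(old) if o != blocked]
            new = int(rng.choice(cands))
            current[c] = new
            is_rev[t] = True
            rtype[t] = (
                REVERSAL_WITHIN if odors.same_category(old, new) else REVERSAL_BETWEEN
            )
        us[t] = current[c]
        seen[c] += 1

    return TrialSchedule(cs=order, us=us, is_reversal=is_rev, reversal_type=rtype)


def validate_schedule(
    schedule: TrialSchedule,
    design: TaskDesign,
    odors: OdorSet,
) -> list[str]:
    """Check every schedule invariant; return a list of violations (empty = valid).

    Never raises: malformed schedules yield violations, not exceptions.
    """
    violations: list[str] = []
    T = schedule.n_trials
    if T != design.n_trials:
        violations.append(f"trial count {T} != design n_trials {design.n_trials}")

    for c in (0, 1):
        n_c = int(np.sum(schedule.cs == c))
        if n_c != design.n_trials // 2:
            violations.append(f"CS {c} appears {n_c} times, expected {design.n_trials // 2}")

    valid_odors = set(odors.odor_ids)
    lo, hi = design.run_length_range
    for c in (0, 1):
        idx = np.flatnonzero(schedule.cs == c)
        prev_us = None
        run_len = 0
        for k, t in enumerate(idx):
            u = int(schedule.us[t])
            if u not in valid_odors:
                violations.append(f"trial {t + 1}: unknown odor id {u}")
                continue
            flagged = bool(schedule.is_reversal[t])
            changed = prev_us is not None and u != prev_us
            if k == 0 and flagged:
                violations.append(f"trial {t + 1}: first presentation of CS {c} flagged as reversal")
            if k > 0 and flagged != changed:
                violations.append(
                    f"trial {t + 1}: is_reversal={flagged} but US "
                    f"{'changed' if changed else 'did not change'}"
                )
            if flagged and prev_us is not None and u == prev_us:
                violations.append(f"trial {t + 1}: reversal must change the US")
            rt = schedule.reversal_type[t]
            if not flagged and rt != REVERSAL_NONE:
                violations.append(f"trial {t + 1}: reversal_type {rt} on non-reversal trial")
            if flagged and changed:
                expect = (
                    REVERSAL_WITHIN
                    if odors.same_category(prev_us, u)
                    else REVERSAL_BETWEEN
                )
                if rt != expect:
                    violations.append(
                        f"trial {t + 1}: reversal_type {rt}, expected {expect}"
                    )
            if changed:
                if not (lo <= run_len <= hi):
                    violations.append(
                        f"trial {t + 1}: CS {c} run length {run_len} outside "
                        f"[{lo}, {hi}]"
                    )
                run_len = 1
            else:
                run_len += 1
            prev_us = u
        if run_len > hi:  # truncated final run may be short, never long
            violations.append(f"CS {c}: final run length {run_len} exceeds {hi}")

    if not design.allow_shared_us:
        current = {}
        for t in range(T):
            current[int(schedule.cs[t])] = int(schedule.us[t])
            if len(current) == 2 and current[0] == current[1]:
                violations.append(f"trial {t + 1}: both CS map to odor {current[0]}")
                break
    return violations


def reversal_bounds(per_cs: int, run_range: tuple[int, int]) -> tuple[int, int]:
    """Exact [min, max] reversal count for one CS given its presentation budget.

    A sequence of runs drawn from ``run_range`` covers ``per_cs``
    presentations, the final run possibly truncated; reversals sit at run
    boundaries. Enumeration-free closed form: fewest boundaries with maximal
    runs, most with minimal runs.
    """
    lo, hi = run_range
    n_min = int(np.ceil(per_cs / hi))  # fewest runs started
    n_max = int(np.ceil(per_cs / lo))
    # when per_cs is an exact multiple of lo, the last run is complete and
    # no further run starts
    if per_cs % lo == 0:
        n_max = per_cs // lo
    return n_min - 1, n_max - 1
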