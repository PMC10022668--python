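"""Pseudorandomized stimulus schedules for the visual and auditory rating tasks.

Both tasks present a sequence of stimulus epochs whose two physical dimensions
(circle size/brightness, or sound frequency/attenuation) change between
epochs under a balanced four-condition design: each transition changes
dimension 1 only, dimension 2 only, both, or neither, with an exact number of
transitions per condition.  Epoch durations are drawn at random and then
repaired to satisfy the design's duration constraints exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DuoscaleError, InfeasibleDesignError, SchemaError

log = logging.getLogger(__name__)

#: Change conditions for one epoch transition.
CONDITIONS: tuple[str, ...] = (
    "change_dim1",
    "change_dim2",
    "change_both",
    "change_neither",
)

#: Condition label for the first visual epoch (no preceding stimulus).
INITIAL = "initial"

_CHANGES = {
    "change_dim1": (True, False),
    "change_dim2": (False, True),
    "change_both": (True, True),
    "change_neither": (False, False),
}

#: Dimension names per task, in (dim1, dim2) order.
TASK_DIMS: dict[str, tuple[str, str]] = {
    "visual": ("size", "brightness"),
    "auditory": ("pitch", "volume"),
}


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus epoch: onset/duration in ms and its two physical values.

    ``dim1_value`` is circle size in pixels or sound frequency in Hz;
    ``dim2_value`` is brightness as a grayscale level (0 black .. 245 white)
    or sound attenuation in dB (lower = louder).
    """

    onset: int
    duration: int
    dim1_value: float
    dim2_value: float
    condition: str


@dataclass(frozen=True)
class TaskSchedule:
    """An ordered, gap-free sequence of stimulus epochs for one task run."""

    task: str
    epochs: tuple[StimulusEpoch, ...]
    total_duration: int
    set_id: int = 0
    seed: int = 0
    part: int = 0
    #: Physical values of the implicit pre-task stimulus (auditory), against
    #: which the first epoch's change condition is evaluated.
    baseline: tuple[float, float] | None = None

    @property
    def dims(self) -> tuple[str, str]:
        return TASK_DIMS[self.task]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.epochs], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        base = self.baseline if self.baseline is not None else (np.nan, np.nan)
        return pd.DataFrame(
            {
                "onset_ms": [e.onset for e in self.epochs],
                "duration_ms": [e.duration for e in self.epochs],
                "condition": [e.condition for e in self.epochs],
                "dim1_value": [e.dim1_value for e in self.epochs],
                "dim2_value": [e.dim2_value for e in self.epochs],
                "task": self.task,
                "set_id": self.set_id,
                "part": self.part,
                "seed": self.seed,
                "baseline_dim1": base[0],
                "baseline_dim2": base[1],
            }
        )


@dataclass(frozen=True)
class VisualDesign:
    """Design parameters of the visual (circles) task."""

    changes_per_condition: int = 5
    duration_bounds: tuple[int, int] = (6742, 13103)
    total_duration: int = 195_000
    dim1_range: tuple[float, float] = (20.0, 300.0)   # size, px
    dim2_range: tuple[float, float] = (0.0, 245.0)    # brightness, grayscale level
    #: A changed dimension must move by at least this fraction of its range.
    min_change_frac: float = 0.10

    @property
    def n_changes(self) -> int:
        return self.changes_per_condition * len(CONDITIONS)


@dataclass(frozen=True)
class AuditoryDesign:
    """Design parameters of one auditory part."""

    changes_per_condition: int = 6
    duration_bounds: tuple[int, int] = (5600, 10500)
    duration_mean: int = 8000
    duration_sd: float = 1450.0
    dim1_range: tuple[float, float] = (100.0, 1500.0)  # frequency, Hz
    dim2_range: tuple[float, float] = (15.0, 65.0)     # attenuation, dB
    part_duration_bounds: tuple[int, int] = (189_000, 196_000)
    min_change_frac: float = 0.10

    @property
    def n_changes(self) -> int:
        return self.changes_per_condition * len(CONDITIONS)


def coded_value(task: str, dim_index: int, raw) -> np.ndarray | float:
    """Physical value as entered in analyses.

    Visual size/brightness and sound frequency enter in raw units.  Sound
    attenuation is reversed and normalized so the predictor increases with
    loudness: 65 dB -> 0, 15 dB -> 1.
    """
    if task == "auditory" and dim_index == 1:
        return (65.0 - np.asarray(raw, dtype=float)) / 50.0
    out = np.asarray(raw, dtype=float)
    return out if out.ndim else float(out)


def normalized_value(task: str, dim_index: int, raw, design=None) -> np.ndarray | float:
    """Coded value rescaled to [0, 1] over the design range (simulator input)."""
    design = design or (VisualDesign() if task == "visual" else AuditoryDesign())
    lo, hi = (design.dim1_range, design.dim2_range)[dim_index]
    if task == "auditory" and dim_index == 1:
        return (hi - np.asarray(raw, dtype=float)) / (hi - lo)
    return (np.asarray(raw, dtype=float) - lo) / (hi - lo)


def _draw_changed(prev: float, lo: float, hi: float, delta: float, rng) -> float:
    """Uniform draw over [lo, hi] excluding the window (prev-delta, prev+delta)."""
    left = max(prev - delta, lo) - lo
    right = hi - min(prev + delta, hi)
    if left + right <= 0:
        raise InfeasibleDesignError(
            f"min change {delta} leaves no admissible values around {prev} in [{lo}, {hi}]"
        )
    u = rng.uniform(0.0, left + right)
    return lo + u if u < left else hi - (left + right - u)


def _redistribute(d: np.ndarray, lo: float, hi: float, total: float) -> np.ndarray:
    """Shift values within [lo, hi] so they sum to ``total`` (waterfilling)."""
    d = np.clip(np.asarray(d, dtype=float), lo, hi)
    n = len(d)
    if not (n * lo <= total <= n * hi):
        raise InfeasibleDesignError(
            f"cannot fit {n} epochs in [{lo}, {hi}] summing to {total}"
        )
    for _ in range(n + 1):
        excess = total - d.sum()
        if abs(excess) < 1e-9:
            return d
        free = (d < hi) if excess > 0 else (d > lo)
        if not free.any():  # pragma: no cover - guarded by the bound check
            raise InfeasibleDesignError("duration repair ran out of slack")
        d[free] += excess / free.sum()
        d = np.clip(d, lo, hi)
    return d


def _round_to_total(d: np.ndarray, lo: int, hi: int, total: int) -> np.ndarray:
    """Largest-remainder rounding to integers within bounds, exact total."""
    base = np.floor(d).astype(int)
    short = int(total - base.sum())
    order = np.argsort(-(d - base), kind="stable")
    i = 0
    for idx in order:
        if i >= short:
            break
        if base[idx] + 1 <= hi:
            base[idx] += 1
            i += 1
    if i < short or base.sum() != total or base.min() < lo or base.max() > hi:
        raise InfeasibleDesignError("integer duration repair failed")
    return base


def _value_sequence(
    conditions, ranges, frac, rng, start: tuple[float, float]
) -> list[tuple[float, float]]:
    """Walk the two dimensions through the condition sequence from ``start``."""
    values = []
    cur = list(start)
    for cond in conditions:
        ch = _CHANGES[cond]
        for j in (0, 1):
            if ch[j]:
                lo, hi = ranges[j]
                cur[j] = _draw_changed(cur[j], lo, hi, frac * (hi - lo), rng)
        values.append((cur[0], cur[1]))
    return values


def generate_visual_schedule(
    seed: int, design: VisualDesign | None = None
) -> TaskSchedule:
    """Generate one pseudorandomized visual-task schedule.

    The task shows an initial circle followed by 20 potential changes (5 per
    condition) in pseudorandom order.  Circle durations are drawn uniformly
    within the design bounds and repaired so they sum to the task's total
    duration exactly; a changed dimension moves by at least
    ``min_change_frac`` of its range, while unchanged dimensions carry the
    previous value forward bit-for-bit.
    """
    design = design or VisualDesign()
    rng = np.random.default_rng([int(seed), 11])
    n_epochs = design.n_changes + 1
    lo, hi = design.duration_bounds
    if n_epochs * lo > design.total_duration or n_epochs * hi < design.total_duration:
        raise InfeasibleDesignError(
            f"{n_epochs} epochs of [{lo}, {hi}] ms cannot total {design.total_duration} ms"
        )
    raw = rng.uniform(lo, hi, n_epochs)
    dur = _round_to_total(
        _redistribute(raw, lo, hi, design.total_duration), lo, hi, design.total_duration
    )

    conditions = [
        str(c) for c in rng.permutation(np.repeat(CONDITIONS, design.changes_per_condition))
    ]
    start = (
        rng.uniform(*design.dim1_range),
        rng.uniform(*design.dim2_range),
    )
    values = [start] + _value_sequence(
        conditions,
        (design.dim1_range, design.dim2_range),
        design.min_change_frac,
        rng,
        start,
    )
    conditions = [INITIAL] + conditions
    onsets = np.concatenate([[0], np.cumsum(dur)[:-1]]).astype(int)
    epochs = tuple(
        StimulusEpoch(int(o), int(d), v[0], v[1], c)
        for o, d, v, c in zip(onsets, dur, values, conditions)
    )
    return TaskSchedule(
        task="visual",
        epochs=epochs,
        total_duration=int(design.total_duration),
        set_id=0,
        seed=int(seed),
    )


def generate_auditory_schedule(
    seed: int, part: int = 1, set_id: int = 1, design: AuditoryDesign | None = None
) -> TaskSchedule:
    """Generate one auditory part: 24 sounds, 6 change conditions each.

    Sound durations are drawn uniformly within bounds and affinely
    renormalized to the design's target sample moments (mean 8000 ms,
    sd 1450 ms), then clipped and repaired; the repair preserves the sample
    mean exactly, so the part lasts ``n * duration_mean`` ms.  The first
    sound's change condition is evaluated against an implicit baseline sound
    stored on the schedule.  The stimulus stream is keyed by ``(seed,
    set_id)`` only, so the same sound set reused in another part yields the
    same sounds.
    """
    design = design or AuditoryDesign()
    if set_id not in (1, 2, 3):
        raise DuoscaleError(f"set_id must be 1, 2 or 3, got {set_id}")
    if part not in (1, 2, 3):
        raise DuoscaleError(f"part must be 1, 2 or 3, got {part}")
    rng = np.random.default_rng([int(seed), 23, int(set_id)])
    n = design.n_changes
    lo, hi = design.duration_bounds
    mean, sd = design.duration_mean, design.duration_sd
    if not (lo < mean < hi):
        raise InfeasibleDesignError(f"target mean {mean} outside ({lo}, {hi})")
    if sd <= 0 or sd >= (hi - lo):
        raise InfeasibleDesignError(f"target sd {sd} infeasible under bounds [{lo}, {hi}]")
    total = n * mean
    if not (n * lo <= total <= n * hi):
        raise InfeasibleDesignError("duration mean incompatible with bounds")

    raw = rng.uniform(lo, hi, n)
    z = (raw - raw.mean()) / raw.std(ddof=1)
    dur = _round_to_total(_redistribute(mean + sd * z, lo, hi, total), lo, hi, total)

    conditions = [
        str(c) for c in rng.permutation(np.repeat(CONDITIONS, design.changes_per_condition))
    ]
    baseline = (
        rng.uniform(*design.dim1_range),
        rng.uniform(*design.dim2_range),
    )
    values = _value_sequence(
        conditions,
        (design.dim1_range, design.dim2_range),
        design.min_change_frac,
        rng,
        baseline,
    )
    onsets = np.concatenate([[0], np.cumsum(dur)[:-1]]).astype(int)
    epochs = tuple(
        StimulusEpoch(int(o), int(d), v[0], v[1], c)
        for o, d, v, c in zip(onsets, dur, values, conditions)
    )
    sched = TaskSchedule(
        task="auditory",
        epochs=epochs,
        total_duration=int(total),
        set_id=int(set_id),
        seed=int(seed),
        part=int(part),
        baseline=baseline,
    )
    plo, phi = design.part_duration_bounds
    if not (plo <= sched.total_duration <= phi):
        raise InfeasibleDesignError(
            f"part duration {sched.total_duration} outside [{plo}, {phi}] ms"
        )
    return sched


def validate_schedule(schedule: TaskSchedule, design=None) -> None:
    """Check counts, bounds, tiling and change-consistency; raise on violation."""
    if design is None:
        design = VisualDesign() if schedule.task == "visual" else AuditoryDesign()
    lo, hi = design.duration_bounds
    t = 0
    for e in schedule.epochs:
        if e.onset != t:
            raise DuoscaleError(f"epoch onset {e.onset} leaves a gap/overlap at {t}")
        if not (lo <= e.duration <= hi):
            raise DuoscaleError(f"duration {e.duration} outside [{lo}, {hi}]")
        t += e.duration
    if t != schedule.total_duration:
        raise DuoscaleError(
            f"epochs tile {t} ms, schedule declares {schedule.total_duration} ms"
        )
    change_epochs = [e for e in schedule.epochs if e.condition != INITIAL]
    counts = {c: 0 for c in CONDITIONS}
    for e in change_epochs:
        counts[e.condition] += 1
    if any(v != design.changes_per_condition for v in counts.values()):
        raise DuoscaleError(f"condition counts {counts} not exactly balanced")
    prev = schedule.baseline
    ranges = (design.dim1_range, design.dim2_range)
    for e in schedule.epochs:
        if e.condition != INITIAL and prev is not None:
            ch = _CHANGES[e.condition]
            cur = (e.dim1_value, e.dim2_value)
            for j in (0, 1):
                delta = abs(cur[j] - prev[j])
                min_delta = design.min_change_frac * (ranges[j][1] - ranges[j][0])
                if ch[j] and delta < min_delta:
                    raise DuoscaleError(
                        f"{e.condition} epoch at {e.onset} moved dim{j + 1} by only {delta}"
                    )
                if not ch[j] and delta != 0.0:
                    raise DuoscaleError(
                        f"{e.condition} epoch at {e.onset} altered unchanged dim{j + 1}"
                    )
        prev = (e.dim1_value, e.dim2_value)


# ---------------------------------------------------------------------------
# Counterbalancing

_PART_LABELS = ("2D", "1D_pitch", "1D_volume")
_LATIN = ((0, 1, 2), (1, 2, 0), (2, 0, 1))


def counterbalance_plan(n_participants: int) -> pd.DataFrame:
    """Per-participant counterbalanced factor assignments.

    Axis mapping and descriptor-set order alternate with period 2 (phase
    shifted so the two factors are not confounded); the order of the three
    auditory parts and the assignment of sound sets to parts are rows of a
    3x3 Latin square.  Every factor is balanced to within one participant for
    any ``n_participants``.
    """
    if n_participants < 1:
        raise DuoscaleError("n_participants must be >= 1")
    rows = []
    for i in range(n_participants):
        part_row = _LATIN[i % 3]
        set_row = _LATIN[(i + i // 3) % 3]
        rows.append(
            {
                "participant": i,
                "axis_assignment": "dim1_x" if i % 2 == 0 else "dim1_y",
                "part_order": "|".join(_PART_LABELS[k] for k in part_row),
                "set_order": "|".join(str(k + 1) for k in set_row),
                "descriptor_set_order": (
                    "pain_first" if (i + i // 2) % 2 == 0 else "fatigue_first"
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV I/O

_SCHEDULE_COLUMNS = [
    "onset_ms",
    "duration_ms",
    "condition",
    "dim1_value",
    "dim2_value",
    "task",
    "set_id",
    "part",
    "seed",
    "baseline_dim1",
    "baseline_dim2",
]


def write_schedule_tsv(schedule: TaskSchedule, path) -> None:
    df = schedule.to_frame()
    # repr is the shortest exact decimal form, so values survive the round trip
    for col in ("dim1_value", "dim2_value", "baseline_dim1", "baseline_dim2"):
        df[col] = df[col].map(lambda v: v if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def read_schedule_tsv(path) -> TaskSchedule:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"schedule TSV missing columns: {missing}")
    epochs = tuple(
        StimulusEpoch(
            int(r.onset_ms),
            int(r.duration_ms),
            float(r.dim1_value),
            float(r.dim2_value),
            str(r.condition),
        )
        for r in df.itertuples()
    )
    b1, b2 = df["baseline_dim1"].iloc[0], df["baseline_dim2"].iloc[0]
    baseline = None if pd.isna(b1) else (float(b1), float(b2))
    return TaskSchedule(
        task=str(df["task"].iloc[0]),
        epochs=epochs,
        total_duration=int(sum(e.duration for e in epochs)),
        set_id=int(df["set_id"].iloc[0]),
        seed=int(df["seed"].iloc[0]),
        part=int(df["part"].iloc[0]),
        baseline=baseline,
    )
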