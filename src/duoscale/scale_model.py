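"""Verbally anchored rating axes with logarithmically spaced intensity descriptors.

The scale places each intensity descriptor along an axis at a position
proportional to the base-10 logarithm of its psychophysically scaled relative
magnitude (RM).  Logarithmic placement devotes more of the axis to weak
sensations, which a linear scale undersamples.  The 'no sensation' anchor has
no defined magnitude (RM = 0) and is pinned to position 0.

Two axes at right angles form a 2D scale on which two stimulus dimensions
(e.g. size/brightness, pitch/volume, pain/fatigue) are rated simultaneously.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .exceptions import ClampWarning, DuoscaleError, MonotonicityError

log = logging.getLogger(__name__)

#: The 13 intensity descriptors in reference order (rank 0 = 'no sensation').
DESCRIPTOR_LABELS: tuple[str, ...] = (
    "no sensation",
    "faint",
    "very weak",
    "weak",
    "very mild",
    "mild",
    "moderate",
    "barely strong",
    "slightly intense",
    "strong",
    "intense",
    "very intense",
    "extremely intense",
)

# Strict-increase separation between consecutive positions, as a fraction of span.
_POSITION_EPS = 1e-6


@dataclass(frozen=True)
class Descriptor:
    """One intensity descriptor: label, reference rank, and relative magnitude.

    ``relative_magnitude`` is the descriptor's scaled perceived intensity in
    line-length-equivalent units; it is 0 only for 'no sensation'.
    """

    label: str
    reference_rank: int
    relative_magnitude: float

    def __post_init__(self) -> None:
        if self.reference_rank < 0:
            raise DuoscaleError(f"negative reference rank for {self.label!r}")
        if self.relative_magnitude < 0:
            raise DuoscaleError(f"negative relative magnitude for {self.label!r}")
        if self.relative_magnitude == 0 and self.reference_rank != 0:
            raise DuoscaleError(
                f"zero relative magnitude only allowed at rank 0, got {self.label!r}"
            )


@dataclass(frozen=True)
class ScaleAxis:
    """An ordered descriptor axis with positions in rating units on [0, span]."""

    descriptors: tuple[Descriptor, ...]
    span: float
    positions: tuple[float, ...]
    dimension_label: str = ""

    def position_of(self, label: str) -> float:
        for d, p in zip(self.descriptors, self.positions):
            if d.label == label:
                return p
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "dimension_label": self.dimension_label,
            "span": self.span,
            "labels": [d.label for d in self.descriptors],
            "reference_ranks": [d.reference_rank for d in self.descriptors],
            "relative_magnitudes": [d.relative_magnitude for d in self.descriptors],
            "positions": list(self.positions),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, obj: dict) -> "ScaleAxis":
        descs = tuple(
            Descriptor(lbl, rank, rm)
            for lbl, rank, rm in zip(
                obj["labels"], obj["reference_ranks"], obj["relative_magnitudes"]
            )
        )
        return cls(
            descriptors=descs,
            span=float(obj["span"]),
            positions=tuple(float(p) for p in obj["positions"]),
            dimension_label=obj.get("dimension_label", ""),
        )

    @classmethod
    def from_json(cls, text: str) -> "ScaleAxis":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class Scale2D:
    """Two descriptor axes rating two distinct stimulus dimensions.

    ``assignment`` maps each rated dimension name to the axis ('x' or 'y')
    on which it is rated.
    """

    axis_x: ScaleAxis
    axis_y: ScaleAxis
    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        axes = sorted(self.assignment.values())
        if axes != ["x", "y"]:
            raise DuoscaleError(
                f"assignment must map two dimensions onto x and y, got {self.assignment}"
            )
        dims = list(self.assignment)
        if dims[0] == dims[1]:
            raise DuoscaleError("the two axes must rate distinct dimensions")

    @property
    def spans(self) -> dict[str, float]:
        return {"x": self.axis_x.span, "y": self.axis_y.span}

    def axis_for(self, dim: str) -> ScaleAxis:
        return self.axis_x if self.assignment[dim] == "x" else self.axis_y


def _load_reference() -> dict:
    with resources.files("duoscale.data").joinpath(
        "descriptor_magnitudes.json"
    ).open() as fh:
        return json.load(fh)


def reference_descriptors(sensation: str) -> tuple[Descriptor, ...]:
    """The 13 packaged descriptors with relative magnitudes for one sensation.

    Parameters
    ----------
    sensation : {"pain", "fatigue"}
    """
    ref = _load_reference()
    try:
        rms = ref["relative_magnitude"][sensation]
    except KeyError:
        raise DuoscaleError(f"unknown sensation {sensation!r}") from None
    out = [Descriptor("no sensation", 0, 0.0)]
    for rank, label in enumerate(ref["labels"][1:], start=1):
        out.append(Descriptor(label, rank, float(rms[label])))
    return tuple(out)


def build_axis(
    descriptors,
    span: float = 100.0,
    dimension_label: str = "",
    nonmonotone: str = "raise",
) -> ScaleAxis:
    """Place descriptors on an axis by log10 of their relative magnitudes.

    For descriptors with positive RM the position is::

        span * (log10(RM) - log10(RM_min+)) / (log10(RM_max) - log10(RM_min+))

    where ``RM_min+`` / ``RM_max`` are the smallest and largest positive RMs.
    A rank-0 descriptor with RM 0 ('no sensation') is pinned to position 0 and
    excluded from the log grid.  Positions are then forced strictly increasing
    by a tiny epsilon chain (``span * 1e-6`` per step), which matters only for
    exact ties.

    Parameters
    ----------
    descriptors : sequence of Descriptor
        Must have reference ranks forming a bijection onto 0..n-1.
    span : float
        Axis length in rating units.
    nonmonotone : {"raise", "repair"}
        How to treat RMs that decrease with reference rank.  ``"repair"``
        pools adjacent violators (average on the log scale), which is needed
        for the packaged tables, each of which contains one small inversion.
    """
    descs = sorted(descriptors, key=lambda d: d.reference_rank)
    n = len(descs)
    if span <= 0:
        raise DuoscaleError(f"span must be positive, got {span}")
    if n < 2:
        raise DuoscaleError("an axis needs at least two descriptors")
    labels = [d.label for d in descs]
    if len(set(labels)) != n:
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise DuoscaleError(f"duplicate descriptor labels: {dupes}")
    if [d.reference_rank for d in descs] != list(range(n)):
        raise DuoscaleError("reference ranks must be a bijection onto 0..n-1")
    if nonmonotone not in ("raise", "repair"):
        raise DuoscaleError(f"nonmonotone must be 'raise' or 'repair', got {nonmonotone!r}")

    pinned = descs[0].relative_magnitude == 0.0
    grid = descs[1:] if pinned else descs
    rms = np.array([d.relative_magnitude for d in grid], dtype=float)
    if np.any(rms <= 0):
        raise DuoscaleError("relative magnitudes must be positive for ranks >= 1")

    bad = [
        (grid[i].label, grid[i + 1].label)
        for i in range(len(rms) - 1)
        if rms[i + 1] < rms[i]
    ]
    if bad:
        if nonmonotone == "raise":
            pairs = ", ".join(f"{a!r} > {b!r}" for a, b in bad)
            raise MonotonicityError(
                f"relative magnitudes not monotone in reference rank: {pairs}"
            )
        log.warning(
            "repairing non-monotone relative magnitudes (pooled adjacent "
            "violators): %s",
            ", ".join(f"{a!r}/{b!r}" for a, b in bad),
        )
        rms = np.exp(_pava(np.log(rms)))

    logrm = np.log10(rms)
    lo, hi = logrm.min(), logrm.max()
    if hi - lo <= 0:
        raise DuoscaleError("degenerate log range: all relative magnitudes equal")
    grid_pos = span * (logrm - lo) / (hi - lo)
    positions = ([0.0] if pinned else []) + list(grid_pos)

    eps = span * _POSITION_EPS
    for i in range(1, n):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + eps

    return ScaleAxis(
        descriptors=tuple(descs),
        span=float(span),
        positions=tuple(float(p) for p in positions),
        dimension_label=dimension_label,
    )


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares isotonic fit (equal weights)."""
    y = np.asarray(y, dtype=float)
    blocks = [[v, 1] for v in y]  # [sum, count]
    out: list[list[float]] = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] / out[-2][1] > out[-1][0] / out[-1][1]:
            s, c = out.pop()
            out[-1][0] += s
            out[-1][1] += c
    res = []
    for s, c in out:
        res.extend([s / c] * int(c))
    return np.array(res)


def reference_axis(
    sensation: str, span: float = 100.0, dimension_label: str | None = None
) -> ScaleAxis:
    """Build the packaged axis (Table-derived RMs) for 'pain' or 'fatigue'.

    Both packaged columns contain one adjacent inversion, so the permissive
    repair path is used.
    """
    return build_axis(
        reference_descriptors(sensation),
        span=span,
        dimension_label=sensation if dimension_label is None else dimension_label,
        nonmonotone="repair",
    )


def _clamp(p: float, span: float) -> float:
    if p < 0.0 or p > span:
        warnings.warn(
            f"position {p} outside [0, {span}]; clamped to boundary", ClampWarning,
            stacklevel=3,
        )
        return min(max(p, 0.0), span)
    return p


def position_to_rating(axis: ScaleAxis, p: float) -> float:
    """Map a cursor position on the axis to a numeric rating.

    The default mapping is the identity on [0, span]: the recorded rating is
    the cursor's distance from the origin in rating units.  Out-of-range
    positions are clamped with a :class:`ClampWarning` (the cursor may rest on
    the boundary).
    """
    return _clamp(float(p), axis.span)


def rating_to_position(axis: ScaleAxis, r: float) -> float:
    """Inverse of :func:`position_to_rating` (identity with boundary clamp)."""
    return _clamp(float(r), axis.span)


def assign_axes(participant_index: int, dims: tuple[str, str] = ("size", "brightness")) -> dict[str, str]:
    """Counterbalanced x/y assignment of the two rated dimensions.

    Even participant indices map ``dims[0]`` to x; odd indices swap, so any
    block of two consecutive participants contains both assignments.
    """
    if participant_index < 0:
        raise DuoscaleError("participant_index must be >= 0")
    a, b = dims
    if participant_index % 2 == 0:
        return {a: "x", b: "y"}
    return {a: "y", b: "x"}
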