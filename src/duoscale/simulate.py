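"""Synthetic participants for the descriptor tasks and the rating tasks.

Three generators mirror the statistical structure the analyses assume:

* continuous 2D rating streams — the latent rating relaxes exponentially
  toward a target that is a linear mix of the current stimulus value, the
  other dimension's value (cross-dimension interference) and the preceding
  epoch's value (carryover), mapped through a normalized power transform onto
  the rating axis, with additive Gaussian sample noise and per-participant
  heterogeneity in gain and mixing weights;
* magnitude-estimation responses — a Stevens power law of stimulus intensity
  with multiplicative (log-normal) noise and a per-participant modulus;
* descriptor rankings — the reference order corrupted by independent
  adjacent transpositions.

Everything is seed-reproducible; each participant derives an independent
stream from the experiment seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import DuoscaleError
from .descriptor_scaling import RankingRecord
from .rating_pipeline import align, downsample
from .scale_model import Scale2D, ScaleAxis, assign_axes, reference_axis
from .task_design import (
    AuditoryDesign,
    TaskSchedule,
    VisualDesign,
    generate_auditory_schedule,
    generate_visual_schedule,
    normalized_value,
)

#: Default log-spaced line lengths for the calibration condition (arbitrary units).
DEFAULT_LINE_LENGTHS: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)

#: A 12-step geometric intensity ladder spanning the reference tables' range
#: (0.4 to 2.6).  Used as generator truth in noisy rank-recovery studies,
#: where adjacent true intensities must be separated for rank order to be
#: identifiable (the packaged tables contain near-ties and two inversions).
GEOMETRIC_DESCRIPTOR_LADDER: tuple[float, ...] = tuple(
    float(v) for v in np.geomspace(0.4, 2.6, 12)
)


@dataclass(frozen=True)
class RaterParams:
    """Population parameters of the synthetic continuous rater.

    ``interference_w`` and ``carryover_w`` are unitless weights on the
    normalized other-dimension and previous-epoch values relative to a unit
    weight on the current value; their defaults mirror the sign and relative
    magnitude of the published rating-accuracy coefficients (generator
    inputs, not reproduction targets).  ``gain_sd`` and ``weight_sd`` are
    between-participant standard deviations of the overall gain and of each
    mixing weight.  ``lag_tau`` is the exponential response-lag time constant
    (0 = instantaneous).
    """

    lag_tau: float = 0.0          # ms
    interference_w: float = -0.06
    carryover_w: float = 0.16
    noise_sd: float = 5.0         # rating units (on span 100)
    psychophysical_exponent: float = 1.0
    gain_sd: float = 0.10
    weight_sd: float = 0.04
    #: Between-participant sd of a constant rating offset, in normalized
    #: target units (fraction of the usable scale).
    intercept_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_tau < 0 or self.noise_sd < 0:
            raise DuoscaleError("lag_tau and noise_sd must be >= 0")
        if self.psychophysical_exponent <= 0:
            raise DuoscaleError("psychophysical_exponent must be positive")

    @classmethod
    def realistic(cls, **overrides) -> "RaterParams":
        """A preset with a human-plausible 400-ms response lag for demos."""
        return replace(cls(lag_tau=400.0), **overrides)


@dataclass(frozen=True)
class ResponderParams:
    """Population parameters of the synthetic magnitude-estimation responder.

    Power-law exponents default to the classic force-production value for
    handgrip (1.7) and a near-linear exponent for button-press duration
    (1.1).  ``alpha_sd`` is the between-participant spread of the log
    modulus, removed by standardization.
    """

    beta_grip: float = 1.7
    beta_button: float = 1.1
    alpha_grip: float = 0.0
    alpha_button: float = 0.0
    lognoise_sd: float = 0.15
    alpha_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_grip <= 0 or self.beta_button <= 0:
            raise DuoscaleError("power-law exponents must be positive")
        if self.lognoise_sd < 0 or self.alpha_sd < 0:
            raise DuoscaleError("noise standard deviations must be >= 0")


def draw_participant_effects(params: RaterParams, rng) -> dict[str, float]:
    """One participant's gain and mixing weights around the population values."""
    return {
        "gain": 1.0 + params.gain_sd * rng.standard_normal(),
        "interference_w": params.interference_w + params.weight_sd * rng.standard_normal(),
        "carryover_w": params.carryover_w + params.weight_sd * rng.standard_normal(),
        "offset": params.intercept_sd * rng.standard_normal(),
    }


def _target_envelope(params: RaterParams) -> tuple[float, float]:
    """Population bounds of the mixed normalized target (3-sigma headroom).

    The latent rating is mapped affinely through this envelope onto
    [0, span], the way an experimenter calibrates stimulus ranges so that
    ratings stay on-scale: without it, targets beyond the axis ends would be
    truncated and attenuate every regression coefficient.  With all weights
    and heterogeneity zero the envelope is [0, 1] and the map is the
    identity on normalized values.
    """
    wi, wc = params.interference_w, params.carryover_w
    m = 3.0 * params.weight_sd
    b = 3.0 * params.intercept_sd
    lo = min(0.0, wi - m) + min(0.0, wc - m) - b
    hi = (1.0 + 3.0 * params.gain_sd) + max(0.0, wi + m) + max(0.0, wc + m) + b
    return lo, hi


def _epoch_series(schedule: TaskSchedule, design, gamma: float):
    """Per-epoch normalized (and power-transformed) values and previous values."""
    raw1 = np.array([e.dim1_value for e in schedule.epochs])
    raw2 = np.array([e.dim2_value for e in schedule.epochs])
    u = [
        np.asarray(normalized_value(schedule.task, 0, raw1, design)) ** gamma,
        np.asarray(normalized_value(schedule.task, 1, raw2, design)) ** gamma,
    ]
    prev = []
    for j in (0, 1):
        if schedule.baseline is not None:
            first = float(
                np.asarray(
                    normalized_value(schedule.task, j, schedule.baseline[j], design)
                )
            ) ** gamma
        else:
            first = u[j][0]  # no preceding stimulus: no carryover distortion
        prev.append(np.concatenate([[first], u[j][:-1]]))
    return u, prev


def simulate_ratings(
    schedule: TaskSchedule,
    params: RaterParams,
    scale: Scale2D | ScaleAxis,
    design=None,
    rng=None,
    participant_effects: dict[str, float] | None = None,
    sample_ms: int = 20,
) -> pd.DataFrame:
    """Simulate one participant's continuous rating stream at ``sample_ms``.

    With a :class:`Scale2D` both task dimensions are rated (columns ``x`` and
    ``y`` per the scale's axis assignment); with a :class:`ScaleAxis` whose
    ``dimension_label`` names one task dimension only that dimension is rated
    (column ``x``), though the other dimension still interferes with it.
    """
    design = design or (
        VisualDesign() if schedule.task == "visual" else AuditoryDesign()
    )
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    eff = participant_effects or draw_participant_effects(params, rng)
    dims = schedule.dims
    if isinstance(scale, Scale2D):
        rated = list(dims)
        axes = {d: scale.axis_for(d) for d in rated}
        cols = {d: scale.assignment[d] for d in rated}
    else:
        if scale.dimension_label not in dims:
            raise DuoscaleError(
                f"1D axis rates {scale.dimension_label!r}, task has {dims}"
            )
        rated = [scale.dimension_label]
        axes = {rated[0]: scale}
        cols = {rated[0]: "x"}

    u, prev = _epoch_series(schedule, design, params.psychophysical_exponent)
    t = np.arange(0, schedule.total_duration, sample_ms, dtype=float)
    epoch_idx = np.searchsorted(schedule.onsets, t, side="right") - 1
    onsets = schedule.onsets

    env_lo, env_hi = _target_envelope(params)
    out = {"t_ms": t}
    for d in rated:
        j = dims.index(d)
        o = 1 - j
        span = axes[d].span
        mixed = (
            eff["gain"] * u[j]
            + eff["interference_w"] * u[o]
            + eff["carryover_w"] * prev[j]
            + eff.get("offset", 0.0)
        )
        target_by_epoch = span * (mixed - env_lo) / (env_hi - env_lo)
        target = target_by_epoch[epoch_idx]
        if params.lag_tau > 0:
            latent = np.empty_like(target)
            r_start = target_by_epoch[0]
            for k in range(len(schedule.epochs)):
                sel = epoch_idx == k
                if not sel.any():
                    continue
                tt = t[sel] - onsets[k]
                tk = target_by_epoch[k]
                latent[sel] = tk + (r_start - tk) * np.exp(-tt / params.lag_tau)
                t_end = (
                    onsets[k + 1] if k + 1 < len(onsets) else schedule.total_duration
                ) - onsets[k]
                r_start = tk + (r_start - tk) * np.exp(-t_end / params.lag_tau)
        else:
            latent = target
        obs = latent + params.noise_sd * rng.standard_normal(len(t))
        out[cols[d]] = np.clip(obs, 0.0, span)
    columns = ["t_ms"] + [c for c in ("x", "y") if c in out]
    return pd.DataFrame(out)[columns]


def true_linear_coefficients(
    task: str,
    rating_dim: str,
    params: RaterParams,
    span: float = 100.0,
    design=None,
) -> dict[str, float]:
    """Population-level regression coefficients implied by a linear rater.

    Valid only for ``psychophysical_exponent == 1``, where the target is an
    affine function of the coded predictors used by :func:`align`.
    """
    if params.psychophysical_exponent != 1.0:
        raise DuoscaleError("closed-form coefficients require exponent 1")
    design = design or (VisualDesign() if task == "visual" else AuditoryDesign())
    dims = ("size", "brightness") if task == "visual" else ("pitch", "volume")
    j = dims.index(rating_dim)
    o = 1 - j
    ranges = (design.dim1_range, design.dim2_range)

    def slope_per_coded(idx):
        lo, hi = ranges[idx]
        if task == "auditory" and idx == 1:
            return 1.0, 0.0  # coded loudness already lives on [0, 1]
        return 1.0 / (hi - lo), -lo / (hi - lo)

    sj, cj = slope_per_coded(j)
    so, co = slope_per_coded(o)
    env_lo, env_hi = _target_envelope(params)
    k = span / (env_hi - env_lo)
    b_cur = k * sj
    b_oth = k * params.interference_w * so
    b_prev = k * params.carryover_w * sj
    intercept = k * (
        cj + params.interference_w * co + params.carryover_w * cj - env_lo
    )
    return {
        "Intercept": intercept,
        "current_value": b_cur,
        "other_value": b_oth,
        "previous_value": b_prev,
    }


def simulate_rating_dataset(
    n_participants: int = 32,
    seed: int = 0,
    task: str = "visual",
    rater: RaterParams | None = None,
    design=None,
    span: float = 100.0,
    rating_dims=None,
    exclude_transition_ms: float = 0.0,
    age_effect_gain: float = 0.0,
    bin_ms: int = 250,
    set_id: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, TaskSchedule]:
    """Full pipeline: schedule -> synthetic raters -> downsample -> align.

    Every participant rates the same schedule on a 2D scale (axis assignment
    counterbalanced by participant parity; age groups alternate
    younger/older).  ``age_effect_gain`` is added to the gain of older
    participants (0 = no true age effect).  Returns the concatenated aligned
    records, a participant metadata table, and the schedule.
    """
    rater = rater or RaterParams()
    if task == "visual":
        schedule = generate_visual_schedule(seed, design)
    else:
        schedule = generate_auditory_schedule(seed, part=1, set_id=set_id, design=design)
    dims = schedule.dims
    rating_dims = tuple(rating_dims) if rating_dims is not None else (dims[0],)
    axis_a = reference_axis("pain", span=span, dimension_label=dims[0])
    axis_b = reference_axis("fatigue", span=span, dimension_label=dims[1])

    records = []
    meta = []
    for p in range(n_participants):
        rng = np.random.default_rng([int(seed), 101, p])
        age = "younger" if p % 2 == 0 else "older"
        eff = draw_participant_effects(rater, rng)
        if age == "older":
            eff["gain"] += age_effect_gain
        assignment = assign_axes(p, dims)
        scale = Scale2D(
            axis_x=axis_a if assignment[dims[0]] == "x" else axis_b,
            axis_y=axis_b if assignment[dims[1]] == "y" else axis_a,
            assignment=assignment,
        )
        stream = simulate_ratings(
            schedule, rater, scale, design=design, rng=rng, participant_effects=eff
        )
        binned = downsample(stream, bin_ms=bin_ms)
        for d in rating_dims:
            records.append(
                align(
                    binned,
                    schedule,
                    rating_dim=d,
                    assignment=assignment,
                    metadata={
                        "participant": p,
                        "age_group": age,
                        "scale_type": "2D",
                        "set_id": schedule.set_id,
                    },
                    exclude_transition_ms=exclude_transition_ms,
                )
            )
        meta.append({"participant": p, "age_group": age, **eff})
    return pd.concat(records, ignore_index=True), pd.DataFrame(meta), schedule


def simulate_magnitude_responses(
    intensities,
    params: ResponderParams,
    n_participants: int,
    n_trials: int = 3,
    stimulus_type: str = "line",
    recorded_intensity=None,
    rng=None,
) -> pd.DataFrame:
    """Power-law magnitude-estimation responses for both modalities.

    ``value = exp(alpha_m + beta_m * log(intensity) + eps)`` with
    ``eps ~ N(0, lognoise_sd^2)`` independently per trial.  ``intensities``
    drive the responses; ``recorded_intensity`` (default: the intensities)
    is what lands in the ``stimulus_intensity`` column — pass descriptor
    reference ranks there when the driving intensity is the descriptor's true
    perceived magnitude.
    """
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities <= 0):
        raise DuoscaleError("intensities must be positive")
    recorded = (
        np.asarray(recorded_intensity, dtype=float)
        if recorded_intensity is not None
        else intensities
    )
    if recorded.shape != intensities.shape:
        raise DuoscaleError("recorded_intensity must match intensities in shape")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    pop = {
        "handgrip": (params.alpha_grip, params.beta_grip),
        "button": (params.alpha_button, params.beta_button),
    }
    rows = []
    for p in range(n_participants):
        for modality, (alpha, beta) in pop.items():
            alpha_p = alpha + params.alpha_sd * rng.standard_normal()
            for intensity, rec in zip(intensities, recorded):
                eps = params.lognoise_sd * rng.standard_normal(n_trials)
                values = np.exp(alpha_p + beta * np.log(intensity) + eps)
                for trial, v in enumerate(values, start=1):
                    rows.append(
                        {
                            "participant": p,
                            "stimulus_type": stimulus_type,
                            "stimulus_intensity": float(rec),
                            "modality": modality,
                            "trial": trial,
                            "value": float(v),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_descriptor_experiment(
    n_participants: int = 30,
    seed: int = 0,
    params: ResponderParams | None = None,
    line_lengths=DEFAULT_LINE_LENGTHS,
    true_rm: dict[str, dict[str, float]] | None = None,
    n_trials: int = 3,
) -> pd.DataFrame:
    """Responses for all three stimulus types (lines + both descriptor sets).

    Descriptor responses are driven by the descriptors' true perceived
    magnitudes (default: the packaged reference tables) but recorded with
    their reference rank 1..12 as ``stimulus_intensity``, matching the
    magnitude-estimation analysis contract.
    """
    from .descriptor_scaling import load_reference_table

    params = params or ResponderParams()
    rng = np.random.default_rng([int(seed), 57])
    if true_rm is None:
        true_rm = {
            s: load_reference_table(s).rm for s in ("fatigue", "pain")
        }
    frames = [
        simulate_magnitude_responses(
            line_lengths, params, n_participants, n_trials, "line", rng=rng
        )
    ]
    for sensation, rm in true_rm.items():
        labels = list(rm)
        intensities = np.array([rm[l] for l in labels])
        ranks = np.arange(1, len(labels) + 1, dtype=float)
        frames.append(
            simulate_magnitude_responses(
                intensities,
                params,
                n_participants,
                n_trials,
                f"{sensation}_descriptor",
                recorded_intensity=ranks,
                rng=rng,
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_rankings(
    reference,
    swap_prob: float,
    n: int,
    seed: int = 0,
    sensation: str = "pain",
    pairs=None,
) -> list[RankingRecord]:
    """Rankings = reference order corrupted by adjacent transpositions.

    For each record the adjacent pairs (restricted to ``pairs`` indices when
    given) are visited left to right on a working copy; each is swapped
    independently with probability ``swap_prob``.
    """
    if not (0.0 <= swap_prob <= 1.0):
        raise DuoscaleError("swap_prob must be in [0, 1]")
    reference = tuple(reference)
    pairs = list(pairs) if pairs is not None else list(range(len(reference) - 1))
    rng = np.random.default_rng([int(seed), 83])
    out = []
    for i in range(n):
        arr = list(reference)
        for k in pairs:
            if rng.random() < swap_prob:
                arr[k], arr[k + 1] = arr[k + 1], arr[k]
        out.append(RankingRecord(participant=i, sensation=sensation, ranking=tuple(arr)))
    return out
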