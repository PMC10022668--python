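"""Analyses of the two descriptor familiarization tasks.

Ranking task: per-descriptor percentage of participants placing the
descriptor at its reference rank, plus the modal rank.

Magnitude-estimation task: responses (handgrip peak force, button-press
duration) are reduced to per-cell geometric means, standardized by modulus
equalization within participant x modality x stimulus type, calibrated
against the line-length condition through a Stevens power law
``R = exp(alpha) * S**beta``, and inverted into line-length-equivalent
relative magnitudes (RMs) of the intensity descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DuoscaleError, SchemaError
from .scale_model import DESCRIPTOR_LABELS, _load_reference

log = logging.getLogger(__name__)

RESPONSE_COLUMNS = [
    "participant",
    "stimulus_type",
    "stimulus_intensity",
    "modality",
    "trial",
    "value",
]

STIMULUS_TYPES = ("line", "fatigue_descriptor", "pain_descriptor")
MODALITIES = ("handgrip", "button")


@dataclass(frozen=True)
class RankingRecord:
    """One participant's ranking of the 12 intensity descriptors, least to most."""

    participant: object
    sensation: str
    ranking: tuple[str, ...]


@dataclass(frozen=True)
class CalibrationFit:
    """Power-law calibration of one response modality on the line condition."""

    modality: str
    exponent_beta: float
    intercept_alpha: float  # natural-log units
    r_squared: float


@dataclass(frozen=True)
class RelativeMagnitudeTable:
    """Relative magnitudes of the 12 intensity descriptors for one sensation."""

    sensation: str
    rm: dict[str, float]

    def values_in_rank_order(self, labels=None) -> np.ndarray:
        labels = labels if labels is not None else DESCRIPTOR_LABELS[1:]
        return np.array([self.rm[l] for l in labels], dtype=float)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def load_reference_table(sensation: str) -> RelativeMagnitudeTable:
    """The packaged reference RM table for 'pain' or 'fatigue'."""
    ref = _load_reference()
    try:
        rm = ref["relative_magnitude"][sensation]
    except KeyError:
        raise DuoscaleError(f"unknown sensation {sensation!r}") from None
    return RelativeMagnitudeTable(sensation=sensation, rm={k: float(v) for k, v in rm.items()})


# ---------------------------------------------------------------------------
# Ranking task


def rank_agreement(records, reference) -> pd.DataFrame:
    """Percentage of participants placing each descriptor at its reference rank.

    Returns a DataFrame indexed by descriptor label with columns
    ``pct_at_reference`` (0..100), ``modal_rank`` (0-based, most frequent
    observed rank) and ``modal_tie`` (True when the mode is not unique).
    """
    records = list(records)
    if not records:
        raise DuoscaleError("need at least one ranking record")
    reference = tuple(reference)
    k = len(reference)
    for rec in records:
        if sorted(rec.ranking) != sorted(reference):
            raise DuoscaleError(
                f"record {rec.participant!r} is not a permutation of the reference"
            )
    n = len(records)
    counts = {label: np.zeros(k, dtype=int) for label in reference}
    for rec in records:
        for pos, label in enumerate(rec.ranking):
            counts[label][pos] += 1
    rows = []
    for ref_pos, label in enumerate(reference):
        c = counts[label]
        modal = int(np.argmax(c))
        rows.append(
            {
                "descriptor": label,
                "pct_at_reference": 100.0 * c[ref_pos] / n,
                "modal_rank": modal,
                "modal_tie": int((c == c[modal]).sum()) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("descriptor")


# ---------------------------------------------------------------------------
# Magnitude estimation


def geometric_mean(values) -> float:
    """exp(mean(log(values))); every value must be strictly positive."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DuoscaleError("geometric mean of an empty set")
    if np.any(v <= 0):
        raise DuoscaleError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def _check_response_frame(responses: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RESPONSE_COLUMNS if c not in responses.columns]
    if missing:
        raise SchemaError(f"response table missing columns: {missing}")
    if np.any(responses["value"].to_numpy(dtype=float) <= 0):
        raise DuoscaleError("response values must be strictly positive")
    return responses


def standardize_responses(
    responses: pd.DataFrame, n_trials: int = 3
) -> pd.DataFrame:
    """Modulus equalization of magnitude-estimation responses.

    Within each participant x modality x stimulus-type block, every stimulus
    cell is reduced to the geometric mean of its trials and divided by the
    geometric grand mean of the block's cell means, so the standardized
    values of a block multiply to 1.  Cells with a trial count different from
    ``n_trials`` are dropped with a logged warning.
    """
    responses = _check_response_frame(responses)
    cell_keys = ["participant", "modality", "stimulus_type", "stimulus_intensity"]
    sizes = responses.groupby(cell_keys, sort=False)["value"].size()
    bad = sizes[sizes != n_trials]
    if len(bad):
        log.warning("dropping %d incomplete cells (expected %d trials)", len(bad), n_trials)
        responses = responses.set_index(cell_keys).drop(index=bad.index).reset_index()
    cells = (
        responses.groupby(cell_keys, sort=False)["value"]
        .apply(geometric_mean)
        .rename("cell_gm")
        .reset_index()
    )
    block_keys = ["participant", "modality", "stimulus_type"]
    grand = (
        cells.groupby(block_keys, sort=False)["cell_gm"]
        .apply(geometric_mean)
        .rename("grand_gm")
        .reset_index()
    )
    out = cells.merge(grand, on=block_keys)
    out["std_value"] = out["cell_gm"] / out["grand_gm"]
    return out[cell_keys + ["std_value"]]


def fit_power_law(lengths, responses, modality: str = "") -> CalibrationFit:
    """OLS of log(response) on log(stimulus): Stevens power-law calibration.

    Returns the exponent beta (slope), intercept alpha (natural-log units)
    and the R-squared of the log-log fit.
    """
    x = np.log(np.asarray(lengths, dtype=float))
    y = np.log(np.asarray(responses, dtype=float))
    if x.shape != y.shape or x.size < 3:
        raise DuoscaleError("need >= 3 paired (length, response) observations")
    if np.unique(x).size < 2:
        raise DuoscaleError("zero variance in stimulus lengths")
    res = stats.linregress(x, y)
    return CalibrationFit(
        modality=modality,
        exponent_beta=float(res.slope),
        intercept_alpha=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def calibrate_participants(std_responses: pd.DataFrame) -> dict[tuple, CalibrationFit]:
    """Per participant x modality power-law fit on the line condition."""
    lines = std_responses[std_responses["stimulus_type"] == "line"]
    if lines.empty:
        raise DuoscaleError("no line-condition rows to calibrate on")
    fits: dict[tuple, CalibrationFit] = {}
    for (p, m), grp in lines.groupby(["participant", "modality"], sort=False):
        fits[(p, m)] = fit_power_law(
            grp["stimulus_intensity"], grp["std_value"], modality=str(m)
        )
    return fits


def relative_magnitudes(
    std_responses: pd.DataFrame,
    fits: dict[tuple, CalibrationFit],
    sensation: str,
    labels=None,
    allow_single_modality: bool = False,
) -> RelativeMagnitudeTable:
    """Line-equivalent relative magnitudes of the intensity descriptors.

    Each standardized descriptor response ``r`` is inverted through that
    participant-and-modality's line calibration,
    ``m = exp((log r - alpha) / beta)``, then aggregated by geometric mean
    across modalities and across participants.  The global scale of the
    result is not identified (calibration removes units).

    ``stimulus_intensity`` for descriptor rows is the reference rank (1..12),
    mapped onto ``labels`` (default: the packaged descriptor order).
    """
    stype = f"{sensation}_descriptor"
    sub = std_responses[std_responses["stimulus_type"] == stype].copy()
    if sub.empty:
        raise DuoscaleError(f"no rows with stimulus_type {stype!r}")
    modalities = sub["modality"].unique()
    if len(modalities) < 2 and not allow_single_modality:
        raise DuoscaleError(
            "both response modalities required (pass allow_single_modality=True to override)"
        )
    for key, fit in fits.items():
        if fit.exponent_beta <= 0:
            raise DuoscaleError(f"non-invertible calibration (beta <= 0) for {key}")

    def invert(row):
        fit = fits[(row["participant"], row["modality"])]
        return float(
            np.exp((np.log(row["std_value"]) - fit.intercept_alpha) / fit.exponent_beta)
        )

    sub["line_equiv"] = sub.apply(invert, axis=1)
    per_participant = (
        sub.groupby(["participant", "stimulus_intensity"], sort=False)["line_equiv"]
        .apply(geometric_mean)
        .reset_index()
    )
    pooled = (
        per_participant.groupby("stimulus_intensity", sort=True)["line_equiv"]
        .apply(geometric_mean)
    )
    labels = list(labels) if labels is not None else list(DESCRIPTOR_LABELS[1:])
    rm = {}
    for rank, value in pooled.items():
        idx = int(rank) - 1
        if not (0 <= idx < len(labels)):
            raise DuoscaleError(f"descriptor rank {rank} outside 1..{len(labels)}")
        rm[labels[idx]] = float(value)
    return RelativeMagnitudeTable(sensation=sensation, rm=rm)


def rescale_to_reference(
    table: RelativeMagnitudeTable, reference: RelativeMagnitudeTable
) -> RelativeMagnitudeTable:
    """Rescale a table so its geometric mean matches the reference's.

    Used before comparisons, since the global RM scale is unidentified.
    """
    labels = list(table.rm)
    factor = geometric_mean(list(reference.rm.values())) / geometric_mean(
        list(table.rm.values())
    )
    return RelativeMagnitudeTable(
        sensation=table.sensation, rm={l: table.rm[l] * factor for l in labels}
    )


def compare_sensations(
    rm_fatigue: RelativeMagnitudeTable, rm_pain: RelativeMagnitudeTable
) -> PairedTestResult:
    """Paired two-sided t-test of fatigue vs pain RMs over the 12 descriptors."""
    if set(rm_fatigue.rm) != set(rm_pain.rm):
        raise DuoscaleError("mismatched descriptor sets")
    labels = sorted(rm_fatigue.rm)
    a = np.array([rm_fatigue.rm[l] for l in labels], dtype=float)
    b = np.array([rm_pain.rm[l] for l in labels], dtype=float)
    d = a - b
    n = len(d)
    df = n - 1
    sd = d.std(ddof=1)
    # treat float-noise-level spread of the differences as exactly constant
    if sd <= 1e-12 * max(1.0, abs(d.mean())):
        if np.allclose(d, 0.0):
            return PairedTestResult(t=0.0, df=df, p=1.0, degenerate=False)
        t = float(np.inf) * np.sign(d.mean())
        return PairedTestResult(t=t, df=df, p=0.0, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df))
    return PairedTestResult(t=t, df=df, p=p)


def check_monotonicity(
    rm: RelativeMagnitudeTable, labels=None
) -> list[tuple[str, str]]:
    """Adjacent descriptor pairs (by reference rank) whose RMs invert.

    A pair ``(lower, higher)`` is flagged when the higher-ranked descriptor
    has a strictly smaller RM than its lower-ranked neighbor.
    """
    labels = list(labels) if labels is not None else list(DESCRIPTOR_LABELS[1:])
    labels = [l for l in labels if l in rm.rm]
    out = []
    for a, b in zip(labels, labels[1:]):
        if rm.rm[b] < rm.rm[a]:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# TSV I/O


def write_responses_tsv(responses: pd.DataFrame, path) -> None:
    _check_response_frame(responses)[RESPONSE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_responses_tsv(path) -> pd.DataFrame:
    return _check_response_frame(pd.read_csv(path, sep="\t", float_precision="round_trip"))
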