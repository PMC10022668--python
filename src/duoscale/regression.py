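"""Mixed-effects rating-accuracy and descriptor-magnitude models.

The original analyses were hierarchical (timepoints within participants
within age groups, with design factors such as scale type or sound set as
intermediate levels).  Here they are expressed as two-level linear mixed
models: a participant random intercept (optionally random slopes for the
level-1 predictors) with group-level factors entered as fixed cross-level
interaction terms.  The fixed-effect targets are identical; pseudo-levels
with two or three units are avoided.

Conventions kept from the hierarchical-modelling tradition: coefficients are
reported with t-ratios; terms involving a participant-level moderator (and,
under random slopes, every term) use ``df = n_groups - 2``; p-values between
0.05 and 0.1 are labelled "trend".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .exceptions import DuoscaleError

log = logging.getLogger(__name__)

#: Deterministic numeric codings for known categorical moderators.
MODERATOR_CODES: dict[str, dict] = {
    "age_group": {"younger": 0, "older": 1},
    "scale_type": {"1D": 0, "2D": 1},
    "stimulus_type": {"line": 0, "fatigue_descriptor": 1, "pain_descriptor": 2},
}


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and with which random structure."""

    outcome: str
    level1_predictors: tuple[str, ...]
    moderators: tuple[str, ...] = ()
    random_structure: str = "intercept"  # or "intercept+slopes"
    center: bool = False

    def __post_init__(self) -> None:
        if self.random_structure not in ("intercept", "intercept+slopes"):
            raise DuoscaleError(
                f"unknown random structure {self.random_structure!r}"
            )


@dataclass(frozen=True)
class TermResult:
    estimate: float
    se: float
    t_ratio: float
    p_value: float
    label: str
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RegressionResult:
    coefficients: dict[str, TermResult]
    resid_var: float
    n_obs: int
    n_groups: int
    outcome: str
    random_structure: str
    converged: bool = True
    fallback: bool = False
    variance_explained: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": term,
                "estimate": c.estimate,
                "se": c.se,
                "t_ratio": c.t_ratio,
                "p_value": c.p_value,
                "label": c.label,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
            }
            for term, c in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


def p_label(p: float) -> str:
    """Significance label: p<0.05 significant; 0.05<=p<0.1 trend; else n.s."""
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "trend"
    return "n.s."


def _encode(df: pd.DataFrame, columns) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        if col in MODERATOR_CODES and df[col].dtype == object:
            codes = MODERATOR_CODES[col]
            unknown = set(df[col].unique()) - set(codes)
            if unknown:
                raise DuoscaleError(f"unknown levels {unknown} for moderator {col!r}")
            df[col] = df[col].map(codes).astype(float)
        elif df[col].dtype == object:
            levels = sorted(df[col].unique())
            df[col] = df[col].map({l: i for i, l in enumerate(levels)}).astype(float)
    return df


def _fit_mixed(data: pd.DataFrame, spec: ModelSpec, group_col: str = "participant"):
    preds = list(spec.level1_predictors)
    mods = list(spec.moderators)
    used = [spec.outcome] + preds + mods + [group_col]
    missing = [c for c in used if c not in data.columns]
    if missing:
        raise DuoscaleError(f"data missing columns: {missing}")
    df = _encode(data[used].copy(), mods)
    df = df.dropna(subset=used).reset_index(drop=True)
    n_groups = df[group_col].nunique()
    if n_groups < 2:
        raise DuoscaleError("need >= 2 participants")
    if spec.center:
        for p in preds:
            df[p] = df[p] - df[p].mean()

    rhs = " + ".join(preds) if preds else "1"
    if mods:
        rhs = f"({rhs}) * ({' + '.join(mods)})" if preds else " + ".join(mods)
    formula = f"{spec.outcome} ~ {rhs}"

    slope_re = None
    if spec.random_structure == "intercept+slopes" and preds:
        # random slopes carry a full (unstructured) covariance; standardized
        # copies keep the covariance optimization well conditioned without
        # changing the model or the fixed-effect standard errors
        for p in preds:
            sd = df[p].std(ddof=0)
            df[f"__z_{p}"] = (df[p] - df[p].mean()) / (sd if sd > 0 else 1.0)
        slope_re = "1 + " + " + ".join(f"__z_{p}" for p in preds)

    def _usable(res):
        if res is None:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return bool(getattr(res, "converged", True)) and np.all(
                np.isfinite(res.bse_fe.to_numpy())
            )

    def run(re_formula):
        model = smf.mixedlm(
            formula, df, groups=df[group_col], re_formula=re_formula,
        )
        res = None
        for method in ("lbfgs", "bfgs", "powell"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(reml=True, method=method, maxiter=200)
                except Exception:
                    continue
            if _usable(res):
                break
        return res

    fallback = False
    res = run(slope_re if slope_re is not None else "1")
    ok = _usable(res)
    if not ok and slope_re is not None:
        log.warning("random-slopes fit failed or singular; refitting intercept-only")
        fallback = True
        res = run("1")
    if res is None:
        raise DuoscaleError("mixed model failed to fit")
    return res, df, n_groups, fallback, formula


def _collect(res, spec: ModelSpec, n_groups: int, fallback: bool) -> dict[str, TermResult]:
    mods = set(spec.moderators)
    slopes = spec.random_structure == "intercept+slopes" and not fallback
    n_obs = int(res.nobs)
    k = len(res.fe_params)
    out = {}
    for term in res.fe_params.index:
        est = float(res.fe_params[term])
        se = float(res.bse_fe[term])
        uses_mod = any(m in term.split(":") for m in mods)
        dfe = (n_groups - 2) if (slopes or uses_mod) else max(n_obs - k, 1)
        t_ratio = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2 * stats.t.sf(abs(t_ratio), dfe))
        crit = float(stats.t.ppf(0.975, dfe))
        out[term] = TermResult(
            estimate=est,
            se=se,
            t_ratio=float(t_ratio),
            p_value=p,
            label=p_label(p),
            ci_low=est - crit * se,
            ci_high=est + crit * se,
        )
    return out


def fit_rating_model(
    records: pd.DataFrame, spec: ModelSpec, group_col: str = "participant"
) -> RegressionResult:
    """Fit a rating-accuracy mixed model on aligned rating records.

    Level-1 predictors (current, other-dimension and previous-epoch physical
    values) enter as fixed effects; each moderator enters as a main effect
    plus an interaction with every level-1 predictor.  Rows with undefined
    predictors (first-epoch ``previous_value``) are dropped.  A singular or
    failed random-slopes fit falls back to a random intercept, flagged on the
    result.
    """
    res, df, n_groups, fallback, _ = _fit_mixed(records, spec, group_col)
    return RegressionResult(
        coefficients=_collect(res, spec, n_groups, fallback),
        resid_var=float(res.scale),
        n_obs=int(res.nobs),
        n_groups=n_groups,
        outcome=spec.outcome,
        random_structure="intercept" if fallback else spec.random_structure,
        converged=bool(getattr(res, "converged", True)),
        fallback=fallback,
    )


def variance_explained(
    null_result: RegressionResult, full_result: RegressionResult
) -> float:
    """Proportional reduction in level-1 residual variance, floored at 0.

    ``(sigma2_null - sigma2_full) / sigma2_null`` — the "percentage of
    variance explained" statistic of the hierarchical-modelling tradition.
    """
    if null_result.outcome != full_result.outcome:
        raise DuoscaleError("models have different outcomes")
    if null_result.n_obs != full_result.n_obs:
        raise DuoscaleError("models were fit on different data")
    s0 = null_result.resid_var
    if s0 <= 0:
        return 0.0
    return max(0.0, (s0 - full_result.resid_var) / s0)


def fit_descriptor_model(
    responses: pd.DataFrame,
    spec: ModelSpec | None = None,
    modality: str | None = None,
    participant_meta: pd.DataFrame | None = None,
) -> RegressionResult:
    """Mixed model of magnitude-estimation responses on stimulus intensity.

    Responses are averaged across trials per cell first.  The outcome is the
    (trial-averaged) response value of one modality; the level-1 predictor is
    the stimulus intensity (line length, or descriptor reference rank);
    moderators such as ``stimulus_type`` and ``age_group`` enter as
    cross-level interactions.  ``participant_meta`` may supply per-participant
    columns (e.g. age_group) joined on ``participant``.
    """
    df = responses.copy()
    if modality is not None:
        df = df[df["modality"] == modality]
    if df.empty:
        raise DuoscaleError("no responses to model")
    if df["modality"].nunique() > 1:
        raise DuoscaleError("fit one modality at a time (pass modality=...)")
    keys = ["participant", "stimulus_type", "stimulus_intensity"]
    df = df.groupby(keys, sort=False, as_index=False)["value"].mean()
    if participant_meta is not None:
        df = df.merge(participant_meta, on="participant", how="left")
    if spec is None:
        # a moderator with a single observed level is a constant column
        mods = [
            m
            for m in ("stimulus_type", "age_group")
            if m in df.columns and df[m].nunique() > 1
        ]
        spec = ModelSpec(
            outcome="value",
            level1_predictors=("stimulus_intensity",),
            moderators=tuple(mods),
        )
    res, dfx, n_groups, fallback, _ = _fit_mixed(df, spec)
    return RegressionResult(
        coefficients=_collect(res, spec, n_groups, fallback),
        resid_var=float(res.scale),
        n_obs=int(res.nobs),
        n_groups=n_groups,
        outcome=spec.outcome,
        random_structure="intercept" if fallback else spec.random_structure,
        converged=bool(getattr(res, "converged", True)),
        fallback=fallback,
    )


def visual_model_spec(
    random_structure: str = "intercept", center: bool = True
) -> ModelSpec:
    """The rating-accuracy model of one visual dimension (age-moderated).

    Level-1 predictors are grand-mean centered by default, the usual
    hierarchical-modelling practice: it decorrelates the participant-level
    intercept from participant-level slopes, which matters for the standard
    errors when random slopes are estimated as independent components.
    """
    return ModelSpec(
        outcome="rating",
        level1_predictors=("current_value", "other_value", "previous_value"),
        moderators=("age_group",),
        random_structure=random_structure,
        center=center,
    )


def null_model_spec(outcome: str = "rating") -> ModelSpec:
    """Intercept-only baseline used for variance-explained comparisons."""
    return ModelSpec(outcome=outcome, level1_predictors=(), moderators=())
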