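"""Derived covariates: stress/fatigue composite, medication flags, total
sleep missed, two-process-model predicted lapses, and the lagged outcome.

The stress/fatigue composite collapses the seven 11-point self-ratings
(sleepiness, tiredness, mental fatigue, physical exhaustion, stress,
workload, sleep quality) into one score: a weighted average with weights
given by the loadings on the first principal component of the standardized
ratings, with the sign anchored so that higher composite = more stressed /
more tired.

The two-process sleep-regulation model supplies a biomathematical covariate:
homeostatic pressure S rises exponentially toward an upper asymptote during
wake and decays toward a lower asymptote during sleep, while a circadian
oscillator C (24-h fundamental plus harmonics of local time) modulates
alertness; predicted lapses are an affine map of (S − C), floored at zero.
Only reported bed/wake times feed it.  The classical time constants
(rise τ ≈ 18.2 h, decay τ ≈ 4.2 h) are defaults, not calibrated claims —
the covariate's role in the ensemble is relative, not absolute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import RATING_COLUMNS

__all__ = [
    "CompositeModel",
    "TwoProcessParams",
    "fit_composite",
    "composite_score",
    "medication_flags",
    "DEFAULT_MED_LEXICON",
    "total_sleep_missed",
    "two_process_s",
    "two_process_lapses",
    "lag_outcome",
    "derive",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# stress/fatigue composite (PCA)
# --------------------------------------------------------------------------


@dataclass(eq=False)
class CompositeModel:
    """First-principal-component weights over the self-rating scales."""

    loadings: pd.Series  # unit-norm PC1 loadings, anchored sign
    variance_explained: float
    sign_anchor: str
    means: pd.Series  # per-rating means used for standardization
    sds: pd.Series

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.to_dict(),
            "variance_explained": self.variance_explained,
            "sign_anchor": self.sign_anchor,
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
        }


def fit_composite(
    ratings: pd.DataFrame,
    *,
    anchor: str = "stressed",
    rating_columns: tuple[str, ...] = RATING_COLUMNS,
) -> CompositeModel:
    """PC1 of the standardized ratings, sign-anchored.

    Correlation-matrix PCA on pairwise-complete observations, so
    track-specific ratings (workload is asked only in the evening, sleep
    quality only in the morning) still enter the composite.  Constant
    columns are dropped with a warning.  Requires ≥ 8 usable observations.
    """
    cols = [c for c in rating_columns if c in ratings.columns]
    X = ratings[cols]
    if len(X.dropna(how="all")) < 8:
        raise ValueError("need at least 8 rating observations for PCA")
    sds = X.std(ddof=1)
    constant = sds[(sds == 0) | sds.isna()].index.tolist()
    if constant:
        warnings.warn(f"dropping constant rating columns: {constant}")
        cols = [c for c in cols if c not in constant]
        X = X[cols]
        sds = sds[cols]
    means = X.mean()
    corr = X.corr(min_periods=2).fillna(0.0).to_numpy()
    np.fill_diagonal(corr, 1.0)
    var, vecs = np.linalg.eigh(corr)
    var, vecs = var[::-1], vecs[:, ::-1]
    var = np.clip(var, 0.0, None)
    loadings = pd.Series(vecs[:, 0], index=cols)
    if anchor in loadings.index and loadings[anchor] < 0:
        loadings = -loadings
    elif anchor not in loadings.index and loadings.sum() < 0:
        loadings = -loadings
    return CompositeModel(
        loadings=loadings,
        variance_explained=float(var[0] / var.sum()),
        sign_anchor=anchor,
        means=means,
        sds=sds,
    )


def composite_score(model: CompositeModel, ratings: pd.DataFrame | pd.Series):
    """Score rows as the loadings-weighted average of the raw ratings.

    A row with some missing ratings is scored with weights renormalized over
    the observed ones; a row with none observed raises.
    """
    if isinstance(ratings, pd.Series):
        return float(composite_score(model, ratings.to_frame().T)[0])
    cols = model.loadings.index
    X = ratings.reindex(columns=cols).to_numpy(dtype=float)
    w = model.loadings.to_numpy()
    obs = ~np.isnan(X)
    if (~obs).all(axis=1).any():
        raise ValueError("row with all ratings missing cannot be scored")
    Xz = np.where(obs, X, 0.0)
    wsum = obs @ w
    if np.any(np.abs(wsum) < 1e-12):
        raise ValueError("observed-loading weights sum to ~0 for some row")
    return (Xz @ w) / wsum


# --------------------------------------------------------------------------
# medication flags
# --------------------------------------------------------------------------

DEFAULT_MED_LEXICON: dict[str, tuple[str, ...]] = {
    "pain": (
        "ibuprofen",
        "acetaminophen",
        "paracetamol",
        "aspirin",
        "naproxen",
        "tylenol",
        "advil",
        "motrin",
        "aleve",
    ),
    "sleep_aid": (
        "zolpidem",
        "ambien",
        "melatonin",
        "zaleplon",
        "sonata",
        "temazepam",
        "eszopiclone",
        "lunesta",
    ),
    "decongestant": (
        "pseudoephedrine",
        "sudafed",
        "phenylephrine",
        "oxymetazoline",
        "afrin",
    ),
    "antihistamine": (
        "loratadine",
        "claritin",
        "cetirizine",
        "zyrtec",
        "diphenhydramine",
        "benadryl",
        "fexofenadine",
        "allegra",
        "chlorpheniramine",
    ),
}

_NULL_RESPONSES = {"", "none", "decline to answer", "n/a", "na"}


def medication_flags(
    text: str | float | None,
    lexicon: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, bool]:
    """Map a free-text medication list to four class flags by
    case-insensitive keyword matching."""
    lexicon = lexicon or DEFAULT_MED_LEXICON
    flags = {k: False for k in lexicon}
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return flags
    t = str(text).strip().lower()
    if t in _NULL_RESPONSES:
        return flags
    matched_any = False
    for cls, words in lexicon.items():
        if any(w in t for w in words):
            flags[cls] = True
            matched_any = True
    if not matched_any:
        logger.info("unmatched medication text: %r", text)
    return flags


# --------------------------------------------------------------------------
# sleep
# --------------------------------------------------------------------------


def total_sleep_missed(
    latency_min: float, waso_min: float, time_in_bed_after_wake_min: float
) -> float:
    """Hours of the sleep opportunity not spent asleep: sleep-onset latency
    + wake after sleep onset + time in bed before getting up."""
    comps = (latency_min, waso_min, time_in_bed_after_wake_min)
    if any(c < 0 for c in comps):
        raise ValueError("sleep components must be nonnegative")
    return float(sum(comps)) / 60.0


# --------------------------------------------------------------------------
# two-process model
# --------------------------------------------------------------------------


@dataclass
class TwoProcessParams:
    """Two-process sleep-regulation parameters.

    Homeostat: exponential rise toward ``s_upper`` with time constant
    ``tau_wake`` (hours) during wake, exponential decay toward ``s_lower``
    with ``tau_sleep`` during sleep.  Circadian: amplitude × (fundamental +
    harmonics) cosine series of local clock time with ``period`` 24 h and
    acrophase ``phase_h``.  Predicted lapses = max(0, lapse_intercept +
    lapse_slope·(S − C)).
    """

    tau_wake: float = 18.2
    tau_sleep: float = 4.2
    s_upper: float = 1.0
    s_lower: float = 0.0
    circadian_amplitude: float = 0.1
    phase_h: float = 16.8
    period_h: float = 24.0
    harmonics: tuple[float, ...] = (1.0, 0.3)
    lapse_intercept: float = 2.0
    lapse_slope: float = 15.0

    def validate(self) -> None:
        if self.tau_wake <= 0 or self.tau_sleep <= 0:
            raise ValueError("time constants must be positive")
        if self.s_lower >= self.s_upper:
            raise ValueError("s_lower must be below s_upper")
        if self.period_h <= 0:
            raise ValueError("period must be positive")


def _circadian(params: TwoProcessParams, clock_hours: float) -> float:
    w = 2.0 * np.pi / params.period_h
    c = sum(
        a * np.cos((m + 1) * w * (clock_hours - params.phase_h))
        for m, a in enumerate(params.harmonics)
    )
    return params.circadian_amplitude * c


def two_process_s(
    sleep_episodes: list[tuple[pd.Timestamp, pd.Timestamp]],
    eval_time: pd.Timestamp,
    params: TwoProcessParams | None = None,
    s0: float = 0.5,
) -> float:
    """Homeostatic pressure S at ``eval_time`` given past sleep episodes.

    Episodes are (bedtime, waketime), non-overlapping; the trajectory is
    propagated with exact piecewise-exponential segments (wake between
    episodes, sleep within) starting ``s0`` at the first bedtime minus a
    standard 16-h wake block.
    """
    params = params or TwoProcessParams()
    params.validate()
    eps = sorted(sleep_episodes, key=lambda e: e[0])
    for (b1, w1), (b2, _) in zip(eps, eps[1:]):
        if b2 < w1:
            raise ValueError("overlapping sleep episodes")
    for b, w in eps:
        if w <= b:
            raise ValueError("waketime must follow bedtime")
    eps = [e for e in eps if e[0] < eval_time]
    if not eps:
        raise ValueError("no completed sleep episode before eval_time")

    def wake(s: float, dt_h: float) -> float:
        return params.s_upper + (s - params.s_upper) * np.exp(-dt_h / params.tau_wake)

    def sleep(s: float, dt_h: float) -> float:
        return params.s_lower + (s - params.s_lower) * np.exp(-dt_h / params.tau_sleep)

    t = eps[0][0] - pd.Timedelta(hours=16.0)
    s = wake(s0, 16.0)  # arrive at first bedtime after a standard wake day
    t = eps[0][0]
    for bed, wk in eps:
        if bed > t:  # wake gap before this episode
            if bed >= eval_time:
                return wake(s, (eval_time - t).total_seconds() / 3600.0)
            s = wake(s, (bed - t).total_seconds() / 3600.0)
            t = bed
        end = min(wk, eval_time)
        if end > t:
            s = sleep(s, (end - t).total_seconds() / 3600.0)
            t = end
        if t >= eval_time:
            return s
    if eval_time > t:
        s = wake(s, (eval_time - t).total_seconds() / 3600.0)
    return s


def two_process_lapses(
    sleep_episodes: list[tuple[pd.Timestamp, pd.Timestamp]],
    eval_time: pd.Timestamp,
    params: TwoProcessParams | None = None,
    s0: float = 0.5,
) -> float:
    """Predicted lapse count at ``eval_time``: affine in (S − C), floored at 0."""
    params = params or TwoProcessParams()
    s = two_process_s(sleep_episodes, eval_time, params, s0)
    clock = eval_time.hour + eval_time.minute / 60.0 + eval_time.second / 3600.0
    c = _circadian(params, clock)
    return float(max(0.0, params.lapse_intercept + params.lapse_slope * (s - c)))


def _predicted_lapses_column(
    df: pd.DataFrame, params: TwoProcessParams | None = None
) -> tuple[pd.Series, pd.Series]:
    """Per-row predicted lapses from diary bed/wake times (already LOCF'd).

    Participants with no usable sleep data get the cohort mean, flagged
    ``imputed-mean``.
    """
    params = params or TwoProcessParams()
    out = np.full(len(df), np.nan)
    src = np.full(len(df), "missing", dtype=object)
    for pid, grp in df.groupby("participant"):
        eps = []
        vals = {}
        for ridx, row in grp.iterrows():
            b, w = row.get("bedtime"), row.get("waketime")
            if pd.notna(b) and pd.notna(w) and w > b:
                if not eps or b >= eps[-1][1]:
                    eps.append((b, w))
            if eps:
                try:
                    vals[ridx] = two_process_lapses(eps, row["timestamp"], params)
                except ValueError:
                    pass
        for ridx, v in vals.items():
            out[df.index.get_loc(ridx)] = v
            src[df.index.get_loc(ridx)] = "observed"
    m = np.nanmean(out) if np.isfinite(out).any() else 0.0
    missing = ~np.isfinite(out)
    out[missing] = m
    src[missing] = "imputed-mean"
    return pd.Series(out, index=df.index), pd.Series(src, index=df.index)


# --------------------------------------------------------------------------
# lagged outcome
# --------------------------------------------------------------------------


def lag_outcome(
    df: pd.DataFrame,
    outcome: str = "lrm50",
    *,
    preflight_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Attach each participant's most recent previous outcome as
    ``<outcome>_lag``.

    Rows must be time-sorted within participant.  The first observation's
    lag is imputed with the participant's pre-flight mean when available,
    else the cohort mean of the outcome; a ``<outcome>_lag_src`` column
    flags ``observed`` vs ``imputed``.
    """
    if not df.groupby("participant")["timestamp"].apply(
        lambda s: s.is_monotonic_increasing
    ).all():
        raise ValueError("rows must be time-sorted within participant")
    out = df.copy()
    lag = out.groupby("participant")[outcome].shift(1)
    src = np.where(lag.notna(), "observed", "imputed")
    cohort_mean = out[outcome].mean()
    fill = out["participant"].map(preflight_means or {}).fillna(cohort_mean)
    out[f"{outcome}_lag"] = lag.fillna(fill)
    out[f"{outcome}_lag_src"] = src
    return out


# --------------------------------------------------------------------------
# one-stop derivation
# --------------------------------------------------------------------------


def derive(
    fused: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    *,
    composite: CompositeModel | None = None,
    two_process: TwoProcessParams | None = None,
    outcome: str = "lrm50",
    preflight_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Add every derived covariate to a fused table.

    Produces ``stress_fatigue``, the four medication flags, the caffeine
    dose count, ``total_sleep_missed_h``, ``pred_lapses`` (+ provenance),
    ``<outcome>_lag`` and, when demographics are given, person-level
    ``age``, ``sex_male``, ``preflight_ops`` plus ``track_evening``.
    """
    df = fused.sort_values(["participant", "timestamp"]).reset_index(drop=True).copy()
    model = composite or fit_composite(df)
    df["stress_fatigue"] = composite_score(model, df)

    meds = df.get("meds_text", pd.Series([""] * len(df)))
    flag_rows = [medication_flags(t) for t in meds]
    for cls in DEFAULT_MED_LEXICON:
        df[f"med_{cls}"] = [float(r[cls]) for r in flag_rows]

    for c in ("sleep_latency_min", "waso_min", "time_in_bed_after_wake_min"):
        if c not in df.columns:
            df[c] = 0.0
    comp = df[
        ["sleep_latency_min", "waso_min", "time_in_bed_after_wake_min"]
    ].fillna(0.0)
    df["total_sleep_missed_h"] = comp.sum(axis=1) / 60.0

    lapses, lapses_src = _predicted_lapses_column(df, two_process)
    df["pred_lapses"] = lapses
    df["pred_lapses_src"] = lapses_src

    if outcome in df.columns:
        df = lag_outcome(df, outcome, preflight_means=preflight_means)

    if demographics is not None:
        demo = demographics.set_index("participant")
        df["age"] = df["participant"].map(demo["age"])
        df["sex_male"] = (df["participant"].map(demo["sex"]) == "M").astype(float)
        df["preflight_ops"] = df["participant"].map(demo["preflight_ops"])
    if "track" in df.columns:
        df["track_evening"] = (df["track"] == "evening").astype(float)
    df.attrs["composite_model"] = model
    return df
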