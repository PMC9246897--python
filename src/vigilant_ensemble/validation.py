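"""Forward-chaining cross-validation and error aggregation.

For participant *i* with ``n_i`` observations, a training length ``t`` drawn
from a grid ({5, 10, …, 50} by default) and a window shift ``k``, a model is
trained on the target participant's observations ``k … k+t−1`` (a partial
time series of length ``t``) *plus all other participants' full series*,
then evaluated on the target's subsequent observation(s).  Incrementing
``t`` grows the training set; incrementing ``k`` slides it forward in
mission time, so the model is trained and tested at different mission
phases.  The nominal number of shifts is the study's printed formula
``N_{i,t} = min(20, n_i − t + 1)``; shifts whose test observation would lie
beyond the participant's series are dropped (and counted), so every emitted
window has its full test horizon.

Errors aggregate on three levels, weighting participants equally regardless
of how many windows they contribute:

* ``MSE(i,t)`` — mean squared test error over shifts ``k`` for one person;
* ``MSE(t)`` — unweighted mean of ``MSE(i,t)`` over participants;
* ``MSE_overall`` — mean of ``MSE(t)`` over the t-grid.

``MAE(i,t)`` is the *median* absolute error over shifts (robust to outcome
spikes).  Training error follows the same shape but also averages over the
``t`` training observations in the window (squared by default; a
``literal`` flag reproduces the unsquared printed form).  ``RMSE(t)/sd(y)``
standardizes error by the outcome's spread.

Also provided: chained individualized prediction — refit on all of a
participant's history plus everyone else's full data at each step — with
participant-level bootstrap interquartile bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .models import fit_ensemble, fit_fcm, fit_lme, fit_rf

__all__ = [
    "Window",
    "ErrorSummary",
    "n_shifts",
    "make_windows",
    "audit_windows",
    "run_forward_chain",
    "aggregate_errors",
    "run_horizon_sweep",
    "chained_prediction",
    "DEFAULT_T_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_T_GRID = tuple(range(5, 55, 5))


@dataclass(frozen=True)
class Window:
    """One forward-chaining evaluation window (1-based positions)."""

    participant: str
    t: int
    k: int
    train_positions: tuple[int, ...]  # target participant's training obs
    test_positions: tuple[int, ...]  # the following horizon obs

    def __post_init__(self):
        if set(self.train_positions) & set(self.test_positions):
            raise ValueError("train/test positions overlap")


def n_shifts(n_i: int, t: int, max_shifts: int = 20) -> int:
    """The study's nominal window-shift count: min(max_shifts, n_i − t + 1)."""
    return min(max_shifts, n_i - t + 1)


def make_windows(
    n_obs: Mapping[str, int],
    t_grid: tuple[int, ...] = DEFAULT_T_GRID,
    *,
    max_shifts: int = 20,
    horizon: int = 1,
    allow_partial_horizon: bool = False,
) -> list[Window]:
    """Enumerate every admissible (participant, t, k) window exactly once.

    ``(i, t)`` pairs with no admissible shift are skipped and logged, as are
    nominal shifts whose (full) test horizon would run past the series.
    With ``allow_partial_horizon`` a window is kept as long as at least one
    test observation exists (used by the horizon sweep).
    """
    if not t_grid:
        raise ValueError("empty training-length grid")
    windows: list[Window] = []
    n_dropped = 0
    for pid, n_i in n_obs.items():
        for t in t_grid:
            if n_i < t + 1:
                logger.debug("skip (%s, t=%d): series too short (n=%d)", pid, t, n_i)
                continue
            emitted = 0
            for k in range(1, n_shifts(n_i, t, max_shifts) + 1):
                first_test = k + t
                last_test = min(k + t + horizon - 1, n_i)
                if first_test > n_i or (
                    not allow_partial_horizon and k + t + horizon - 1 > n_i
                ):
                    n_dropped += 1
                    continue
                windows.append(
                    Window(
                        participant=pid,
                        t=t,
                        k=k,
                        train_positions=tuple(range(k, k + t)),
                        test_positions=tuple(range(first_test, last_test + 1)),
                    )
                )
                emitted += 1
            if emitted == 0:
                logger.debug("skip (%s, t=%d): no admissible shift", pid, t)
    if n_dropped:
        logger.info("dropped %d nominal shifts lacking a test horizon", n_dropped)
    return windows


def audit_windows(windows: list[Window], n_obs: Mapping[str, int]) -> dict:
    """Programmatic leakage audit.

    Checks, for every window: train/test disjoint; test strictly after the
    training window; positions within the participant's series.  Returns a
    report dict; raises AssertionError on violation.
    """
    n_checked = 0
    for w in windows:
        train, test = set(w.train_positions), set(w.test_positions)
        assert not (train & test), f"train/test overlap in {w}"
        assert min(test) > max(train), f"test not after training window in {w}"
        assert max(test) <= n_obs[w.participant], f"test beyond series in {w}"
        assert min(train) >= 1, f"bad train position in {w}"
        # no future observation of the target participant enters training
        assert all(p < min(test) for p in w.train_positions), f"future leak in {w}"
        n_checked += 1
    return {"n_windows": n_checked, "violations": 0}


def _window_seed(master: int, index: int) -> int:
    return int(
        np.random.SeedSequence(entropy=master, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


def _make_fitter(model_spec, covariates, outcome, fit_kwargs):
    """Turn a model spec into fit(train_df, seed) -> predictor."""
    if callable(model_spec):
        return model_spec
    kw = dict(fit_kwargs or {})
    if model_spec == "lme":
        return lambda d, seed: fit_lme(d, covariates, outcome, **kw)
    if model_spec == "rf":
        return lambda d, seed: fit_rf(d, covariates, outcome, seed=seed, **kw)
    if model_spec == "fcm":
        return lambda d, seed: fit_fcm(d, covariates, outcome, **kw)
    if model_spec == "ensemble":
        return lambda d, seed: fit_ensemble(d, covariates, outcome, seed=seed, **kw)
    raise ValueError(f"unknown model spec {model_spec!r}")


def run_forward_chain(
    df: pd.DataFrame,
    model_spec,
    windows: list[Window],
    covariates: list[str] | None = None,
    outcome: str = "lrm50",
    *,
    seed: int = 0,
    fit_kwargs: dict | None = None,
    record_train: bool = True,
) -> pd.DataFrame:
    """Refit-and-predict over every window; returns the cell table.

    ``model_spec`` is ``"lme" | "rf" | "fcm" | "ensemble"`` or a callable
    ``(train_df, seed) -> predictor`` (any object with
    ``.predict(df) -> array``), which lets tests plug in stubs.  Cells carry
    participant, t, k, horizon index h, observed y, prediction, and the
    squared/absolute errors; training-set predictions are recorded with
    ``set == "train"`` for the training-error summaries.  Window fit
    failures are logged, counted in ``cells.attrs['n_failed']`` and
    excluded.
    """
    df = df.sort_values(["participant", "timestamp"]).reset_index(drop=True)
    pos = {
        pid: idx for pid, idx in df.groupby("participant").indices.items()
    }  # row positions per participant, time-ordered
    fitter = _make_fitter(model_spec, covariates, outcome, fit_kwargs)

    records = []
    n_failed = 0
    for w_idx, w in enumerate(windows):
        idx_i = pos[w.participant]
        train_self = idx_i[[p - 1 for p in w.train_positions]]
        test_self = idx_i[[p - 1 for p in w.test_positions]]
        others = np.concatenate(
            [idx for pid, idx in pos.items() if pid != w.participant]
        ) if len(pos) > 1 else np.array([], dtype=int)
        train_idx = np.concatenate([others, train_self])
        train_df = df.iloc[train_idx]
        test_df = df.iloc[test_self]
        wseed = _window_seed(seed, w_idx)
        try:
            model = fitter(train_df, wseed)
            yhat_test = np.asarray(model.predict(test_df), dtype=float)
            yhat_train = (
                np.asarray(model.predict(df.iloc[train_self]), dtype=float)
                if record_train
                else None
            )
        except Exception as exc:  # noqa: BLE001 - window failures are data
            logger.warning("window fit failed (%s): %s", w, exc)
            n_failed += 1
            continue
        y_test = test_df[outcome].to_numpy(dtype=float)
        for h, (yt, yh) in enumerate(zip(y_test, yhat_test), start=1):
            records.append(
                {
                    "participant": w.participant,
                    "t": w.t,
                    "k": w.k,
                    "h": h,
                    "set": "test",
                    "y": yt,
                    "yhat": yh,
                }
            )
        if yhat_train is not None:
            y_tr = df.iloc[train_self][outcome].to_numpy(dtype=float)
            for j, (yt, yh) in enumerate(zip(y_tr, yhat_train), start=1):
                records.append(
                    {
                        "participant": w.participant,
                        "t": w.t,
                        "k": w.k,
                        "h": j,
                        "set": "train",
                        "y": yt,
                        "yhat": yh,
                    }
                )
    cells = pd.DataFrame(
        records, columns=["participant", "t", "k", "h", "set", "y", "yhat"]
    )
    cells["squared_error"] = (cells["y"] - cells["yhat"]) ** 2
    cells["absolute_error"] = (cells["y"] - cells["yhat"]).abs()
    cells.attrs["n_failed"] = n_failed
    return cells


@dataclass
class ErrorSummary:
    """Multi-level forward-chaining error summary."""

    mse_it: pd.DataFrame  # columns participant, t, mse
    mse_t: pd.Series  # index t
    mse_overall: float
    mae_it: pd.DataFrame
    mae_t: pd.Series
    mae_overall: float
    mse_train_it: pd.DataFrame | None
    rmse_over_sd_t: pd.Series
    sd_y: float
    n_cells: int


def aggregate_errors(
    cells: pd.DataFrame, *, literal_train: bool = False
) -> ErrorSummary:
    """Aggregate cell errors into the study's nested summaries.

    MSE(i,t) = mean over shifts k of squared test error; MSE(t) = unweighted
    mean over participants; MSE_overall = mean over the t-grid.  MAE(i,t) is
    the median absolute error over shifts.  Training error divides the
    per-(i,t) sum over shifts *and* window positions by the number of
    shifts; ``literal_train`` reproduces the unsquared variant.
    """
    test = cells[cells["set"] == "test"]
    if test.empty:
        raise ValueError("no test cells to aggregate")
    mse_it = (
        test.groupby(["participant", "t"])["squared_error"].mean().rename("mse")
    ).reset_index()
    mse_t = mse_it.groupby("t")["mse"].mean()
    mse_overall = float(mse_t.mean())
    mae_it = (
        test.groupby(["participant", "t"])["absolute_error"].median().rename("mae")
    ).reset_index()
    mae_t = mae_it.groupby("t")["mae"].mean()
    mae_overall = float(mae_t.mean())

    train = cells[cells["set"] == "train"]
    mse_train_it = None
    if not train.empty:
        def _train_err(g: pd.DataFrame) -> float:
            n_k = g["k"].nunique()
            resid = (
                g["y"] - g["yhat"] if literal_train else g["squared_error"]
            )
            return float(resid.sum() / n_k)

        mse_train_it = (
            train.groupby(["participant", "t"])
            .apply(_train_err, include_groups=False)
            .rename("mse_train")
            .reset_index()
        )

    sd_y = float(test["y"].std(ddof=1)) if len(test) > 1 else float("nan")
    rmse_over_sd_t = np.sqrt(mse_t) / sd_y
    return ErrorSummary(
        mse_it=mse_it,
        mse_t=mse_t,
        mse_overall=mse_overall,
        mae_it=mae_it,
        mae_t=mae_t,
        mae_overall=mae_overall,
        mse_train_it=mse_train_it,
        rmse_over_sd_t=rmse_over_sd_t,
        sd_y=sd_y,
        n_cells=int(len(test)),
    )


def run_horizon_sweep(
    df: pd.DataFrame,
    model_spec,
    covariates: list[str] | None = None,
    outcome: str = "lrm50",
    *,
    horizons: tuple[int, ...] = tuple(range(1, 8)),
    t_grid: tuple[int, ...] = DEFAULT_T_GRID,
    max_shifts: int = 20,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> dict[int, ErrorSummary]:
    """One error summary per prediction horizon (h-th-ahead observation).

    A single forward-chaining pass is run at the maximum horizon with
    partial test spans allowed; horizon h's summary then uses only the
    h-th-ahead test cells from windows long enough to contain them.
    """
    h_max = max(horizons)
    n_obs = df.groupby("participant").size().to_dict()
    windows = make_windows(
        n_obs, t_grid, max_shifts=max_shifts, horizon=h_max,
        allow_partial_horizon=True,
    )
    cells = run_forward_chain(
        df, model_spec, windows, covariates, outcome,
        seed=seed, fit_kwargs=fit_kwargs, record_train=False,
    )
    out = {}
    test = cells[cells["set"] == "test"]
    for h in horizons:
        sub = test[test["h"] == h]
        if sub.empty:
            logger.info("horizon %d: no admissible cells", h)
            continue
        out[h] = aggregate_errors(sub)
    return out


def chained_prediction(
    df: pd.DataFrame,
    participant: str,
    model_spec,
    covariates: list[str] | None = None,
    outcome: str = "lrm50",
    *,
    n_bootstrap: int = 100,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Chained refit-and-predict for one participant with bootstrap bands.

    At each observation j ≥ 2 the model is refit on the participant's
    observations 1..j−1 plus all other participants' full series, and
    predicts observation j.  Sampling variability is estimated by
    bootstrapping the *other* participants (entire series with replacement;
    the target's prior data enters each resample exactly once) and taking
    the interquartile range of the bootstrap predictions.  Returns the
    chain table and a manifest with the per-draw resample composition and
    the chain RMSE.
    """
    df = df.sort_values(["participant", "timestamp"]).reset_index(drop=True)
    pos = {pid: idx for pid, idx in df.groupby("participant").indices.items()}
    if participant not in pos:
        raise ValueError(f"unknown participant {participant!r}")
    idx_i = pos[participant]
    if len(idx_i) < 2:
        raise ValueError("participant needs at least 2 observations")
    others = [pid for pid in pos if pid != participant]
    fitter = _make_fitter(model_spec, covariates, outcome, fit_kwargs)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    draws = [list(rng.choice(others, size=len(others), replace=True))
             for _ in range(n_bootstrap)] if others else [[]] * n_bootstrap

    rows = []
    for j in range(2, len(idx_i) + 1):
        prior_self = idx_i[: j - 1]
        target = df.iloc[[idx_i[j - 1]]]
        base_idx = (
            np.concatenate([np.concatenate([pos[p] for p in others]), prior_self])
            if others
            else prior_self
        )
        model = fitter(df.iloc[base_idx], _window_seed(seed, j))
        yhat = float(np.asarray(model.predict(target))[0])
        boots = []
        for b, comp in enumerate(draws):
            # target's prior data enters exactly once; duplicated resampled
            # participants are relabelled so they stay distinct grouping units
            parts = [df.iloc[prior_self]]
            seen: dict[str, int] = {}
            for p in comp:
                seen[p] = seen.get(p, 0) + 1
                block = df.iloc[pos[p]]
                if seen[p] > 1:
                    block = block.copy()
                    block["participant"] = f"{p}__b{seen[p]}"
                parts.append(block)
            bdf = pd.concat(parts, ignore_index=True)
            bm = fitter(bdf, _window_seed(seed, 10_000 + b * 1000 + j))
            boots.append(float(np.asarray(bm.predict(target))[0]))
        q25, q75 = (
            np.percentile(boots, [25, 75]) if boots else (yhat, yhat)
        )
        rows.append(
            {
                "position": j,
                "timestamp": target["timestamp"].iloc[0]
                if "timestamp" in target.columns
                else j,
                "mission_frac": target.get("mission_frac", pd.Series([np.nan])).iloc[0],
                "y": float(target[outcome].iloc[0]),
                "yhat": yhat,
                "q25": float(q25),
                "q75": float(q75),
            }
        )
    chain = pd.DataFrame(rows)
    rmse = float(np.sqrt(np.mean((chain["y"] - chain["yhat"]) ** 2)))
    manifest = {
        "participant": participant,
        "n_bootstrap": n_bootstrap,
        "resamples": draws,
        "rmse": rmse,
    }
    return chain, manifest
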