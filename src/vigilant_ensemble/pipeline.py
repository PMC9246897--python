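"""End-to-end orchestration: simulate → fuse → derive → fit → validate →
rank → report, as one seeded, manifest-tracked run.

The run writes CSV stage outputs, static PNG report figures (error-vs-
training-length curves, an effect heatmap, the importance chart, a chained-
prediction trace) and a JSON manifest with the config hash, master seed and
per-file digests, so every number in the report is traceable to a stage
output.  ``toggle_predict`` answers "what if": a single ensemble prediction
for one participant with chosen covariates overridden (others held at that
participant's averages), placed against the participant's own score
distribution with worst-15% / best-15% bands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .fusion import fuse
from .importance import select_top, top10_rate
from .models import EnsembleFit, effect_heatmap, fit_ensemble
from .predictors import derive
from .synthetic_data import CohortConfig, simulate
from .validation import (
    DEFAULT_T_GRID,
    aggregate_errors,
    chained_prediction,
    make_windows,
    run_forward_chain,
)

__all__ = ["DEFAULT_COVARIATES", "run_full_analysis", "toggle_predict"]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = [
    "lrm50_lag",
    "stress_fatigue",
    "temperature",
    "co2",
    "o2",
    "radiation",
    "noise",
    "occupancy",
    "caffeine_doses",
    "total_sleep_missed_h",
    "pred_lapses",
    "age",
    "preflight_ops",
    "sex_male",
    "track_evening",
    "med_pain",
    "med_sleep_aid",
    "med_decongestant",
    "med_antihistamine",
]


def usable_covariates(df: pd.DataFrame, candidates: list[str] | None = None) -> list[str]:
    """Candidates that exist, are complete, non-constant and not collinear
    with the covariates already kept (greedy rank check with intercept)."""
    candidates = candidates or DEFAULT_COVARIATES
    out: list[str] = []
    basis = [np.ones(len(df))]
    for c in candidates:
        if c not in df.columns:
            continue
        col = df[c]
        if col.isna().any() or col.nunique() < 2:
            continue
        x = col.to_numpy(dtype=float)
        z = (x - x.mean()) / x.std()  # scale-free rank test
        trial = np.column_stack(basis + [z])
        if np.linalg.matrix_rank(trial) <= len(basis):
            continue
        basis.append(z)
        out.append(c)
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_full_analysis(
    config: dict | None = None,
    out_dir: str = "run_out",
    *,
    seed: int | None = None,
    make_plots: bool = True,
) -> dict:
    """Execute the whole analysis on a synthetic cohort; returns the manifest.

    ``config`` keys (all optional): ``cohort`` (generator fields), ``covariates``,
    ``cv`` (``t_grid``, ``max_shifts``, ``models``, ``rf_trees``),
    ``importance`` (``n_draws``, ``frac``, ``n_trees``), ``chained``
    (``participant``, ``n_bootstrap``).  A stage failure halts the run with
    the stage name; completed stages stay on disk.
    """
    config = dict(config or {})
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _hash_config(config),
        "stages": {},
        "warnings": {},
    }
    cohort_cfg = CohortConfig(**config.get("cohort", {}))
    if seed is not None:
        cohort_cfg.seed = int(seed)
    manifest["master_seed"] = cohort_cfg.seed

    def _stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"started": time.time()}

    def _done(name, files):
        st = manifest["stages"][name]
        st["seconds"] = round(time.time() - st.pop("started"), 2)
        st["outputs"] = {os.path.basename(f): _sha256(f) for f in files}

    # 1. simulate ----------------------------------------------------------
    _stage("simulate")
    cohort = simulate(cohort_cfg)
    paths = cohort.write_csv(out_dir)
    _done("simulate", list(paths.values()))

    # 2. fuse --------------------------------------------------------------
    _stage("fuse")
    fused = fuse(cohort.rst, cohort.env_streams)
    fused_path = os.path.join(out_dir, "fused.csv")
    fused.to_csv(fused_path, index=False)
    manifest["warnings"]["fuse_excluded_rows"] = fused.attrs.get("n_excluded", 0)
    _done("fuse", [fused_path])

    # 3. derive ------------------------------------------------------------
    _stage("derive")
    derived = derive(fused, cohort.demographics)
    derived_path = os.path.join(out_dir, "fused_plus.csv")
    derived.to_csv(derived_path, index=False)
    _done("derive", [derived_path])

    covariates = config.get("covariates") or usable_covariates(derived)

    # 4. fit full-data ensemble -------------------------------------------
    _stage("fit")
    cv_cfg = dict(config.get("cv", {}))
    rf_trees = int(cv_cfg.get("rf_trees", 200))
    bundle = fit_ensemble(
        derived, covariates, seed=cohort_cfg.seed,
        rf_kwargs={"n_trees": rf_trees},
    )
    fit_meta = os.path.join(out_dir, "model_meta.json")
    with open(fit_meta, "w") as fh:
        json.dump(
            {
                "covariates": covariates,
                "lme": {
                    "beta0": bundle.lme.beta0,
                    "beta": bundle.lme.beta.to_dict(),
                    "rho": bundle.lme.rho,
                    "sigma_person": bundle.lme.sigma_person,
                    "sigma": bundle.lme.sigma,
                },
                "rf": {"n_trees": rf_trees, "oob_score": bundle.rf.oob_score},
                "fcm": {"lam_f": bundle.fcm.lam_f, "lam_b": bundle.fcm.lam_b,
                        "gcv": bundle.fcm.gcv},
            },
            fh,
            indent=2,
        )
    _done("fit", [fit_meta])

    # 5. validate ----------------------------------------------------------
    _stage("validate")
    t_grid = tuple(cv_cfg.get("t_grid", DEFAULT_T_GRID))
    max_shifts = int(cv_cfg.get("max_shifts", 20))
    model_names = list(cv_cfg.get("models", ["lme", "rf", "fcm"]))
    n_obs = derived.groupby("participant").size().to_dict()
    windows = make_windows(n_obs, t_grid, max_shifts=max_shifts)
    summaries = {}
    cell_frames = {}
    for name in model_names:
        fit_kwargs = None
        if name == "rf":
            fit_kwargs = {"n_trees": rf_trees}
        elif name == "lme":
            fit_kwargs = {"drop_collinear": True}
        elif name == "ensemble":
            fit_kwargs = {
                "rf_kwargs": {"n_trees": rf_trees},
                "lme_kwargs": {"drop_collinear": True},
            }
        cells = run_forward_chain(
            derived, name, windows, covariates,
            seed=cohort_cfg.seed, fit_kwargs=fit_kwargs,
        )
        cell_frames[name] = cells
        summaries[name] = aggregate_errors(cells)
    if "ensemble" not in summaries and set(model_names) >= {"lme", "rf", "fcm"}:
        # exact by the equal-weight identity: average component predictions
        ens = cell_frames["lme"].copy()
        ens["yhat"] = (
            cell_frames["lme"]["yhat"]
            + cell_frames["rf"]["yhat"]
            + cell_frames["fcm"]["yhat"]
        ) / 3.0
        ens["squared_error"] = (ens["y"] - ens["yhat"]) ** 2
        ens["absolute_error"] = (ens["y"] - ens["yhat"]).abs()
        cell_frames["ensemble"] = ens
        summaries["ensemble"] = aggregate_errors(ens)
    cv_files = []
    mse_rows = []
    for name, cells in cell_frames.items():
        p = os.path.join(out_dir, f"cv_cells_{name}.csv")
        cells.to_csv(p, index=False)
        cv_files.append(p)
        s = summaries[name]
        for t, v in s.mse_t.items():
            mse_rows.append({"model": name, "t": t, "mse": v,
                             "rmse_over_sd": s.rmse_over_sd_t[t]})
        mse_rows.append({"model": name, "t": "overall", "mse": s.mse_overall,
                         "rmse_over_sd": np.sqrt(s.mse_overall) / s.sd_y})
    mse_path = os.path.join(out_dir, "cv_summary.csv")
    pd.DataFrame(mse_rows).to_csv(mse_path, index=False)
    cv_files.append(mse_path)
    _done("validate", cv_files)

    # 6. rank --------------------------------------------------------------
    _stage("rank")
    imp_cfg = dict(config.get("importance", {}))
    table = top10_rate(
        derived,
        covariates,
        n_draws=int(imp_cfg.get("n_draws", 100)),
        frac=float(imp_cfg.get("frac", 0.5)),
        n_trees=int(imp_cfg.get("n_trees", 100)),
        seed=cohort_cfg.seed,
    )
    imp_path = os.path.join(out_dir, "importance.csv")
    table.to_csv(imp_path)
    manifest["top10_variables"] = select_top(table)
    _done("rank", [imp_path])

    # 7. chained prediction -------------------------------------------------
    ch_cfg = dict(config.get("chained", {}))
    chain = None
    if ch_cfg.get("enabled", True):
        _stage("chained")
        pid = ch_cfg.get("participant") or sorted(n_obs)[0]
        chain, ch_manifest = chained_prediction(
            derived, pid, "lme", covariates,
            n_bootstrap=int(ch_cfg.get("n_bootstrap", 20)),
            seed=cohort_cfg.seed,
            fit_kwargs={"drop_collinear": True},
        )
        chain_path = os.path.join(out_dir, "chained_prediction.csv")
        chain.to_csv(chain_path, index=False)
        manifest["chained_rmse"] = ch_manifest["rmse"]
        _done("chained", [chain_path])

    # 8. report figures -----------------------------------------------------
    if make_plots:
        _stage("report")
        figs = _make_figures(out_dir, summaries, bundle, derived, table, chain)
        _done("report", figs)

    manifest["mse_overall"] = {m: s.mse_overall for m, s in summaries.items()}
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _make_figures(out_dir, summaries, bundle, derived, imp_table, chain):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = []

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, s in summaries.items():
        ax.plot(s.mse_t.index, s.mse_t.values, marker="o", label=name)
    ax.set_xlabel("training length t (observations)")
    ax.set_ylabel("MSE(t)")
    ax.set_title("Forward-chaining test error (synthetic cohort)")
    ax.legend()
    p = os.path.join(out_dir, "fig_mse_vs_t.png")
    fig.tight_layout()
    fig.savefig(p, dpi=100)
    plt.close(fig)
    files.append(p)

    # effect heatmap for the first continuous environmental covariate
    for cov in ("temperature", "co2", "radiation"):
        if cov in bundle.fcm.covariates:
            M, xg, tg = effect_heatmap(bundle.fcm, cov, derived)
            fig, ax = plt.subplots(figsize=(5.5, 4))
            im = ax.pcolormesh(tg, xg, M, shading="auto", cmap="viridis")
            fig.colorbar(im, ax=ax, label="predicted LRM-50")
            ax.set_xlabel("mission fraction")
            ax.set_ylabel(cov)
            ax.set_title(f"Time-varying effect surface: {cov} (synthetic)")
            p = os.path.join(out_dir, f"fig_heatmap_{cov}.png")
            fig.tight_layout()
            fig.savefig(p, dpi=100)
            plt.close(fig)
            files.append(p)
            break

    t = imp_table.table.sort_values("top10_rate")
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(t) + 1.5))
    ax.barh(t["variable"], t["top10_rate"], color="seagreen")
    ax.set_xlabel("Top-10 Rate")
    ax.set_title("Variable importance stability (synthetic)")
    p = os.path.join(out_dir, "fig_importance.png")
    fig.tight_layout()
    fig.savefig(p, dpi=100)
    plt.close(fig)
    files.append(p)

    if chain is not None and len(chain):
        fig, ax = plt.subplots(figsize=(6, 4))
        lower = np.clip(chain["yhat"] - chain["q25"], 0, None)
        upper = np.clip(chain["q75"] - chain["yhat"], 0, None)
        ax.errorbar(
            chain["mission_frac"], chain["yhat"], yerr=[lower, upper],
            fmt="-", color="seagreen", label="chained prediction (IQR)",
        )
        ax.plot(chain["mission_frac"], chain["y"], "o", mfc="none",
                color="goldenrod", label="observed")
        ax.set_xlabel("mission fraction")
        ax.set_ylabel("LRM-50")
        ax.set_title("Chained individualized prediction (synthetic)")
        ax.legend()
        p = os.path.join(out_dir, "fig_chained.png")
        fig.tight_layout()
        fig.savefig(p, dpi=100)
        plt.close(fig)
        files.append(p)
    return files


def toggle_predict(
    bundle: EnsembleFit,
    data: pd.DataFrame,
    participant: str,
    overrides: dict[str, float] | None = None,
    outcome: str = "lrm50",
) -> dict:
    """Single what-if ensemble prediction for one participant.

    Covariates default to the participant's observed averages; ``overrides``
    replaces chosen ones.  The prediction is located against the
    participant's observed score distribution (empirical percentile and the
    worst-15% / best-15% quantile bands).
    """
    overrides = dict(overrides or {})
    unknown = [v for v in overrides if v not in bundle.covariates]
    if unknown:
        raise ValueError(f"unknown covariates in overrides: {unknown}")
    sub = data[data["participant"] == participant]
    if sub.empty:
        raise ValueError(f"unknown participant {participant!r}")
    row = {c: float(sub[c].mean()) for c in bundle.covariates}
    row.update(overrides)
    row["participant"] = participant
    row["mission_frac"] = float(sub["mission_frac"].mean())
    pred = float(bundle.predict(pd.DataFrame([row]))[0])
    hist = sub[outcome].dropna().to_numpy()
    percentile = float(np.mean(hist <= pred) * 100.0)
    q15, q85 = np.percentile(hist, [15, 85])
    return {
        "participant": participant,
        "prediction": pred,
        "percentile_vs_history": percentile,
        "best15_threshold": float(q15),  # lower LRM-50 = better
        "worst15_threshold": float(q85),
        "n_history": int(len(hist)),
    }
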