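"""Forward-chaining windows, leakage audit, error aggregation and chained
individualized prediction."""

import numpy as np
import pandas as pd
import pytest

from vigilant_ensemble.validation import (
    Window,
    aggregate_errors,
    audit_windows,
    chained_prediction,
    make_windows,
    n_shifts,
    run_forward_chain,
    run_horizon_sweep,
)

UTC = "UTC"


def _toy_df(n_obs: dict, seed=0, outcome_value=None):
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp("2011-03-01", tz=UTC)
    rows = []
    for pid, n in n_obs.items():
        for j in range(n):
            rows.append(
                {
                    "participant": pid,
                    "timestamp": t0 + pd.Timedelta(days=j),
                    "mission_frac": j / max(n - 1, 1),
                    "x": rng.normal(),
                    "lrm50": (
                        outcome_value
                        if outcome_value is not None
                        else float(rng.normal())
                    ),
                }
            )
    return pd.DataFrame(rows)


class TestWindows:
    @pytest.mark.parametrize(
        "n_i, t, expected",
        [(100, 5, 20), (12, 10, 3), (25, 20, 6), (10, 10, 1)],
    )
    def test_nominal_shift_count_formula(self, n_i, t, expected):
        assert n_shifts(n_i, t) == expected

    def test_enumeration_matches_brute_force_oracle(self):
        n_obs = {"A": 37, "B": 12, "C": 8}
        t_grid = (5, 10, 15)
        horizon = 1
        windows = make_windows(n_obs, t_grid, horizon=horizon)
        got = {(w.participant, w.t, w.k) for w in windows}
        # independent brute-force triple loop
        expected = set()
        for pid, n_i in n_obs.items():
            for t in t_grid:
                if n_i < t + 1:
                    continue
                for k in range(1, min(20, n_i - t + 1) + 1):
                    if k + t + horizon - 1 <= n_i:
                        expected.add((pid, t, k))
        assert got == expected

    def test_window_contents(self):
        (w,) = [
            w for w in make_windows({"A": 12}, (10,)) if w.k == 1
        ]
        assert w.train_positions == tuple(range(1, 11))
        assert w.test_positions == (11,)

    def test_train_test_overlap_rejected(self):
        with pytest.raises(ValueError):
            Window("A", 5, 1, (1, 2, 3), (3, 4))

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            make_windows({"A": 10}, ())

    def test_audit_passes_on_generated_windows(self):
        n_obs = {"A": 40, "B": 23}
        windows = make_windows(n_obs, (5, 10, 20), horizon=2)
        report = audit_windows(windows, n_obs)
        assert report["n_windows"] == len(windows)
        assert report["violations"] == 0

    def test_audit_catches_future_leak(self):
        bad = Window("A", 3, 1, (1, 2, 5), (4,))
        with pytest.raises(AssertionError):
            audit_windows([bad], {"A": 10})


class TestForwardChain:
    def test_perfect_predictor_zero_errors(self, perfect_fitter):
        df = _toy_df({"A": 15, "B": 12})
        windows = make_windows({"A": 15, "B": 12}, (5, 10))
        cells = run_forward_chain(df, perfect_fitter, windows)
        assert (cells["squared_error"] == 0).all()

    def test_constant_predictor_on_constant_outcome(self, constant_fitter):
        df = _toy_df({"A": 12, "B": 12}, outcome_value=3.0)
        windows = make_windows({"A": 12, "B": 12}, (5,))
        cells = run_forward_chain(df, constant_fitter, windows)
        test = cells[cells["set"] == "test"]
        assert np.allclose(test["squared_error"], 9.0)

    def test_failed_window_fit_excluded_and_counted(self):
        df = _toy_df({"A": 12, "B": 12})

        calls = {"n": 0}

        def flaky(train_df, seed):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("boom")

            class P:
                def predict(self, d):
                    return np.zeros(len(d))

            return P()

        windows = make_windows({"A": 12, "B": 12}, (5,))
        cells = run_forward_chain(df, flaky, windows)
        assert cells.attrs["n_failed"] == 1
        assert cells["k"].notna().all()

    def test_train_cells_recorded_for_training_error(self, perfect_fitter):
        df = _toy_df({"A": 10, "B": 10})
        windows = make_windows({"A": 10, "B": 10}, (5,))
        cells = run_forward_chain(df, perfect_fitter, windows)
        train = cells[cells["set"] == "train"]
        # each window records its t training observations
        counts = train.groupby(["participant", "t", "k"]).size()
        assert (counts == 5).all()


class TestAggregation:
    def _cells(self, rows):
        df = pd.DataFrame(rows)
        df["squared_error"] = (df["y"] - df["yhat"]) ** 2
        df["absolute_error"] = (df["y"] - df["yhat"]).abs()
        return df

    def test_person_means_then_unweighted_average(self):
        rows = []
        for k, e in enumerate([1.0, 1.0], start=1):
            rows.append({"participant": "A", "t": 5, "k": k, "h": 1,
                         "set": "test", "y": e, "yhat": 0.0})
        for k, e in enumerate([np.sqrt(3.0)] * 2, start=1):
            rows.append({"participant": "B", "t": 5, "k": k, "h": 1,
                         "set": "test", "y": e, "yhat": 0.0})
        s = aggregate_errors(self._cells(rows))
        assert s.mse_t[5] == pytest.approx(2.0)  # (1 + 3) / 2

    def test_equal_person_weighting_contract(self):
        rows = [
            {"participant": "A", "t": 5, "k": k, "h": 1, "set": "test",
             "y": 0.0, "yhat": 0.0}
            for k in range(1, 21)
        ] + [
            {"participant": "B", "t": 5, "k": k, "h": 1, "set": "test",
             "y": 2.0, "yhat": 0.0}
            for k in (1, 2)
        ]
        s = aggregate_errors(self._cells(rows))
        # equal person weights: (0 + 4)/2, not the pooled 8/22
        assert s.mse_t[5] == pytest.approx(2.0)

    def test_matches_brute_force_aggregation_oracle(self):
        rng = np.random.default_rng(9)
        rows = []
        for pid in "ABCD":
            for t in (5, 10):
                for k in range(1, int(rng.integers(2, 9))):
                    rows.append(
                        {
                            "participant": pid,
                            "t": t,
                            "k": k,
                            "h": 1,
                            "set": "test",
                            "y": float(rng.normal()),
                            "yhat": float(rng.normal()),
                        }
                    )
        cells = self._cells(rows)
        s = aggregate_errors(cells)
        # independent nested-loop oracle
        ts = sorted({r["t"] for r in rows})
        mse_t = {}
        mae_t = {}
        for t in ts:
            person_mses, person_maes = [], []
            for pid in "ABCD":
                errs = [
                    (r["y"] - r["yhat"]) ** 2
                    for r in rows
                    if r["participant"] == pid and r["t"] == t
                ]
                abss = [
                    abs(r["y"] - r["yhat"])
                    for r in rows
                    if r["participant"] == pid and r["t"] == t
                ]
                if errs:
                    person_mses.append(np.mean(errs))
                    person_maes.append(np.median(abss))
            mse_t[t] = np.mean(person_mses)
            mae_t[t] = np.mean(person_maes)
        overall = np.mean(list(mse_t.values()))
        for t in ts:
            assert s.mse_t[t] == pytest.approx(mse_t[t], rel=1e-12)
            assert s.mae_t[t] == pytest.approx(mae_t[t], rel=1e-12)
        assert s.mse_overall == pytest.approx(overall, rel=1e-12)

    def test_invariant_to_cell_ordering(self):
        rng = np.random.default_rng(10)
        rows = [
            {"participant": p, "t": t, "k": k, "h": 1, "set": "test",
             "y": float(rng.normal()), "yhat": float(rng.normal())}
            for p in "AB" for t in (5, 10) for k in range(1, 6)
        ]
        cells = self._cells(rows)
        shuffled = cells.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a, b = aggregate_errors(cells), aggregate_errors(shuffled)
        assert a.mse_overall == pytest.approx(b.mse_overall, rel=1e-14)
        pd.testing.assert_series_equal(a.mse_t, b.mse_t)

    def test_training_error_squared_and_literal_modes(self):
        rows = [
            {"participant": "A", "t": 2, "k": 1, "h": j, "set": "train",
             "y": 2.0, "yhat": 0.0}
            for j in (1, 2)
        ] + [
            {"participant": "A", "t": 2, "k": 1, "h": 1, "set": "test",
             "y": 0.0, "yhat": 0.0},
            {"participant": "B", "t": 2, "k": 1, "h": 1, "set": "test",
             "y": 0.0, "yhat": 0.0},
        ]
        cells = self._cells(rows)
        s_sq = aggregate_errors(cells)
        row = s_sq.mse_train_it.set_index(["participant", "t"]).loc[("A", 2)]
        assert row["mse_train"] == pytest.approx(8.0)  # (4 + 4) / 1 shift
        s_lit = aggregate_errors(cells, literal_train=True)
        row = s_lit.mse_train_it.set_index(["participant", "t"]).loc[("A", 2)]
        assert row["mse_train"] == pytest.approx(4.0)  # (2 + 2) / 1, unsquared

    def test_rmse_over_sd_definition(self):
        rng = np.random.default_rng(11)
        rows = [
            {"participant": p, "t": 5, "k": k, "h": 1, "set": "test",
             "y": float(rng.normal()), "yhat": 0.0}
            for p in "AB" for k in range(1, 8)
        ]
        s = aggregate_errors(self._cells(rows))
        expected = np.sqrt(s.mse_t[5]) / s.sd_y
        assert s.rmse_over_sd_t[5] == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_errors(self._cells([]) if False else pd.DataFrame(
                columns=["participant", "t", "k", "h", "set", "y", "yhat",
                         "squared_error", "absolute_error"]
            ))


class TestHorizonSweep:
    def test_perfect_predictor_zero_at_every_horizon(self, perfect_fitter):
        df = _toy_df({"A": 20, "B": 20})
        out = run_horizon_sweep(
            df, perfect_fitter, horizons=(1, 2, 3), t_grid=(5, 10)
        )
        assert set(out) == {1, 2, 3}
        for s in out.values():
            assert s.mse_overall == 0.0

    def test_horizon_one_matches_plain_run(self, constant_fitter):
        n_obs = {"A": 16, "B": 14}
        df = _toy_df(n_obs, seed=5)
        windows = make_windows(n_obs, (5, 10))
        plain = aggregate_errors(
            run_forward_chain(df, constant_fitter, windows)
        )
        sweep = run_horizon_sweep(
            df, constant_fitter, horizons=(1, 2), t_grid=(5, 10)
        )
        assert sweep[1].mse_overall == pytest.approx(plain.mse_overall, rel=1e-12)
        pd.testing.assert_series_equal(sweep[1].mse_t, plain.mse_t)


class TestChainedPrediction:
    def test_perfect_predictor_zero_rmse_degenerate_bands(self, perfect_fitter):
        df = _toy_df({"A": 8, "B": 8})
        chain, manifest = chained_prediction(
            df, "A", perfect_fitter, n_bootstrap=5, seed=0
        )
        assert manifest["rmse"] == pytest.approx(0.0)
        assert np.allclose(chain["q75"] - chain["q25"], 0.0)
        assert len(chain) == 7  # predictions at observations 2..8

    def test_single_bootstrap_zero_band_width(self, constant_fitter):
        df = _toy_df({"A": 5, "B": 5})
        chain, _ = chained_prediction(
            df, "A", constant_fitter, n_bootstrap=1, seed=0
        )
        assert np.allclose(chain["q75"], chain["q25"])

    def test_resample_composition_audit(self, constant_fitter):
        df = _toy_df({"A": 6, "B": 6, "C": 6, "D": 6})
        _, manifest = chained_prediction(
            df, "B", constant_fitter, n_bootstrap=10, seed=1
        )
        for comp in manifest["resamples"]:
            assert "B" not in comp  # target enters via its prior data only
            assert len(comp) == 3  # others resampled with replacement

    def test_too_short_history_raises(self, constant_fitter):
        df = _toy_df({"A": 1, "B": 6})
        with pytest.raises(ValueError, match="at least 2"):
            chained_prediction(df, "A", constant_fitter, n_bootstrap=1)
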