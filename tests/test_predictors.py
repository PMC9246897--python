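"""Derived covariates: PCA composite, medication flags, sleep arithmetic,
two-process model dynamics and the lagged outcome."""

import numpy as np
import pandas as pd
import pytest

from vigilant_ensemble.predictors import (
    CompositeModel,
    TwoProcessParams,
    composite_score,
    derive,
    fit_composite,
    lag_outcome,
    medication_flags,
    total_sleep_missed,
    two_process_lapses,
    two_process_s,
)
from vigilant_ensemble.synthetic_data import RATING_COLUMNS

UTC = "UTC"


def _ratings_frame(matrix):
    return pd.DataFrame(matrix, columns=list(RATING_COLUMNS))


class TestComposite:
    def test_identical_columns_equal_loadings(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 10, 30)
        X = _ratings_frame(np.tile(col[:, None], (1, 7)))
        model = fit_composite(X)
        assert np.allclose(np.abs(model.loadings), 1 / np.sqrt(7))
        assert model.variance_explained == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=200)
        X = np.column_stack(
            [latent + rng.normal(0, 0.3, 200) for _ in range(4)]
            + [rng.normal(size=200) for _ in range(3)]
        )
        df = _ratings_frame(X)
        model = fit_composite(df)
        # independent oracle: eigenvector of the correlation matrix
        corr = np.corrcoef(X, rowvar=False)
        w, v = np.linalg.eigh(corr)
        pc1 = v[:, -1]
        expected = np.abs(pc1)
        assert np.allclose(np.abs(model.loadings.to_numpy()), expected, atol=1e-8)
        # PC1 loads on the correlated block
        block = np.abs(model.loadings.to_numpy()[:4])
        noise = np.abs(model.loadings.to_numpy()[4:])
        assert block.min() > noise.max()

    def test_sign_anchor_keeps_stress_positive(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(size=100)
        X = np.column_stack([latent + rng.normal(0, 0.4, 100) for _ in range(7)])
        for flip in (1.0, -1.0):
            model = fit_composite(_ratings_frame(flip * X))
            assert model.loadings["stressed"] > 0

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = _ratings_frame(rng.uniform(0, 10, (20, 7)))
        X["workload"] = 5.0
        with pytest.warns(UserWarning, match="workload"):
            model = fit_composite(X)
        assert "workload" not in model.loadings.index

    def test_too_few_rows_raise(self):
        X = _ratings_frame(np.random.default_rng(4).uniform(0, 10, (5, 7)))
        with pytest.raises(ValueError, match="at least 8"):
            fit_composite(X)


class TestCompositeScore:
    def _equal_model(self):
        w = pd.Series(np.full(7, 1 / np.sqrt(7)), index=list(RATING_COLUMNS))
        return CompositeModel(
            loadings=w, variance_explained=1.0, sign_anchor="stressed",
            means=w * 0, sds=w * 0 + 1,
        )

    def test_equal_loadings_all_fives(self):
        model = self._equal_model()
        row = pd.Series({c: 5.0 for c in RATING_COLUMNS})
        assert composite_score(model, row) == pytest.approx(5.0)

    def test_anchor_only_loading(self):
        w = pd.Series(0.0, index=list(RATING_COLUMNS))
        w["stressed"] = 1.0
        model = CompositeModel(w, 1.0, "stressed", w * 0, w * 0 + 1)
        row = pd.Series({c: 3.0 for c in RATING_COLUMNS})
        row["stressed"] = 8.0
        assert composite_score(model, row) == pytest.approx(8.0)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.1, 1.0, 7)
        w /= np.linalg.norm(w)
        model = CompositeModel(
            pd.Series(w, index=list(RATING_COLUMNS)), 0.5, "stressed",
            pd.Series(0.0, index=list(RATING_COLUMNS)),
            pd.Series(1.0, index=list(RATING_COLUMNS)),
        )
        X = _ratings_frame(rng.uniform(0, 10, (50, 7)))
        scores = composite_score(model, X)
        expected = X.to_numpy() @ w / w.sum()
        assert np.allclose(scores, expected)

    def test_missing_rating_renormalizes(self):
        model = self._equal_model()
        row = pd.Series({c: 6.0 for c in RATING_COLUMNS})
        row["workload"] = np.nan
        assert composite_score(model, row) == pytest.approx(6.0)

    def test_all_missing_raises(self):
        model = self._equal_model()
        row = pd.Series({c: np.nan for c in RATING_COLUMNS})
        with pytest.raises(ValueError):
            composite_score(model, row)


class TestMedicationFlags:
    @pytest.mark.parametrize(
        "text, expected_true",
        [
            ("ibuprofen 400mg", {"pain"}),
            ("None", set()),
            ("Decline to answer", set()),
            ("zolpidem; loratadine", {"sleep_aid", "antihistamine"}),
            ("Sudafed and Tylenol", {"decongestant", "pain"}),
            (np.nan, set()),
        ],
    )
    def test_lexicon_cases(self, text, expected_true):
        flags = medication_flags(text)
        assert {k for k, v in flags.items() if v} == expected_true


class TestTotalSleepMissed:
    def test_zero(self):
        assert total_sleep_missed(0, 0, 0) == 0.0

    def test_one_hour(self):
        assert total_sleep_missed(20, 30, 10) == pytest.approx(1.0)

    def test_random_records_match_sum_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a, b, c = rng.uniform(0, 120, 3)
            assert total_sleep_missed(a, b, c) == pytest.approx((a + b + c) / 60.0)

    def test_negative_component_raises(self):
        with pytest.raises(ValueError):
            total_sleep_missed(-1, 0, 0)


def _schedule(n_days, wake_h=16.0, sleep_h=8.0, start="2011-03-01 23:00"):
    """Regular wake/sleep episodes: bed at start, sleep sleep_h, etc."""
    t0 = pd.Timestamp(start, tz=UTC)
    eps = []
    for d in range(n_days):
        bed = t0 + pd.Timedelta(hours=d * (wake_h + sleep_h))
        eps.append((bed, bed + pd.Timedelta(hours=sleep_h)))
    return eps


class TestTwoProcess:
    def test_infinite_tau_wake_freezes_homeostat(self):
        params = TwoProcessParams(tau_wake=1e12)
        eps = _schedule(3)
        t_eval = eps[-1][1] + pd.Timedelta(hours=10)
        s = two_process_s(eps, t_eval, params)
        # after the last sleep episode S cannot rise: equals its post-sleep value
        s_at_wake = two_process_s(eps, eps[-1][1], params)
        assert s == pytest.approx(s_at_wake, abs=1e-9)

    def test_long_wake_reaches_upper_asymptote(self):
        params = TwoProcessParams()
        eps = _schedule(2)
        t_eval = eps[-1][1] + pd.Timedelta(days=30)
        s = two_process_s(eps, t_eval, params)
        assert s == pytest.approx(params.s_upper, abs=1e-6)

    def test_s_stays_within_band(self):
        params = TwoProcessParams()
        eps = _schedule(10)
        rng = np.random.default_rng(7)
        t0 = eps[0][0]
        for _ in range(50):
            t_eval = t0 + pd.Timedelta(hours=float(rng.uniform(1, 9 * 24)))
            s = two_process_s(eps, t_eval, params)
            assert params.s_lower - 1e-12 <= s <= params.s_upper + 1e-12

    def test_periodic_schedule_converges_to_periodic_orbit(self):
        params = TwoProcessParams()
        eps = _schedule(40)
        base = eps[0][0] + pd.Timedelta(days=30, hours=12)
        s1 = two_process_s(eps, base, params)
        s2 = two_process_s(eps, base + pd.Timedelta(hours=24), params)
        assert abs(s1 - s2) < 1e-6

    def test_closed_form_matches_rk4_integrator(self):
        # independent oracle: fine-step RK4 on the piecewise-linear ODE
        params = TwoProcessParams()
        eps = _schedule(6)
        t0 = eps[0][0]
        t_eval = t0 + pd.Timedelta(days=5, hours=3)

        def ds(s, awake):
            if awake:
                return (params.s_upper - s) / params.tau_wake
            return (params.s_lower - s) / params.tau_sleep

        def awake_at(h):
            t = t0 + pd.Timedelta(hours=h)
            return not any(b <= t < w for b, w in eps)

        total_h = (t_eval - t0).total_seconds() / 3600.0
        dt = 0.002
        # match the implementation's initial condition: S0=0.5 propagated
        # through a 16-h wake block ending at the first bedtime
        s = params.s_upper + (0.5 - params.s_upper) * np.exp(-16.0 / params.tau_wake)
        h = 0.0
        n = int(round(total_h / dt))
        for i in range(n):
            mid = h + dt / 2
            awake = awake_at(mid)
            k1 = ds(s, awake)
            k2 = ds(s + dt / 2 * k1, awake)
            k3 = ds(s + dt / 2 * k2, awake)
            k4 = ds(s + dt * k3, awake)
            s += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            h += dt
        assert two_process_s(eps, t_eval, params) == pytest.approx(s, abs=1e-6)

    def test_predicted_lapses_nonnegative(self):
        params = TwoProcessParams(lapse_intercept=-5.0)
        eps = _schedule(4)
        t_eval = eps[0][1] + pd.Timedelta(minutes=30)
        assert two_process_lapses(eps, t_eval, params) >= 0.0

    def test_overlapping_episodes_raise(self):
        t0 = pd.Timestamp("2011-03-01 23:00", tz=UTC)
        eps = [
            (t0, t0 + pd.Timedelta(hours=8)),
            (t0 + pd.Timedelta(hours=4), t0 + pd.Timedelta(hours=12)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            two_process_s(eps, t0 + pd.Timedelta(hours=20))

    def test_no_history_raises(self):
        eps = _schedule(2)
        with pytest.raises(ValueError, match="no completed sleep"):
            two_process_s(eps, eps[0][0] - pd.Timedelta(hours=1))


class TestLagOutcome:
    def _df(self, values, pid="P01"):
        t0 = pd.Timestamp("2011-03-01", tz=UTC)
        return pd.DataFrame(
            {
                "participant": pid,
                "timestamp": [t0 + pd.Timedelta(days=i) for i in range(len(values))],
                "lrm50": values,
            }
        )

    def test_simple_series_shifts(self):
        df = pd.concat(
            [self._df([1.0, 2.0, 3.0], "A"), self._df([10.0, 20.0], "B")],
            ignore_index=True,
        )
        out = lag_outcome(df)
        a = out[out["participant"] == "A"]
        assert list(a["lrm50_lag"].iloc[1:]) == [1.0, 2.0]
        assert a["lrm50_lag_src"].iloc[0] == "imputed"

    def test_first_row_uses_preflight_mean_when_given(self):
        df = self._df([5.0, 6.0])
        out = lag_outcome(df, preflight_means={"P01": -42.0})
        assert out["lrm50_lag"].iloc[0] == pytest.approx(-42.0)

    def test_single_observation_participant_gets_cohort_mean(self):
        df = pd.concat(
            [self._df([0.0, 4.0], "A"), self._df([8.0], "B")], ignore_index=True
        )
        out = lag_outcome(df)
        b = out[out["participant"] == "B"]
        assert b["lrm50_lag"].iloc[0] == pytest.approx(4.0)  # cohort mean

    def test_sorted_requirement_and_permutation_invariance(self):
        df = pd.concat(
            [self._df([1.0, 2.0, 3.0], "A"), self._df([4.0, 5.0], "B")],
            ignore_index=True,
        )
        shuffled = df.sample(frac=1.0, random_state=0)
        with pytest.raises(ValueError):
            lag_outcome(shuffled)
        resorted = shuffled.sort_values(["participant", "timestamp"]).reset_index(
            drop=True
        )
        pd.testing.assert_frame_equal(lag_outcome(resorted), lag_outcome(df))


def test_derive_populates_all_covariates(tiny_derived):
    for col in (
        "stress_fatigue",
        "med_pain",
        "med_sleep_aid",
        "total_sleep_missed_h",
        "pred_lapses",
        "lrm50_lag",
        "age",
        "preflight_ops",
        "track_evening",
    ):
        assert col in tiny_derived.columns
        assert tiny_derived[col].notna().all()
    assert (tiny_derived["pred_lapses"] >= 0).all()
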