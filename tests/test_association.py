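"""Logistic association: ML fit vs grid oracle, quartiles, curves, binned rates."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ems3d.association import (
    AssociationError,
    LogisticFit,
    assign_quartiles,
    binned_observed_rate,
    fit_logistic,
    make_outcome_frame,
    probability_curve,
    quartile_or,
    two_by_two_or,
)


def simulate_records(rng, n, beta0, beta1, score_max=0.8):
    ems = rng.uniform(0.0, score_max, size=n)
    p = expit(beta0 + beta1 * ems)
    y = rng.random(n) < p
    mfi = np.where(y, 6000.0, 300.0)
    return make_outcome_frame(ems, mfi, pair_id=[f"p{i}" for i in range(n)])


def grid_maximize_loglik(ems, y, b0_range, b1_range, rounds=8, width=41):
    """Brute-force likelihood-surface maximization by iterative grid refinement."""
    lo0, hi0 = b0_range
    lo1, hi1 = b1_range
    best = (np.nan, np.nan)
    for _ in range(rounds):
        b0s = np.linspace(lo0, hi0, width)
        b1s = np.linspace(lo1, hi1, width)
        ll = np.empty((width, width))
        for i, b0 in enumerate(b0s):
            eta = b0 + np.outer(b1s, ems)
            ll[i] = (y * eta - np.log1p(np.exp(eta))).sum(axis=1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (b0s[i], b1s[j])
        span0, span1 = (hi0 - lo0) / 5.0, (hi1 - lo1) / 5.0
        lo0, hi0 = best[0] - span0 / 2, best[0] + span0 / 2
        lo1, hi1 = best[1] - span1 / 2, best[1] + span1 / 2
    return best


class TestFitLogistic:
    def test_matches_brute_force_grid_on_small_fixture(self, rng):
        records = simulate_records(rng, 50, beta0=-1.0, beta1=4.0)
        fit = fit_logistic(records)
        b0, b1 = grid_maximize_loglik(
            records["ems3d"].to_numpy(), records["dsa_2000"].to_numpy(float),
            (-6.0, 6.0), (-20.0, 20.0),
        )
        assert fit.params["const"] == pytest.approx(b0, abs=1e-3)
        assert fit.params["ems3d"] == pytest.approx(b1, abs=1e-3)

    def test_recovers_true_slope_within_two_se(self, rng):
        records = simulate_records(rng, 2000, beta0=-2.0, beta1=8.0)
        fit = fit_logistic(records)
        assert abs(fit.params["ems3d"] - 8.0) <= 2.0 * fit.bse["ems3d"]
        assert fit.or_per_01 == pytest.approx(np.exp(0.1 * fit.params["ems3d"]))
        lo, hi = fit.or_ci
        assert lo < fit.or_per_01 < hi

    def test_recovery_rate_across_replicates(self):
        """~95% nominal coverage: the true slope lies within 2 SE in >= 90% of
        seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1_000 + seed)
            records = simulate_records(rng, 400, beta0=-2.0, beta1=8.0)
            fit = fit_logistic(records)
            hits += abs(fit.params["ems3d"] - 8.0) <= 2.0 * fit.bse["ems3d"]
        assert hits >= 90

    def test_constant_outcome_rejected(self, rng):
        records = simulate_records(rng, 30, beta0=-1.0, beta1=2.0)
        records["dsa_2000"] = False
        with pytest.raises(AssociationError, match="constant"):
            fit_logistic(records)

    def test_complete_separation_rejected(self):
        ems = np.concatenate([np.linspace(0.0, 0.2, 20), np.linspace(0.6, 0.8, 20)])
        mfi = np.where(ems > 0.4, 6000.0, 300.0)
        records = make_outcome_frame(ems, mfi)
        with pytest.raises(AssociationError):
            fit_logistic(records)

    def test_cluster_robust_errors_at_least_as_conservative_direction(self, rng):
        records = simulate_records(rng, 500, beta0=-2.0, beta1=8.0)
        records["pair_id"] = [f"p{i // 4}" for i in range(len(records))]
        plain = fit_logistic(records)
        robust = fit_logistic(records, cluster="pair_id")
        # point estimates identical; only the variance estimator changes
        assert robust.params["ems3d"] == pytest.approx(plain.params["ems3d"], abs=1e-8)
        assert robust.bse["ems3d"] > 0

    def test_summary_mentions_or_scale(self, rng):
        fit = fit_logistic(simulate_records(rng, 300, -1.0, 5.0))
        assert "OR/0.1U" in fit.summary()


class TestQuartiles:
    def test_cross_product_oracle(self):
        assert two_by_two_or(10, 10, 2, 18) == pytest.approx(9.0)

    def test_ties_go_to_lower_quartile(self):
        values = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
        q = assign_quartiles(values)
        # q25 = 1.5, q50 = 2.5, q75 = 3.5: clean split into pairs
        assert list(q) == [1, 1, 2, 2, 3, 3, 4, 4]
        tied = assign_quartiles(np.array([1.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 5.0]))
        assert (tied[1:-1] <= 3).all()  # values at the cut never promoted

    def test_flat_risk_has_or_near_one(self, rng):
        ems = rng.uniform(0, 1, 400)
        y = rng.random(400) < 0.4
        records = make_outcome_frame(ems, np.where(y, 6000.0, 300.0))
        table = quartile_or(records)
        for _, row in table.iloc[1:].iterrows():
            assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_monotone_risk_gives_nondecreasing_ors(self, rng):
        records = simulate_records(rng, 2000, beta0=-3.0, beta1=7.0, score_max=1.0)
        table = quartile_or(records)
        ors = table["odds_ratio"].to_numpy()
        assert np.all(np.diff(ors) >= 0)

    def test_zero_cell_notes_continuity(self):
        ems = np.array([0.05] * 10 + [0.3] * 10 + [0.6] * 10 + [0.9] * 10)
        mfi = np.array([300.0] * 10 + [300.0] * 5 + [6000.0] * 25)
        table = quartile_or(make_outcome_frame(ems, mfi))
        assert (table["note"].str.contains("continuity")).any()
        assert np.isfinite(table["odds_ratio"].iloc[-1])

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(AssociationError, match="8 records"):
            quartile_or(simulate_records(rng, 5, 0.0, 0.0))


class TestProbabilityCurve:
    def _null_fit(self):
        idx = ["const", "ems3d"]
        return LogisticFit(
            params=pd.Series([0.0, 0.0], index=idx),
            bse=pd.Series([0.1, 0.1], index=idx),
            cov=pd.DataFrame(np.eye(2) * 0.01, index=idx, columns=idx),
            llf=0.0, nobs=10, outcome="dsa_2000",
            or_per_01=1.0, or_ci=(0.9, 1.1),
        )

    def test_null_model_is_flat_half(self):
        curve = probability_curve(self._null_fit(), np.linspace(0, 1, 11))
        np.testing.assert_allclose(curve["probability"], 0.5)
        assert (curve["ci_low"] < 0.5).all() and (curve["ci_high"] > 0.5).all()

    def test_monotone_when_slope_positive(self, rng):
        fit = fit_logistic(simulate_records(rng, 800, -2.0, 8.0))
        curve = probability_curve(fit, np.linspace(0, 0.8, 50))
        assert (np.diff(curve["probability"]) > 0).all()

    def test_curve_tracks_empirical_bin_rates(self, rng):
        records = simulate_records(rng, 3000, beta0=-2.0, beta1=8.0)
        fit = fit_logistic(records)
        edges = np.linspace(0.0, 0.8, 5)
        rates = binned_observed_rate(records, edges)
        mids = (edges[:-1] + edges[1:]) / 2.0
        curve = probability_curve(fit, mids)
        for (_, row), p_hat in zip(rates.iterrows(), curve["probability"]):
            p_obs = row["events"] / row["count"]
            se = np.sqrt(p_hat * (1 - p_hat) / row["count"])
            assert abs(p_obs - p_hat) < 4.0 * se + 0.02


class TestBinnedRates:
    def test_worked_proportions(self):
        ems = np.concatenate([np.full(27, 0.02), np.full(110, 0.5)])
        events = np.zeros(137, dtype=bool)
        events[:3] = True  # 3 of 27 low-score mismatches
        events[27 : 27 + 78] = True  # 78 of 110 high-score mismatches
        records = make_outcome_frame(ems, np.where(events, 6000.0, 300.0))
        out = binned_observed_rate(records, [0.0, 0.045, 1.0])
        assert out.loc[0, "count"] == 27 and out.loc[0, "events"] == 3
        assert out.loc[0, "percent"] == 11.0
        assert out.loc[1, "count"] == 110 and out.loc[1, "events"] == 78
        assert out.loc[1, "percent"] == 71.0

    def test_zero_events_and_empty_bin(self):
        records = make_outcome_frame([0.1, 0.2], [300.0, 300.0])
        out = binned_observed_rate(records, [0.0, 0.3, 0.6])
        assert out.loc[0, "percent"] == 0.0
        assert out.loc[1, "count"] == 0 and np.isnan(out.loc[1, "percent"])

    def test_unordered_bounds_rejected(self):
        records = make_outcome_frame([0.1], [300.0])
        with pytest.raises(AssociationError, match="increasing"):
            binned_observed_rate(records, [0.5, 0.1])


def test_high_level_dsa_never_exceeds_dsa(rng):
    mfi = rng.lognormal(np.log(2000.0), 1.2, size=500)
    records = make_outcome_frame(rng.uniform(0, 1, 500), mfi)
    assert records["dsa_8000"].sum() <= records["dsa_2000"].sum()
    assert (records.loc[records["dsa_8000"], "dsa_2000"]).all()
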