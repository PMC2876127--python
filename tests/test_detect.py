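"""Moderated testing: per-feature fits, variance prior, BH, GEL50."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xcgh.detect import (
    ModerationPrior,
    bh_adjust,
    call_excess,
    estimate_moderation_prior,
    fit_feature_means,
    gel50,
    moderate,
)


def ma_frame(values: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for fid, ms in values.items():
        for j, m in enumerate(ms):
            rows.append({"array_id": f"a{j}", "feature_id": fid, "M": m,
                         "A": 12.0, "included": True})
    return pd.DataFrame(rows)


class TestFitFeatureMeans:
    def test_hand_computed_values(self):
        res = fit_feature_means(ma_frame({
            "f1": [1.0, 1.0, 1.0],
            "f2": [0.8, 1.2],
        })).set_index("feature_id")
        assert res.loc["f1", "coef"] == pytest.approx(1.0)
        assert res.loc["f1", "s2"] == pytest.approx(0.0)
        assert res.loc["f1", "df"] == 2
        assert res.loc["f2", "coef"] == pytest.approx(1.0)
        assert res.loc["f2", "s2"] == pytest.approx(0.08)
        assert res.loc["f2", "df"] == 1

    def test_array_order_irrelevant(self):
        ma = ma_frame({"f1": [0.3, 0.9, 0.6]})
        res1 = fit_feature_means(ma)
        res2 = fit_feature_means(ma.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(res1, res2)

    def test_single_array_feature_is_an_internal_error(self):
        with pytest.raises(ValueError, match="< 2"):
            fit_feature_means(ma_frame({"f1": [1.0]}))


class TestModerationPrior:
    def test_monte_carlo_parameter_recovery(self):
        # hierarchical draw at known (d0=4, s0_sq=0.02), df=5 per feature
        rng = np.random.default_rng(42)
        n, d0, s0_sq, df = 5000, 4.0, 0.02, 5
        v = s0_sq * d0 / rng.chisquare(d0, size=n)
        s2 = v * rng.chisquare(df, size=n) / df
        prior = estimate_moderation_prior(s2, np.full(n, df))
        assert 2.5 <= prior.d0 <= 6.5
        assert abs(prior.s0_sq - s0_sq) <= 0.25 * s0_sq

    def test_no_excess_spread_gives_infinite_d0(self):
        s2 = np.full(200, 0.05)
        prior = estimate_moderation_prior(s2, np.full(200, 5))
        assert np.isinf(prior.d0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        s2 = 0.02 * 4 / rng.chisquare(4, size=2000) * rng.chisquare(5, 2000) / 5
        df = np.full(2000, 5)
        p1 = estimate_moderation_prior(s2, df)
        p2 = estimate_moderation_prior(10.0 * s2, df)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-9)
        assert p2.s0_sq == pytest.approx(10.0 * p1.s0_sq, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_moderation_prior(np.zeros(100), np.full(100, 5))
        with pytest.raises(ValueError, match="< 50"):
            estimate_moderation_prior(np.full(10, 0.1), np.full(10, 5))


class TestModerate:
    def results(self, coef=0.5, s2=0.05, df=5):
        return pd.DataFrame({
            "feature_id": ["f1"], "coef": [coef], "s2": [s2],
            "df": [df], "n_included": [df + 1],
        })

    def test_hand_computed_shrinkage(self):
        out = moderate(self.results(), ModerationPrior(d0=4.0, s0_sq=0.01))
        assert out["s2_moderated"].iloc[0] == pytest.approx((0.04 + 0.25) / 9)

    def test_d0_zero_limit_is_ordinary_t(self):
        out = moderate(self.results(), ModerationPrior(d0=0.0, s0_sq=123.0))
        assert out["s2_moderated"].iloc[0] == pytest.approx(0.05)
        t = 0.5 / np.sqrt(0.05 / 6)
        assert out["t_moderated"].iloc[0] == pytest.approx(t)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.t.sf(t, 5))

    def test_d0_infinite_limit_is_z_on_pooled_variance(self):
        out = moderate(self.results(), ModerationPrior(d0=np.inf, s0_sq=0.02))
        assert out["s2_moderated"].iloc[0] == pytest.approx(0.02)
        z = 0.5 / np.sqrt(0.02 / 6)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(z))

    def test_moderation_shrinks_log_variance_spread(self):
        rng = np.random.default_rng(3)
        n = 2000
        s2 = 0.02 * 4 / rng.chisquare(4, n) * rng.chisquare(5, n) / 5
        res = pd.DataFrame({
            "feature_id": [f"f{i}" for i in range(n)],
            "coef": rng.normal(0, 0.2, n), "s2": s2,
            "df": 5, "n_included": 6,
        })
        prior = estimate_moderation_prior(res["s2"], res["df"])
        out = moderate(res, prior)
        assert (np.log(out["s2_moderated"]).var()
                < np.log(out["s2"]).var())

    def test_one_sided_upper_tail(self):
        prior = ModerationPrior(d0=4.0, s0_sq=0.01)
        two = moderate(self.results(coef=0.5), prior)["p"].iloc[0]
        up = moderate(self.results(coef=0.5), prior, one_sided=True)["p"].iloc[0]
        down = moderate(self.results(coef=-0.5), prior, one_sided=True)["p"].iloc[0]
        assert up == pytest.approx(two / 2)
        assert down == pytest.approx(1 - two / 2)


def bh_brute_force(p):
    """O(m^2) literal step-up definition: q_i = min over all j with
    p_j >= p_i of p_j * m / rank(p_j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_and_singleton(self):
        np.testing.assert_allclose(bh_adjust([0.05] * 10), [0.05] * 10)
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 1)
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p),
                                       atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestBHAdjustProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(deadline=None, max_examples=75, derandomize=True)
    def test_step_up_definition_and_bounds(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_brute_force(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)  # adjustment never lowers p
        assert np.all(q <= 1.0)


class TestCallExcess:
    @pytest.mark.parametrize("q,coef,called", [
        (0.05, 0.8, True),
        (0.05, -0.8, False),  # direction requirement
        (0.15, 2.0, False),
        (0.1, 0.8, False),    # threshold is strict
    ])
    def test_direction_and_threshold(self, q, coef, called):
        res = pd.DataFrame({"feature_id": ["f"], "coef": [coef], "q": [q]})
        assert call_excess(res, alpha=0.1)["called_excess"].iloc[0] == called


class TestGel50:
    def test_vanishing_noise_drives_gel50_to_zero(self):
        prior = ModerationPrior(d0=np.inf, s0_sq=1e-8)
        assert gel50(prior, df_typical=5, n_arrays=6, seed=1,
                     mu_grid=np.arange(0, 0.2, 0.01)) < 0.02

    def test_non_decreasing_in_prior_variance(self):
        values = [
            gel50(ModerationPrior(d0=4.0, s0_sq=s0), df_typical=5,
                  n_arrays=6, n_sim=4000, seed=2)
            for s0 in (0.01, 0.05, 0.2)
        ]
        assert values[0] <= values[1] <= values[2]

    def test_matches_independent_brute_force_resimulation(self):
        """Fixed config cross-checked against a self-contained re-simulation
        (own moderated-t formula, own step-up threshold search)."""
        prior = ModerationPrior(d0=4.0, s0_sq=0.02)
        value = gel50(prior, df_typical=5, n_arrays=6, alpha=0.1,
                      n_sim=2000, seed=1)

        def brute(mu, rng, n=20000, frac_alt=0.1, df=5, n_arr=6, alpha=0.1):
            n_alt = int(frac_alt * n)
            means = np.concatenate([np.full(n_alt, mu), np.zeros(n - n_alt)])
            v = prior.s0_sq * prior.d0 / rng.chisquare(prior.d0, n)
            coef = rng.normal(means, np.sqrt(v / n_arr))
            s2 = v * rng.chisquare(df, n) / df
            s2m = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
            t = coef / np.sqrt(s2m / n_arr)
            p = 2 * stats.t.sf(np.abs(t), df + prior.d0)
            ps = np.sort(p)
            passing = np.flatnonzero(ps <= alpha * np.arange(1, n + 1) / n)
            thr = ps[passing.max()] if len(passing) else -1.0
            called = (p <= thr) & (coef > 0)
            return called[:n_alt].mean()

        rng = np.random.default_rng(99)
        grid = np.arange(0.0, 1.5001, 0.05)
        power = np.array([brute(mu, rng) for mu in grid])
        i = np.flatnonzero(power >= 0.5)[0]
        x0, x1, y0, y1 = grid[i - 1], grid[i], power[i - 1], power[i]
        oracle = x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)
        assert abs(value - oracle) <= 0.03

    def test_power_at_unit_log_ratio_exceeds_90_percent(self):
        """A true 2:1 ratio (M=+1) is detected >90% of the time under the
        default-calibration noise prior and six replicate arrays."""
        prior = ModerationPrior(d0=5.0, s0_sq=0.33**2)
        value = gel50(prior, df_typical=5, n_arrays=6, alpha=0.1,
                      n_sim=4000, seed=3)
        # GEL50 well below 1 means power at mu=1 is far beyond 50%...
        assert value < 0.7
        rng = np.random.default_rng(4)
        v = prior.s0_sq * prior.d0 / rng.chisquare(prior.d0, 4000)
        coef = rng.normal(1.0, np.sqrt(v / 6))
        s2 = v * rng.chisquare(5, 4000) / 5
        res = pd.DataFrame({"coef": coef, "s2": s2, "df": 5, "n_included": 6})
        out = moderate(res, prior)
        out["q"] = bh_adjust(out["p"])
        out = call_excess(out, alpha=0.1)
        assert out["called_excess"].mean() > 0.9
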