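"""The synthetic hybridization generator and its ground-truth contracts."""


import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xcgh import core, preprocess, simulate
from xcgh.simulate import (
    ConfigurationError,
    ConfounderProbs,
    DyeBias,
    IdentityModel,
    SimulationConfig,
    expected_log_ratio,
    hybridization_efficiency,
    make_design,
    simulate_arrays,
    simulate_hit_tables,
    simulate_truth,
)

from conftest import small_config


NO_CONFOUNDERS = ConfounderProbs(0.0, 0.0, 0.0, 0.0, 0.0)


def quiet_config(**overrides):
    """Noise-free, confounder-free configuration."""
    base = dict(
        n_features=400, sigma_feature=0.0, sigma_feature_div=0.0,
        sigma_array=0.0, a_array_jitter=0.0, dye_bias=DyeBias(0.0),
        confounder_probs=NO_CONFOUNDERS, nonspecific_frac=0.0,
        tech_error_prob=0.0, bg_sd=0.0, seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def truth_frame(rows):
    """Hand-built ground-truth rows for expected_log_ratio checks."""
    defaults = dict(
        feature_id="f", is_x=True, copies_test=2, copies_ref=1,
        deleted=False, moved_off_x=False, moved_onto_x=False,
        heterochromatic=False, paralog_family=False,
        extra_ref_loci=0, extra_test_loci=0,
        paralog_identity_ref=np.nan, paralog_offset=0.0,
        identity_test=1.0,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestHybridizationEfficiency:
    @pytest.mark.parametrize("identity,beta,expected", [
        (1.0, 0.0, 1.0),
        (1.0, 50.0, 1.0),
        (0.9, 5.0, 0.5),
        (0.7, 5.0, 0.0),  # clamped
    ])
    def test_values(self, identity, beta, expected):
        assert hybridization_efficiency(identity, beta) == pytest.approx(expected)

    def test_monotone_non_increasing_in_divergence(self):
        ids = np.linspace(0, 1, 101)
        h = hybridization_efficiency(ids, 7.0)
        assert np.all(np.diff(h) >= 0)  # increasing identity -> increasing h

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hybridization_efficiency(1.2, 5.0)


class TestExpectedLogRatio:
    def config(self, beta):
        return SimulationConfig(
            beta_div=beta,
            divergence_model={"test": IdentityModel(0.95, 0.02)},
        )

    def test_x_duplication_and_autosome_baseline(self):
        truth = truth_frame([
            dict(is_x=True, copies_ref=1, identity_test=1.0),
            dict(is_x=False, copies_ref=2, identity_test=1.0),
        ])
        m = expected_log_ratio(truth, "test", self.config(5.0))
        assert m[0] == pytest.approx(1.0)
        assert m[1] == pytest.approx(0.0)

    def test_divergence_masks_the_duplication(self):
        # identity 0.9 at beta 5 halves efficiency: log2(2 * 0.5 / 1) = 0
        truth = truth_frame([dict(identity_test=0.9)])
        m = expected_log_ratio(truth, "test", self.config(5.0))
        assert m[0] == pytest.approx(0.0)

    def test_deleted_feature_is_nan(self):
        truth = truth_frame([dict(deleted=True)])
        assert np.isnan(expected_log_ratio(truth, "test", self.config(5.0))[0])

    def test_reference_paralogs_depress_the_ratio(self):
        # X locus 2:1 plus one fully-conserved autosomal ref paralog (2 copies)
        truth = truth_frame([
            dict(extra_ref_loci=1, paralog_identity_ref=1.0),
        ])
        m = expected_log_ratio(truth, "test", self.config(0.0))
        assert m[0] == pytest.approx(np.log2(2.0 / 3.0))


class TestSimulateTruth:
    def test_deterministic_x_count(self):
        ann, truth, _ = simulate_truth(small_config(n_features=1000, x_fraction=0.2))
        assert int(ann["is_x"].sum()) == 200
        assert (ann["is_x"] == (ann["chromosome"] == "X")).all()

    def test_no_confounders_means_pure_copy_ratios(self):
        cfg = small_config(n_features=500, confounder_probs=NO_CONFOUNDERS)
        _, truth, _ = simulate_truth(cfg)
        assert (truth["copies_test"] == 2).all()
        assert (truth.loc[truth["is_x"], "copies_ref"] == 1).all()
        assert (truth.loc[~truth["is_x"], "copies_ref"] == 2).all()
        assert not truth[["deleted", "moved_off_x", "moved_onto_x",
                          "heterochromatic", "paralog_family"]].any().any()

    def test_same_seed_reproduces_bit_identically(self):
        a1, t1, _ = simulate_truth(small_config())
        a2, t2, _ = simulate_truth(small_config())
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_few_positives_rejected(self):
        with pytest.raises(ConfigurationError, match="too few"):
            simulate_truth(small_config(n_features=50, x_fraction=0.1))

    def test_conserved_sets_scaled_and_nested(self):
        cfg = small_config(n_features=2000)
        ann, truth, _ = simulate_truth(cfg)
        n1000, n100 = simulate.conserved_set_sizes(2000)
        assert ann["conserved_1000"].sum() == n1000 == round(0.053 * 2000)
        assert ann["conserved_100"].sum() == n100 == max(5, round(0.005 * 2000))
        assert (ann["conserved_100"] <= ann["conserved_1000"]).all()
        # conserved features are the most conserved across species
        idents = truth[[c for c in truth.columns if c.startswith("identity_")]]
        min_ident = idents.min(axis=1)
        cons = min_ident[ann["conserved_1000"].to_numpy()]
        rest = min_ident[~ann["conserved_1000"].to_numpy()]
        assert cons.min() >= rest.max() - 1e-12


class TestSimulateArrays:
    def test_noise_free_m_equals_expected_log_ratio(self):
        cfg = quiet_config()
        ann, truth, _ = simulate_truth(cfg)
        design = make_design("platform", 4)
        scan = simulate_arrays(truth, design, cfg, "platform")
        scan = preprocess.apply_qc(scan)
        corrected = preprocess.background_correct_minimum(scan)
        ma = preprocess.compute_ma(corrected, design)
        expected = expected_log_ratio(truth, "platform", cfg)
        merged = ma.merge(truth[["feature_id"]], on="feature_id")
        exp = dict(zip(truth["feature_id"], expected))
        for fid, grp in merged.groupby("feature_id"):
            assert grp["M"].to_numpy() == pytest.approx(exp[fid], abs=1e-9)

    def test_dye_swap_exchanges_channels(self):
        cfg = quiet_config()
        _, truth, _ = simulate_truth(cfg)
        design = pd.DataFrame({
            "array_id": ["fwd", "rev"], "test_sample": "platform",
            "reference_sample": "platform_male", "dye_orientation": [1, -1],
        })
        scan = simulate_arrays(truth, design, cfg, "platform")
        fwd = scan[scan["array_id"] == "fwd"].set_index("feature_id")
        rev = scan[scan["array_id"] == "rev"].set_index("feature_id")
        np.testing.assert_allclose(fwd["fg1"], rev["fg2"])
        np.testing.assert_allclose(fwd["fg2"], rev["fg1"])

    def test_same_seed_bit_identical_tables(self):
        cfg = small_config(n_features=300)
        _, truth, _ = simulate_truth(cfg)
        design = make_design("simulans_like", 4)
        s1 = simulate_arrays(truth, design, cfg, "simulans_like")
        s2 = simulate_arrays(truth, design, cfg, "simulans_like")
        pd.testing.assert_frame_equal(s1, s2)

    def test_different_seeds_distributionally_equivalent(self):
        """KS check on observed M across seeds: same generative law."""
        def m_values(seed):
            cfg = small_config(n_features=1500, seed=seed)
            _, truth, _ = simulate_truth(cfg)
            design = make_design("simulans_like", 2)
            scan = preprocess.apply_qc(
                simulate_arrays(truth, design, cfg, "simulans_like")
            )
            corrected = preprocess.background_correct_minimum(scan)
            ma = preprocess.compute_ma(corrected, design)
            return ma.loc[ma["included"], "M"].to_numpy()

        ref = m_values(100)
        failures = sum(
            stats.ks_2samp(ref, m_values(100 + k)).pvalue < 0.01
            for k in range(1, 6)
        )
        assert failures <= 1

    def test_divergence_slope_recovered_within_2_se(self):
        """Regression of mean M on identity recovers the efficiency slope.

        The oracle is the same regression applied to the *noiseless*
        expected log ratios of the identical features; the noisy estimate
        must agree within twice its standard error.
        """
        cfg = small_config(
            n_features=4000, confounder_probs=NO_CONFOUNDERS, seed=21
        )
        ann, truth, _ = simulate_truth(cfg)
        design = make_design("simulans_like", cfg.n_arrays)
        scan = preprocess.apply_qc(
            simulate_arrays(truth, design, cfg, "simulans_like")
        )
        corrected = preprocess.background_correct_minimum(scan)
        ma = preprocess.compute_ma(corrected, design)
        mean_m = ma[ma["included"]].groupby("feature_id")["M"].mean()
        ident = truth.set_index("feature_id")["identity_simulans_like"]
        # single-copy diverged autosomal features, moderately diverged so the
        # efficiency curve is locally linear (no clamp region)
        use = truth[~truth["is_x"]].set_index("feature_id").index.intersection(
            mean_m.index
        )
        mask = (ident.loc[use] > 0.93) & (ident.loc[use] < 0.999)
        use = use[mask]
        fit = stats.linregress(ident.loc[use], mean_m.loc[use])
        oracle = stats.linregress(
            ident.loc[use],
            expected_log_ratio(
                truth.set_index("feature_id").loc[use].reset_index(),
                "simulans_like", cfg,
            ),
        )
        assert abs(fit.slope - oracle.slope) < 2 * fit.stderr


@pytest.fixture(scope="module")
def planted():
    cfg = small_config(n_features=10_000, seed=17)
    ann, truth, meta = simulate_truth(cfg)
    hits_het, hits_ref = simulate_hit_tables(
        truth, ann, meta, cfg, "simulans_like"
    )
    profile = core.derive_divergence_profile(
        hits_het, hits_ref, ann, meta["simulans_like"], meta["platform"]
    ).set_index("feature_id")
    return truth.set_index("feature_id"), hits_het, profile


class TestSimulateHitTables:
    def test_deleted_features_emit_no_het_hits(self, planted):
        truth, hits_het, profile = planted
        deleted = truth.index[truth["deleted"]]
        assert len(deleted) > 0
        assert not hits_het["query_id"].isin(set(deleted)).any()
        assert profile.loc[deleted, "no_hit"].all()

    def test_planted_confounders_recovered_in_correct_category(self, planted):
        truth, _, profile = planted
        live = ~truth["deleted"]
        cases = [
            (truth["moved_off_x"] & live, "autosomal_only"),
            (truth["moved_onto_x"] & live, "het_x_hit"),
            (truth["heterochromatic"] & live, "tel_or_het"),
        ]
        for planted_mask, flag in cases:
            ids = truth.index[planted_mask]
            assert len(ids) >= 5
            recovery = profile.loc[ids, flag].mean()
            assert recovery >= 0.95, f"{flag}: {recovery:.2f}"
        ref_only = truth.index[(truth["extra_ref_loci"] > 0)
                               & (truth["extra_test_loci"] == 0) & live]
        assert (profile.loc[ref_only, "hit_ratio"] < 1).mean() >= 0.95
        test_only = truth.index[(truth["extra_test_loci"] > 0)
                                & (truth["extra_ref_loci"] == 0) & live]
        assert (profile.loc[test_only, "hit_ratio"] > 1).mean() >= 0.95

    def test_paralog_counts_drive_hit_ratio(self):
        """Two extra reference-genome paralogs: hit ratio 1/3 by composition."""
        cfg = quiet_config(n_features=400)
        ann, truth, meta = simulate_truth(cfg)
        truth.loc[0, "extra_ref_loci"] = 2
        truth.loc[0, "paralog_identity_ref"] = 0.95
        hits_het, hits_ref = simulate_hit_tables(
            truth, ann, meta, cfg, "simulans_like"
        )
        prof = core.derive_divergence_profile(
            hits_het, hits_ref, ann, meta["simulans_like"], meta["platform"]
        ).set_index("feature_id")
        fid = truth.loc[0, "feature_id"]
        assert prof.loc[fid, "hit_ratio"] == pytest.approx(1.0 / 3.0)

    def test_no_confounders_no_flags(self):
        cfg = quiet_config(n_features=400)
        ann, truth, meta = simulate_truth(cfg)
        hits_het, hits_ref = simulate_hit_tables(
            truth, ann, meta, cfg, "simulans_like"
        )
        prof = core.derive_divergence_profile(
            hits_het, hits_ref, ann, meta["simulans_like"], meta["platform"]
        )
        for flag in ("no_hit", "autosomal_only", "het_x_hit", "tel_or_het",
                     "ref_not_found"):
            assert not prof[flag].any(), flag
        assert (prof["hit_ratio"] == 1.0).all()
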