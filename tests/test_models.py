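"""Design matrices, hurdle composition, pooled quasi-likelihood fits."""

import numpy as np
import pandas as pd
import pytest

from feedernet.errors import ValidationError
from feedernet.models import (
    analysis_of_deviance,
    build_design,
    destandardize,
    fit_binomial_glmm,
    fit_hurdle,
    fit_pooled,
    fit_truncated_poisson_glmm,
    mcfadden_r2,
    pooled_pair_table,
    raw_scale_effects,
    standardize,
    table2_report,
)


class TestStandardize:
    def test_closed_form(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert (mean, sd) == (2.0, 1.0)

    def test_moments(self, rng):
        z, _, _ = standardize(rng.normal(3, 7, size=200))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_round_trip(self, rng):
        x = rng.normal(10, 4, size=50)
        z, mean, sd = standardize(x)
        np.testing.assert_allclose(destandardize(z, mean, sd), x, rtol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            standardize([2.0, 2.0, 2.0])


class TestDesign:
    def test_baselines_are_absorbed(self):
        df = pd.DataFrame(
            {
                "veg_cover_pct": [10.0, 30.0, 50.0, 20.0],
                "distance_m": [100.0, 200.0, 150.0, 260.0],
                "ringing_dist_m": [5.0, 40.0, 18.0, 90.0],
                "road_gap_class": [0, 1, 2, 0],
                "season": ["summer", "autumn", "winter", "spring"],
                "species": ["blue_tit", "great_tit", "blue_tit", "blue_tit"],
            }
        )
        X, scalers = build_design(df)
        # the summer / blue-tit / zero-gap row maps to all-zero factor codes
        assert X.loc[0, ["road_gap_1", "road_gap_2", "season_autumn",
                         "season_winter", "season_spring",
                         "species_great_tit"]].sum() == 0
        assert X.loc[1, "road_gap_1"] == 1
        assert X.loc[2, "road_gap_2"] == 1
        assert X.loc[1, "species_great_tit"] == 1
        assert set(scalers) == {"veg_cover_pct", "distance_m", "ringing_dist_m"}
        for col in ("veg_z", "dist_z", "ring_z"):
            assert abs(X[col].mean()) < 1e-12


@pytest.fixture(scope="module")
def hurdle_inputs(full_study, full_events):
    from feedernet.connectivity import build_functional, build_structural

    events, _ = full_events
    struct = build_structural(events, full_study.stations)
    func = build_functional(events)
    net = "medium"
    return (
        struct[struct.network_id == net].reset_index(drop=True),
        func[func.network_id == net].reset_index(drop=True),
        full_study.features[full_study.features.network_id == net].reset_index(
            drop=True
        ),
    )


class TestHurdle:
    def test_joint_loglik_is_sum_of_parts(self, hurdle_inputs):
        struct, func, feats = hurdle_inputs
        h = fit_hurdle(struct, func, feats)
        assert h.loglik == pytest.approx(h.zero.loglik_ + h.count.loglik_)

    def test_parts_are_independent(self, hurdle_inputs, rng):
        """Permuting the presence responses leaves the count part
        untouched (the hurdle factorizes)."""
        struct, func, feats = hurdle_inputs
        struct_perm = struct.copy()
        struct_perm["presence"] = rng.permutation(
            struct_perm["presence"].to_numpy()
        )
        a = fit_hurdle(struct, func, feats)
        b = fit_hurdle(struct_perm, func, feats)
        pd.testing.assert_series_equal(a.count.beta_, b.count.beta_)

    def test_report_is_table_shaped(self, hurdle_inputs):
        struct, func, feats = hurdle_inputs
        h = fit_hurdle(struct, func, feats)
        text = h.report()
        for needle in ("veg_z", "road_gap_2", "season_spring", "R2 marginal",
                       "sigma2_feeder", "sigma2_tag", "CI 2.5%"):
            assert needle in text
        assert "R2 conditional" in table2_report(h.zero)

    def test_plain_poisson_comparison_family(self, hurdle_inputs):
        """The count part can be fitted as plain Poisson for comparison;
        at the study's rates the two families land close together."""
        struct, func, feats = hurdle_inputs
        trunc = fit_truncated_poisson_glmm(func, feats)
        plain = fit_truncated_poisson_glmm(func, feats, count_family="poisson")
        assert type(plain).__name__ == "PoissonGLMM"
        shared = trunc.beta_.index.intersection(plain.beta_.index)
        # same sign pattern and broadly similar effect sizes
        signs_agree = np.sign(trunc.beta_[shared]) == np.sign(plain.beta_[shared])
        assert signs_agree[trunc.beta_[shared].abs() > 0.15].all()

    def test_random_effect_structure(self, hurdle_inputs):
        struct, func, feats = hurdle_inputs
        h = fit_hurdle(struct, func, feats)
        assert set(h.zero.vc_) == {"feeder"}
        assert set(h.count.vc_) == {"feeder", "tag"}
        assert all(v >= 0 for v in h.count.vc_.values())
        # marginal R2 never exceeds conditional
        assert h.zero.r2_marginal_ <= h.zero.r2_conditional_
        assert h.count.r2_marginal_ <= h.count.r2_conditional_

    def test_raw_scale_transform_is_reparameterization(self, hurdle_inputs):
        """Fitting on standardized covariates and mapping back equals
        fitting on raw covariates directly (same ML optimum)."""
        struct, func, feats = hurdle_inputs
        fit_std = fit_binomial_glmm(struct, feats)
        raw_b, raw_se, _ = raw_scale_effects(fit_std)
        from feedernet.glmm import BinomialGLMM
        from feedernet.models import _join_features, build_design, feeder_memberships

        df = _join_features(struct, feats)
        # exact identity: the raw-scale coefficients reproduce the fitted
        # linear predictor on the raw design
        Xraw, _ = build_design(df, standardize_continuous=False,
                               drop_empty_levels=True)
        rename = {"veg_z": "veg_cover_pct", "dist_z": "distance_m",
                  "ring_z": "ringing_dist_m"}
        cols = ["intercept"] + [rename.get(c, c) for c in Xraw.columns]
        eta_raw = raw_b[cols].to_numpy() @ np.vstack(
            [np.ones(len(Xraw)), Xraw.to_numpy().T]
        )
        np.testing.assert_allclose(eta_raw, fit_std.eta_fixed_, rtol=1e-10,
                                   atol=1e-10)
        # and an independent fit on the raw design lands at the same
        # optimum (up to optimizer tolerance)
        direct = BinomialGLMM().fit(
            Xraw, df["presence"].to_numpy(float),
            memberships={"feeder": feeder_memberships(df)},
        )
        got = raw_b[["intercept", "veg_cover_pct", "distance_m"]].to_numpy()
        want = direct.beta_[["intercept", "veg_z", "dist_z"]].to_numpy()
        np.testing.assert_allclose(got, want, rtol=2e-2, atol=1e-4)


class TestPooled:
    def test_self_comparison_gives_zero_deviance_change(self):
        stat, p = analysis_of_deviance(123.4, 123.4, 2.0, 2)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_mcfadden_zero_when_null_equals_full(self):
        assert mcfadden_r2(-500.0, -500.0) == 0.0

    def test_quasibinomial_pooled_fit(self, full_events, full_study):
        events, _ = full_events
        table = pooled_pair_table(events, full_study.stations)
        assert len(table) == 3 * 136
        assert table["count"].sum() == len(events)
        fit = fit_pooled(table, family="quasibinomial")
        assert fit.anova_df == 2
        assert fit.dispersion > 0
        assert 0 <= fit.mcfadden_r2 < 1
        assert fit.params["distance_m"] < 0  # movement decays with distance

    def test_quasipoisson_uses_positive_counts_only(self, full_events,
                                                    full_study):
        events, _ = full_events
        table = pooled_pair_table(events, full_study.stations)
        fit = fit_pooled(table, family="quasipoisson")
        assert fit.n_obs == int((table["count"] >= 1).sum())
        assert fit.dispersion > 1  # per-pair totals are overdispersed
        assert "pseudo-R2" in fit.report()

    def test_equidispersed_data_has_unit_dispersion(self, rng):
        """Poisson counts generated with no extra variation give a
        Pearson dispersion near 1."""
        n = 3000
        nets = rng.choice(["low", "medium", "high"], size=n)
        dist = rng.uniform(50, 400, size=n)
        # rates high enough that zeros (excluded downstream) are negligible
        lam = np.exp(2.5 + 0.3 * (nets == "low") - 0.002 * dist)
        counts = rng.poisson(lam)
        table = pd.DataFrame(
            {
                "network_id": nets,
                "feeder_a": "A",
                "feeder_b": "B",
                "distance_m": dist,
                "count": counts,
                "presence": 1,
            }
        )
        fit = fit_pooled(table, family="quasipoisson")
        assert fit.dispersion == pytest.approx(1.0, abs=0.15)

    def test_single_network_rejected(self, rng):
        table = pd.DataFrame(
            {
                "network_id": ["low"] * 10,
                "feeder_a": "A",
                "feeder_b": "B",
                "distance_m": rng.uniform(50, 300, 10),
                "count": rng.integers(0, 5, 10),
                "presence": rng.integers(0, 2, 10),
            }
        )
        with pytest.raises(ValidationError, match="2 networks"):
            fit_pooled(table)
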