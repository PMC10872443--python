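"""Reliability statistics: parameter recovery, oracles, pooling, properties."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from voxelrel.icc import (
    ICCEstimate,
    adjacent_pairs,
    fit_internal_consistency,
    fit_variance_components_2level,
    icc_oneway,
    icc_pair_from_components,
    multilevel_alpha,
    pool_icc_meta,
)
from voxelrel.synthetic import (
    VarianceComponents,
    generate_parcel_voxels,
    generate_predictor_panel,
)


def _pair_cells(sigma_part, sigma_eps, n, seed):
    """Two-session cell means with participant variance and error variance."""
    vc = VarianceComponents(0.0, (0.0, 0.0), sigma_part, 0.0, sigma_eps)
    panel = generate_parcel_voxels(vc, n, 2, 1, seed=seed)
    return panel.groupby(["participant", "session"])["value"].mean().reset_index()


class TestICCPairArithmetic:
    @pytest.mark.parametrize(
        "pi2,eps2,expected", [(0.0, 1.0, 0.0), (1.0, 0.0, 1.0), (1.0, 3.0, 0.25)]
    )
    def test_ratio(self, pi2, eps2, expected):
        assert icc_pair_from_components(pi2, eps2) == pytest.approx(expected)

    def test_drawwise_preserves_count(self):
        pi2 = np.linspace(0.1, 1.0, 57)
        out = icc_pair_from_components(pi2, np.ones(57))
        assert out.shape == (57,)

    def test_both_zero_undefined(self):
        with pytest.raises(ZeroDivisionError):
            icc_pair_from_components(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            icc_pair_from_components(-0.1, 1.0)


class TestTwoLevelFit:
    def test_null_participant_variance_gives_near_zero_icc(self):
        cells = _pair_cells(0.0, 1.0, 100, seed=1)
        est = fit_variance_components_2level(cells, (1, 2), seed=2)
        assert est.icc_median < 0.05

    def test_parameter_recovery_half(self):
        cells = _pair_cells(1.0, 1.0, 500, seed=2)
        est = fit_variance_components_2level(cells, (1, 2), seed=5)
        assert est.icc_median == pytest.approx(0.5, abs=0.05)
        assert 0 <= est.icc_median <= 1 and est.logit_sd >= 0

    def test_anova_oracle_agreement(self):
        cells = _pair_cells(0.8, 1.2, 60, seed=6)
        est = fit_variance_components_2level(cells, (1, 2), seed=7)
        clean = cells.copy()
        clean.attrs = {}
        oracle = pg.intraclass_corr(
            clean, targets="participant", raters="session", ratings="value"
        )
        icc3 = float(oracle.iloc[2]["ICC"])  # ICC(C,1): consistency
        assert est.icc_median == pytest.approx(icc3, abs=0.02)

    def test_reml_backend_agrees_with_posterior_median(self):
        cells = _pair_cells(1.0, 1.0, 200, seed=8)
        mcmc = fit_variance_components_2level(cells, (1, 2), seed=9)
        reml = fit_variance_components_2level(cells, (1, 2), backend="reml")
        assert abs(mcmc.icc_median - reml.icc_median) < 0.05

    def test_too_few_participants_rejected(self):
        cells = _pair_cells(1.0, 1.0, 2, seed=1)
        with pytest.raises(ValueError, match="participants"):
            fit_variance_components_2level(cells, (1, 2))

    def test_session_effects_conditioned_out(self):
        cells = _pair_cells(1.0, 1.0, 200, seed=10)
        shifted = cells.copy()
        shifted.loc[shifted["session"] == 2, "value"] += 10.0
        a = fit_variance_components_2level(cells, (1, 2), backend="reml")
        b = fit_variance_components_2level(shifted, (1, 2), backend="reml")
        assert a.icc_median == pytest.approx(b.icc_median, abs=1e-9)


class TestPooling:
    @staticmethod
    def _estimate(icc, sd, pair):
        logit = float(np.log(icc / (1 - icc)))
        return ICCEstimate(
            pair=pair, icc_median=icc, logit_median=logit, logit_sd=sd,
            sigma_pi2=1.0, sigma_eps2=1.0,
        )

    def test_homogeneous_inputs_pool_to_common_value(self):
        ests = [self._estimate(0.30, 0.01, (i, i + 1)) for i in range(1, 10)]
        pooled = pool_icc_meta(ests, seed=1)
        assert pooled.icc_median == pytest.approx(0.30, abs=0.01)

    def test_pooled_median_within_input_range(self):
        rng = np.random.default_rng(2)
        iccs = rng.uniform(0.1, 0.6, size=8)
        ests = [self._estimate(v, 0.2, (i, i + 1)) for i, v in enumerate(iccs)]
        pooled = pool_icc_meta(ests, seed=3)
        assert iccs.min() - 0.02 <= pooled.icc_median <= iccs.max() + 0.02

    def test_fixed_effect_matches_inverse_variance_oracle(self):
        iccs = [0.2, 0.3, 0.4, 0.25]
        sds = [0.1, 0.2, 0.15, 0.3]
        ests = [self._estimate(v, s, (i, i + 1)) for i, (v, s) in enumerate(zip(iccs, sds))]
        pooled = pool_icc_meta(ests, fixed_effect=True)
        d = np.log(np.array(iccs) / (1 - np.array(iccs)))
        w = 1 / np.array(sds) ** 2
        mu = np.sum(w * d) / np.sum(w)
        oracle = 1 / (1 + np.exp(-mu))
        assert pooled.icc_median == pytest.approx(oracle, abs=0.01)

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError):
            pool_icc_meta([self._estimate(0.3, 0.1, (1, 2))])

    def test_nonfinite_se_rejected(self):
        ests = [self._estimate(0.3, 0.1, (1, 2)),
                self._estimate(0.3, float("nan"), (2, 3))]
        with pytest.raises(ValueError):
            pool_icc_meta(ests)


class TestAdjacentPairs:
    def test_overlapping_default(self):
        assert adjacent_pairs([1, 2, 3, 4]) == [(1, 2), (2, 3), (3, 4)]

    def test_disjoint_option(self):
        assert adjacent_pairs(range(1, 11), disjoint=True) == [
            (1, 2), (3, 4), (5, 6), (7, 8), (9, 10)
        ]


class TestInternalConsistency:
    def test_component_recovery_one_quarter(self, three_level_panel):
        est = fit_internal_consistency(three_level_panel, seed=3)
        assert est.icc_median == pytest.approx(0.25, abs=0.04)
        assert est.icc_ci[0] < est.icc_median < est.icc_ci[1]

    def test_reml_matches_mcmc_on_balanced_data(self, three_level_panel):
        mcmc = fit_internal_consistency(three_level_panel, seed=4)
        reml = fit_internal_consistency(three_level_panel, backend="reml")
        assert abs(mcmc.icc_median - reml.icc_median) < 0.05

    def test_null_session_variance_gives_near_zero(self):
        vc = VarianceComponents(0.0, tuple(np.zeros(6)), 1.0, 0.0, 1.0)
        panel = generate_parcel_voxels(vc, 40, 6, 20, seed=5)
        est = fit_internal_consistency(panel, backend="reml")
        assert est.icc_median < 0.05

    def test_single_voxel_rejected(self):
        vc = VarianceComponents.linear_habituation(3)
        panel = generate_parcel_voxels(vc, 5, 3, 1, seed=0)
        with pytest.raises(ValueError, match="voxels"):
            fit_internal_consistency(panel)

    def test_subsampled_voxels_track_full_parcel_estimates(self):
        # 15-voxel subsets vs all 50 voxels across 30 simulated parcels
        rng = np.random.default_rng(12)
        full, sub = [], []
        for r in range(30):
            pi2 = float(rng.uniform(0.1, 1.0))
            vc = VarianceComponents(0.0, tuple(np.zeros(8)), 0.2, pi2, 0.8)
            panel = generate_parcel_voxels(vc, 30, 8, 50, seed=300 + r)
            full.append(fit_internal_consistency(panel, backend="reml").icc_median)
            keep = rng.choice(np.arange(1, 51), size=15, replace=False)
            panel15 = panel[panel["voxel"].isin(keep)]
            sub.append(fit_internal_consistency(panel15, backend="reml").icc_median)
        assert np.corrcoef(full, sub)[0, 1] >= 0.9

    def test_monotone_in_session_variance(self):
        meds = []
        for pi2 in (0.2, 0.6, 1.2):
            vc = VarianceComponents(0.0, tuple(np.zeros(6)), 0.3, pi2, 1.0)
            panel = generate_parcel_voxels(vc, 40, 6, 25, seed=77)
            meds.append(fit_internal_consistency(panel, backend="reml").icc_median)
        assert meds[0] < meds[1] < meds[2]

    def test_credible_interval_calibration(self):
        # 95% CI covers the true value 0.4 in >= 88 of 100 parcels
        hits = 0
        vc = VarianceComponents(0.0, tuple(np.zeros(10)), 0.1, 0.4, 0.5)
        for r in range(100):
            panel = generate_parcel_voxels(vc, 30, 10, 20, seed=4000 + r)
            est = fit_internal_consistency(panel, seed=r, n_draws=1000)
            if est.icc_ci[0] <= 0.4 <= est.icc_ci[1]:
                hits += 1
        assert hits >= 88


class TestAlpha:
    def test_worked_value(self):
        assert multilevel_alpha(1, 1, 2, 2).alpha == pytest.approx(1 / 3)

    def test_large_k_limit(self):
        assert multilevel_alpha(1, 1, 2, 10**6).alpha == pytest.approx(0.5, abs=1e-5)

    def test_k_one_reproduces_raw_share(self):
        assert multilevel_alpha(1, 1, 2, 1).alpha == pytest.approx(0.25)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            multilevel_alpha(1, 1, 2, 0)


class TestOneWayICC:
    def test_zero_within_variance_gives_one(self):
        df = pd.DataFrame(
            {"participant": np.repeat([1, 2, 3], 4),
             "x": np.repeat([1.0, 2.0, 3.0], 4)}
        )
        # add microscopic within noise to avoid the degenerate error
        df["x"] += np.tile([0, 1e-9, -1e-9, 0], 3)
        assert icc_oneway(df) == pytest.approx(1.0, abs=1e-6)

    def test_half_split_recovery(self):
        panel = generate_predictor_panel(1.0, 1.0, 500, 10, seed=3)
        assert icc_oneway(panel) == pytest.approx(0.5, abs=0.05)

    def test_matches_anova_oracle(self):
        panel = generate_predictor_panel(0.8, 1.3, 40, 6, seed=5)
        clean = panel.copy()
        clean.attrs = {}
        oracle = pg.intraclass_corr(
            clean, targets="participant", raters="session", ratings="x"
        )
        assert icc_oneway(panel) == pytest.approx(float(oracle.iloc[0]["ICC"]), abs=0.02)

    def test_constant_data_degenerate(self):
        df = pd.DataFrame({"participant": np.repeat([1, 2, 3], 3), "x": 1.0})
        with pytest.raises(ValueError):
            icc_oneway(df)
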