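"""Permutation tests, effect sizes, bootstrap intervals, power, density."""

import numpy as np
import pandas as pd
import pytest

from oracles import permutation_p_exhaustive, power_t2n_quadrature
from synaptomap.statistics import (
    bca_ci,
    bca_ci_two_sample,
    cluster_correlation_matrices,
    cohens_d,
    compare_conditions,
    dendrite_length_um,
    permutation_t_test,
    power_t2n,
    synapse_density,
)
from synaptomap.synthetic_data import SynthConfig


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        res = permutation_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration(self):
        a, b = [10.0, 11.0, 12.0], [0.0, 1.0, 2.0]
        res = permutation_t_test(a, b, seed=0)
        assert res.exact
        assert res.p_value == pytest.approx(permutation_p_exhaustive(a, b))
        assert res.p_value == pytest.approx(2 / 20)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_groups_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.4, 1.0, size=rng.integers(3, 6))
        b = rng.normal(0.0, 1.0, size=rng.integers(3, 6))
        res = permutation_t_test(a, b, seed=seed)
        assert res.exact  # total size <= 12 enumerates exhaustively
        assert res.p_value == pytest.approx(permutation_p_exhaustive(a, b))

    def test_exchangeability_of_labels(self):
        """Swapping the two groups flips the observed sign, not the p."""
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 1, 5), rng.normal(0, 1, 6)
        r1 = permutation_t_test(a, b, seed=9)
        r2 = permutation_t_test(b, a, seed=9)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.observed == pytest.approx(-r2.observed)

    def test_ci_brackets_observed_difference(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(2, 0.5, 6), rng.normal(0, 0.5, 5)
        res = permutation_t_test(a, b, seed=1)
        assert res.ci_low <= res.observed <= res.ci_high

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            permutation_t_test([1.0], [2.0, 3.0])


class TestCohensD:
    def test_hand_computed_example(self):
        # pooled sd of {0,2} and {2,4} is sqrt(2); d = -2/sqrt(2)
        assert cohens_d([0.0, 2.0], [2.0, 4.0]) == pytest.approx(-np.sqrt(2.0))

    def test_identical_groups_zero(self):
        assert cohens_d([0.0, 2.0], [0.0, 2.0]) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 1, 6), rng.normal(0, 1, 5)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestBcaCi:
    def test_constant_data_degenerates_to_point(self):
        lo, hi = bca_ci(np.full(10, 3.3), np.mean, seed=0)
        assert lo == hi == pytest.approx(3.3)

    def test_symmetric_case_close_to_percentile_interval(self):
        """With no bias or skew the BCa adjustments vanish and the interval
        matches the plain percentile bootstrap within Monte-Carlo error."""
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, 60)
        data = np.concatenate([data, -data])  # exactly symmetric sample
        lo, hi = bca_ci(data, np.mean, n_boot=4000, seed=5)
        boot = np.array([
            rng.choice(data, size=data.size, replace=True).mean()
            for _ in range(4000)
        ])
        plo, phi = np.percentile(boot, [2.5, 97.5])
        width = phi - plo
        assert lo == pytest.approx(plo, abs=0.15 * width)
        assert hi == pytest.approx(phi, abs=0.15 * width)

    def test_coverage_of_the_mean(self):
        """BCa coverage for the mean of Normal(0,1) samples of size 20 over
        1000 simulations stays near the nominal 95%."""
        rng = np.random.default_rng(123)
        hits = 0
        n_sim = 1000
        for i in range(n_sim):
            data = rng.normal(0, 1, 20)
            lo, hi = bca_ci(data, np.mean, n_boot=1000, seed=int(rng.integers(2**31)))
            hits += lo <= 0.0 <= hi
        assert 0.90 <= hits / n_sim <= 0.98

    def test_two_sample_interval_brackets_estimate(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 6), rng.normal(0, 1, 5)
        d = cohens_d(a, b)
        lo, hi = bca_ci_two_sample(a, b, cohens_d, n_boot=2000, seed=3)
        assert lo <= d <= hi


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert power_t2n(0.0, 6, 5) == pytest.approx(0.05, abs=1e-9)

    def test_huge_effect_power_approaches_one(self):
        assert power_t2n(10.0, 6, 5) > 0.999

    def test_matches_quadrature_oracle(self):
        for d, n1, n2 in [(1.0, 6, 5), (0.5, 10, 8), (2.0, 4, 4)]:
            assert power_t2n(d, n1, n2) == pytest.approx(
                power_t2n_quadrature(d, n1, n2), abs=1e-4
            )

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            power_t2n(1.0, 1, 5)


class TestCorrelationMatrices:
    def _table(self, n=200, proportional=True, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(0, 0.4, n)
        rows = {
            "replicate": np.repeat(np.arange(4), n // 4),
            "IntegratedIntensity__Synapsin1__vGlut1": x,
            "IntegratedIntensity__Synapsin1__PSD95": (
                2.0 * x if proportional else rng.lognormal(0, 0.4, n)
            ),
            "IntegratedIntensity__Synapsin1__Synapsin1": rng.lognormal(0, 0.4, n),
        }
        return pd.DataFrame(rows)

    def test_proportional_targets_fully_correlated_and_unmasked(self):
        summ = cluster_correlation_matrices(self._table(proportional=True))[0]
        assert summ.averaged.loc["vGlut1", "PSD95"] == pytest.approx(1.0)
        assert summ.masked.loc["vGlut1", "PSD95"] == pytest.approx(1.0)

    def test_independent_targets_masked(self):
        summ = cluster_correlation_matrices(self._table(proportional=False))[0]
        assert np.isnan(summ.masked.loc["vGlut1", "PSD95"])

    def test_diagonal_always_one_and_never_masked(self):
        summ = cluster_correlation_matrices(self._table())[0]
        assert np.allclose(np.diag(summ.averaged), 1.0)
        assert np.allclose(np.diag(summ.masked), 1.0)

    def test_averaged_is_elementwise_mean_of_replicates(self):
        summ = cluster_correlation_matrices(self._table(proportional=False))[0]
        stack = np.stack([m.to_numpy() for m in summ.per_replicate.values()])
        np.testing.assert_allclose(
            np.nanmean(stack, axis=0), summ.averaged.to_numpy(), atol=1e-12
        )


class TestDensity:
    def test_ten_synapses_on_twenty_micron_skeleton(self):
        mask = np.zeros((5, 200), bool)
        n_px = int(round(20.0 / 0.187)) + 1
        mask[2, 10 : 10 + n_px] = True
        out = synapse_density(10, mask, pixel_size_um=0.187)
        assert out["density_all"] == pytest.approx(100 * 10 / out["length_um"])
        assert out["length_um"] == pytest.approx(n_px * 0.187)

    def test_straight_dendrite_107_pixels(self):
        mask = np.zeros((3, 120), bool)
        mask[1, 5:112] = True  # 107 px straight line
        assert dendrite_length_um(mask, 0.187) == pytest.approx(20.009)

    def test_diagonal_runs_weighted_sqrt2(self):
        mask = np.zeros((40, 40), bool)
        idx = np.arange(5, 35)
        mask[idx, idx] = True  # 30 px pure diagonal
        got = dendrite_length_um(mask, 1.0)
        assert got == pytest.approx(30 + (np.sqrt(2) - 1) * 29)

    def test_axial_tiling_preserves_total_length(self):
        mask = np.zeros((9, 300), bool)
        mask[4, 10:290] = True
        whole = dendrite_length_um(mask, 0.187)
        left = dendrite_length_um(mask[:, :150], 0.187)
        right = dendrite_length_um(mask[:, 150:], 0.187)
        assert whole == pytest.approx(left + right)

    def test_generator_field_length_within_ten_percent_of_truth(
        self, processed_default_field
    ):
        proc, truth, _ = processed_default_field
        got = dendrite_length_um(proc.dendrite_mask, 0.187)
        want = truth.fields["skeleton_length_um"].iloc[0]
        assert got == pytest.approx(want, rel=0.10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dendrite_length_um(np.zeros((5, 5), bool))


class TestCompareConditions:
    def _truth_table(self, seed, effects=None, fields=2):
        from synaptomap.feature_extraction import FeatureTable, normalize_to_untreated
        from synaptomap.synthetic_data import (
            generate_truth_cohort,
            truth_intensity_table,
        )

        config = SynthConfig(
            seed=seed, fields_per_replicate=fields,
            treatment_effects=effects or {},
        )
        tab = truth_intensity_table(generate_truth_cohort(config))
        return normalize_to_untreated(FeatureTable(tab)).data

    def test_row_count_is_targets_times_scopes(self):
        table = self._truth_table(seed=1)
        out = compare_conditions(table, n_shuffles=500, n_boot=200, seed=0)
        assert len(out) == 11 * 2  # all targets x {excitatory, inhibitory}
        assert set(out["scope"]) == {"excitatory", "inhibitory"}

    def test_injected_effect_detected(self):
        table = self._truth_table(seed=5, effects={"vGlut1": 1.5}, fields=3)
        out = compare_conditions(table, n_shuffles=2000, n_boot=200, seed=2)
        row = out[(out["target"] == "vGlut1") & (out["scope"] == "excitatory")]
        assert row["p_value"].iloc[0] < 0.05
        assert row["observed_difference"].iloc[0] < 0  # untreated minus treated
        assert row["cohens_d"].iloc[0] < 0

    def test_density_battery_runs_per_cluster(self):
        densities = pd.DataFrame(
            {
                "replicate": list(range(6)) * 1 + list(range(6, 11)),
                "treatment": ["untreated"] * 6 + ["treated"] * 5,
                "cluster": [1] * 11,
                "density": np.concatenate(
                    [np.random.default_rng(0).normal(50, 4, 6),
                     np.random.default_rng(1).normal(30, 4, 5)]
                ),
            }
        )
        table = self._truth_table(seed=2)
        out = compare_conditions(
            table, densities=densities, n_shuffles=500, n_boot=200, seed=0
        )
        dens_rows = out[out["target"] == "synapse_density"]
        assert len(dens_rows) == 1
        assert dens_rows["p_value"].iloc[0] < 0.05
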