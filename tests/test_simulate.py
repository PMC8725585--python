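import numpy as np
import pytest

from vanadiome.nestedness import nodf, nodf_test
from vanadiome.simulate import (
    ScenarioSpec,
    make_nested_matrix,
    simulate_neutral_community,
    simulate_niche_community,
    simulate_scenario,
)


class TestNeutralUrn:
    def test_zero_sum_constraint(self):
        for s in range(10):
            c = simulate_neutral_community(5.0, 0.4, 200, seed=s)
            assert c.sum() == 200
            assert (c > 0).all()

    def test_reproducible_by_seed(self):
        a = simulate_neutral_community(5.0, 0.4, 300, seed=42)
        b = simulate_neutral_community(5.0, 0.4, 300, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_mean_species_count_matches_ewens_expectation(self):
        # at m=1 the urn is the Ewens process: E[S] = sum theta/(theta+i-1)
        theta, J, reps = 5.0, 100, 2000
        expected = sum(theta / (theta + i) for i in range(J))
        rng = np.random.default_rng(0)
        S = [len(simulate_neutral_community(theta, 1.0, J, seed=rng))
             for _ in range(reps)]
        se = np.std(S, ddof=1) / np.sqrt(reps)
        assert np.mean(S) == pytest.approx(expected, abs=4 * se + 0.05)

    def test_richness_increases_with_theta(self):
        rng = np.random.default_rng(1)
        means = []
        for theta in (1.0, 5.0, 25.0):
            S = [len(simulate_neutral_community(theta, 0.5, 300, seed=rng))
                 for _ in range(60)]
            means.append(np.mean(S))
        assert means[0] < means[1] < means[2]

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            simulate_neutral_community(0.0, 0.5, 100)
        with pytest.raises(ValueError):
            simulate_neutral_community(1.0, 1.5, 100)
        with pytest.raises(ValueError):
            simulate_neutral_community(1.0, 0.5, 1)


class TestNicheCommunities:
    def test_preemption_mean_proportions(self):
        # alpha=0.5, S=2: expected proportions (2/3, 1/3)
        rng = np.random.default_rng(2)
        tops = []
        for _ in range(300):
            c = simulate_niche_community("preemption", {"alpha": 0.5}, 2, 300,
                                         seed=rng)
            tops.append(max(c) / 300)
        assert np.mean(tops) == pytest.approx(2 / 3, abs=0.02)

    def test_J_conserved(self):
        c = simulate_niche_community("zipf", {"p1": 0.3, "gamma": -0.8}, 30, 1234,
                                     seed=3)
        assert c.sum() == 1234

    def test_steep_zipf_dominance(self):
        c = simulate_niche_community("zipf", {"p1": 0.9, "gamma": -3.0}, 20, 5000,
                                     seed=4)
        assert max(c) / 5000 > 0.8

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_niche_community("preemption", {"alpha": 0.0}, 5, 100, seed=0)


class TestNestedMatrix:
    def test_noiseless_is_perfectly_nested(self):
        # distinct row AND column fills: every pair is a strict subset pair
        M = make_nested_matrix(5, [5, 4, 3, 2, 1], noise=0.0, seed=0)
        assert nodf(M).nodf_total == pytest.approx(100.0)
        np.testing.assert_array_equal(M.sum(axis=1), [5, 4, 3, 2, 1])
        # stepped profiles tie some column fills, which score 0 by definition
        M2 = make_nested_matrix(5, [10, 8, 6, 4, 2], noise=0.0, seed=0)
        res = nodf(M2)
        assert res.nodf_rows == pytest.approx(100.0)
        assert res.nodf_cols < 100.0

    def test_full_noise_indistinguishable_from_null(self):
        rejections = 0
        for s in range(10):
            M = make_nested_matrix(8, list(range(18, 2, -2)), noise=1.0, seed=s,
                                   n_features=60)
            res = nodf_test(M, "equiprobable", n=99, seed=100 + s)
            rejections += res.nested
        assert rejections <= 2

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="decreasing"):
            make_nested_matrix(3, [4, 4, 2], noise=0.0)
        with pytest.raises(ValueError):
            make_nested_matrix(2, [5, 2], n_features=3)


class TestScenario:
    def test_structure_of_outputs(self):
        taxon, gene, meta, truth = simulate_scenario(ScenarioSpec(seed=0))
        assert taxon.mode == "counts" and gene.mode == "relative"
        # 12 group labels (4 baselines + 2 habitats x 4 doses) x 3 replicates
        assert taxon.n_samples == gene.n_samples == len(meta) == 36
        assert set(meta["group_label"]) == {
            "G0", "G21", "S0", "S21",
            "GV0", "GV1", "GV2", "GV3", "SV0", "SV1", "SV2", "SV3",
        }
        assert (taxon.data.sum(axis=1) == 20000).all()
        np.testing.assert_allclose(gene.abundance.sum(axis=1), 1.0, atol=1e-9)
        assert set(truth["vdg_catalog"].values()) <= {
            "reductive_metabolism", "transporter_efflux", "oxidative_damage_repair"
        }
        assert truth["expected"]["largest_abiotic_effect"] == "NH4_N"

    def test_bit_reproducible(self):
        a = simulate_scenario(ScenarioSpec(seed=7))
        b = simulate_scenario(ScenarioSpec(seed=7))
        assert a[0].data.equals(b[0].data)
        assert a[1].data.equals(b[1].data)
        assert a[2].equals(b[2])

    def test_null_scenario_has_no_dose_effect(self):
        from vanadiome.diversity import alpha_diversity, gradient_correlation

        spec = ScenarioSpec(seed=3, turnover_gut=0.0, turnover_soil=0.0,
                            richness_decline=0.0, evenness_decline=0.0)
        taxon, _, meta, _ = simulate_scenario(spec)
        ids = [s for s in meta.index if "V" in meta.loc[s, "group_label"]]
        div = alpha_diversity(taxon.subset_samples(ids))
        r, p = gradient_correlation(div["shannon_H"].to_numpy(),
                                    meta.loc[ids, "dose"].to_numpy())
        assert p > 0.01  # no systematic alpha trend without the dose mechanisms

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="redundancy"):
            ScenarioSpec(redundancy_soil=1000)
        with pytest.raises(ValueError, match="core"):
            ScenarioSpec(n_core=200, n_active=150)

    def test_nh4_has_largest_abiotic_dose_effect(self):
        from scipy.stats import pearsonr

        _, _, meta, _ = simulate_scenario(ScenarioSpec(seed=1))
        ids = [s for s in meta.index if "V" in meta.loc[s, "group_label"]]
        doses = meta.loc[ids, "dose"]
        slopes = {
            f: abs(pearsonr(meta.loc[ids, f], doses)[0])
            for f in ("pH", "TN", "NO3_N", "NH4_N", "TC", "AP", "AHN", "AS")
        }
        assert max(slopes, key=slopes.get) == "NH4_N"
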