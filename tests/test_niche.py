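import numpy as np
import pandas as pd
import pytest

from vanadiome.niche import levins_breadth, screen_vdg, vdg_carrier_summary
from vanadiome.simulate import simulate_vdg_generalist_tables
from vanadiome.tables import CommunityTable, VDGCatalog


def _table(values, index=None, columns=None, **kw):
    df = pd.DataFrame(values, index=index, columns=columns, dtype=float)
    return CommunityTable(df, **kw)


class TestLevinsBreadth:
    def test_uniform_feature_has_B_equal_N(self):
        N = 12
        t = _table(np.ones((N, 2)), index=[f"s{i}" for i in range(N)],
                   columns=["u", "v"])
        res = levins_breadth(t)
        assert res.per_feature["u"] == pytest.approx(N, abs=1e-9)
        assert res.N == N

    def test_single_community_feature_has_B_1(self):
        vals = np.zeros((5, 1))
        vals[2, 0] = 7
        t = _table(vals, index=[f"s{i}" for i in range(5)], columns=["x"])
        assert levins_breadth(t).per_feature["x"] == pytest.approx(1.0)

    def test_half_half_gives_2(self):
        vals = np.zeros((4, 1))
        vals[0, 0] = 3
        vals[1, 0] = 3
        t = _table(vals, index=list("abcd"), columns=["x"])
        assert levins_breadth(t).per_feature["x"] == pytest.approx(2.0)

    def test_scaling_a_community_total_changes_nothing_uniform(self):
        # P is normalised per feature, so B is driven by the feature's own
        # distribution, invariant to multiplying a feature column by a constant
        vals = np.array([[2.0, 4.0], [2.0, 4.0], [2.0, 4.0]])
        t = _table(vals, index=list("abc"), columns=["u", "v"])
        res = levins_breadth(t)
        assert res.per_feature["u"] == pytest.approx(res.per_feature["v"])

    def test_absent_feature_rejected(self):
        t = _table([[1, 0], [1, 0]], index=["a", "b"], columns=["u", "v"])
        with pytest.raises(ValueError, match="absent"):
            levins_breadth(t)

    def test_community_mean_over_present_features(self):
        vals = np.array([[1.0, 1.0], [1.0, 0.0]])
        t = _table(vals, index=["a", "b"], columns=["u", "v"])
        res = levins_breadth(t)
        # u even over 2 communities (B=2), v only in a (B=1)
        assert res.community_mean["a"] == pytest.approx(1.5)
        assert res.community_mean["b"] == pytest.approx(2.0)


class TestScreenVDG:
    def _gene_table(self):
        df = pd.DataFrame(
            [[5, 3, 2, 10], [1, 1, 8, 10]],
            index=["s1", "s2"], columns=["K1", "K2", "K3", "K4"], dtype=float,
        )
        return CommunityTable(df, feature_kind="gene", mode="counts")

    def test_subtable_and_warning_for_missing_ko(self):
        cat = VDGCatalog({"K1": "reductive_metabolism", "K3": "transporter_efflux",
                          "K9": "oxidative_damage_repair"})
        with pytest.warns(UserWarning, match="K9"):
            sub, per_sample = screen_vdg(self._gene_table(), cat)
        assert sub.feature_ids == ["K1", "K3"]
        # abundances are untouched copies
        assert sub.data.loc["s1", "K1"] == 5
        assert per_sample.loc["s1", "vdg_total"] == 7
        assert per_sample.loc["s1", "vdg_proportion"] == pytest.approx(7 / 20)
        assert ((per_sample["vdg_proportion"] >= 0)
                & (per_sample["vdg_proportion"] <= 1)).all()

    def test_empty_intersection_rejected(self):
        cat = VDGCatalog({"K9": "reductive_metabolism"})
        with pytest.raises(ValueError, match="no catalog KO"):
            screen_vdg(self._gene_table(), cat)


class TestCarrierSummary:
    def test_symmetric_habitats_share_50_50(self):
        taxa = pd.DataFrame(
            [[4, 2, 1], [4, 2, 1], [4, 2, 1], [4, 2, 1]],
            index=["g1", "g2", "s1", "s2"], columns=["t1", "t2", "t3"], dtype=float,
        )
        genes = pd.DataFrame(
            [[3, 1]] * 4, index=taxa.index, columns=["K1", "K2"], dtype=float
        )
        meta = pd.DataFrame(
            {
                "habitat": ["gut", "gut", "soil", "soil"],
                "dose": [0.0] * 4,
                "replicate": [1, 2, 1, 2],
                "group_label": ["G0", "G0", "S0", "S0"],
            },
            index=taxa.index,
        )
        cat = VDGCatalog({"K1": "reductive_metabolism"})
        summary = vdg_carrier_summary(
            CommunityTable(taxa), ["t1"], CommunityTable(genes, feature_kind="gene"),
            cat, meta,
        )
        np.testing.assert_allclose(summary.habitat_shares.to_numpy(), 50.0)
        np.testing.assert_allclose(summary.habitat_shares.sum(axis=0), 100.0,
                                   atol=1e-9)

    def test_soil_generalist_fixture_breadth_contrast(self):
        for seed in range(5):
            table, meta, carriers = simulate_vdg_generalist_tables(seed=seed)
            genes = pd.DataFrame(
                np.ones((table.n_samples, 1)), index=table.data.index, columns=["K1"]
            )
            cat = VDGCatalog({"K1": "reductive_metabolism"})
            summary = vdg_carrier_summary(
                table, carriers, CommunityTable(genes, feature_kind="gene"), cat, meta
            )
            assert summary.carrier_breadth["soil"] > summary.carrier_breadth["gut"]

    def test_empty_carrier_set_rejected(self):
        taxa = _table([[1, 1], [1, 1]], index=["a", "b"], columns=["t1", "t2"])
        genes = CommunityTable(
            pd.DataFrame([[1.0], [1.0]], index=["a", "b"], columns=["K1"]),
            feature_kind="gene",
        )
        meta = pd.DataFrame(
            {"habitat": ["gut", "soil"], "dose": [0, 0], "replicate": [1, 1],
             "group_label": ["G0", "S0"]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="carrier"):
            vdg_carrier_summary(taxa, ["zzz"], genes,
                                VDGCatalog({"K1": "reductive_metabolism"}), meta)
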