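"""Phenotypic difference index: group-wise PCC differences per position."""

import numpy as np
import pandas as pd
import pytest

import stpheno as sp


def make_pcc(values, samples, positions):
    df = pd.DataFrame(values, index=samples, columns=positions, dtype=float)
    return sp.PCCMap(values=df, undefined=df.isna(), n_genes_used=10, min_overlap=1)


def make_groups(assignments):
    """assignments: {sample: (condition, timepoint)}"""
    return pd.DataFrame(
        {
            "condition": {s: c for s, (c, t) in assignments.items()},
            "timepoint": {s: t for s, (c, t) in assignments.items()},
        }
    )


class TestComputePdi:
    def test_identical_groups_give_zero_everywhere(self):
        rows = [[0.3, -0.2, 0.8]] * 4
        pcc = make_pcc(rows, ["a1", "a2", "b1", "b2"], ["P1", "P2", "P3"])
        groups = make_groups({
            "a1": ("KO", "D3"), "a2": ("KO", "D3"),
            "b1": ("WT", "D3"), "b2": ("WT", "D3"),
        })
        pdi = sp.compute_pdi(pcc, groups, [("KO", "WT")])
        np.testing.assert_allclose(pdi.values.to_numpy(), 0.0)

    def test_extreme_opposition_hits_plus_two(self):
        pcc = make_pcc([[1.0], [-1.0]], ["ko1", "wt1"], ["P1"])
        groups = make_groups({"ko1": ("KO", "D3"), "wt1": ("WT", "D3")})
        pdi = sp.compute_pdi(pcc, groups, [("KO", "WT")])
        assert pdi.values.loc["P1", "KO_D3_vs_WT_D3"] == pytest.approx(2.0)

    def test_swapping_roles_negates(self):
        rng = np.random.default_rng(3)
        rows = rng.uniform(-1, 1, size=(4, 5))
        samples = ["k1", "k2", "w1", "w2"]
        pcc = make_pcc(rows, samples, [f"P{i}" for i in range(5)])
        groups = make_groups({
            "k1": ("KO", "D1"), "k2": ("KO", "D1"),
            "w1": ("WT", "D1"), "w2": ("WT", "D1"),
        })
        fwd = sp.compute_pdi(pcc, groups, [("KO", "WT")])
        rev = sp.compute_pdi(pcc, groups, [("WT", "KO")])
        np.testing.assert_allclose(
            fwd.values.to_numpy(), -rev.values.to_numpy()
        )

    def test_mean_aggregation_matches_replicate_loop(self):
        rng = np.random.default_rng(9)
        n_k, n_w, n_pos = 3, 4, 6
        rows = rng.uniform(-1, 1, size=(n_k + n_w, n_pos))
        samples = [f"k{i}" for i in range(n_k)] + [f"w{i}" for i in range(n_w)]
        pcc = make_pcc(rows, samples, [f"P{i}" for i in range(n_pos)])
        groups = make_groups(
            {s: ("KO" if s.startswith("k") else "WT", "D2") for s in samples}
        )
        pdi = sp.compute_pdi(pcc, groups, [("KO", "WT")])
        # brute-force loop over replicates
        for j in range(n_pos):
            expected = rows[:n_k, j].sum() / n_k - rows[n_k:, j].sum() / n_w
            got = pdi.values.iloc[j, 0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_timepoints_matched_within_comparison(self):
        pcc = make_pcc(
            [[0.9], [0.1], [0.8], [0.2]],
            ["k_d1", "k_d2", "w_d1", "w_d2"], ["P1"],
        )
        groups = make_groups({
            "k_d1": ("KO", "D1"), "k_d2": ("KO", "D2"),
            "w_d1": ("WT", "D1"), "w_d2": ("WT", "D2"),
        })
        pdi = sp.compute_pdi(pcc, groups, [("KO", "WT")])
        assert set(pdi.labels) == {"KO_D1_vs_WT_D1", "KO_D2_vs_WT_D2"}
        assert pdi.values.loc["P1", "KO_D1_vs_WT_D1"] == pytest.approx(0.1)
        assert pdi.values.loc["P1", "KO_D2_vs_WT_D2"] == pytest.approx(-0.1)

    def test_one_sided_timepoint_skipped_with_warning(self, caplog):
        pcc = make_pcc([[0.9], [0.8], [0.2]], ["k1", "k2", "w1"], ["P1"])
        groups = make_groups({
            "k1": ("KO", "D1"), "k2": ("KO", "D9"), "w1": ("WT", "D1"),
        })
        with caplog.at_level("WARNING", logger="stpheno"):
            pdi = sp.compute_pdi(pcc, groups, [("KO", "WT")])
        assert list(pdi.labels) == ["KO_D1_vs_WT_D1"]
        assert any("D9" in r.message for r in caplog.records)

    def test_missing_condition_is_error(self):
        pcc = make_pcc([[0.9]], ["k1"], ["P1"])
        groups = make_groups({"k1": ("KO", "D1")})
        with pytest.raises(sp.StphenoError, match="WT"):
            sp.compute_pdi(pcc, groups, [("KO", "WT")])

    def test_undefined_cells_excluded_from_means(self, caplog):
        pcc = make_pcc(
            [[0.6], [np.nan], [0.2]], ["k1", "k2", "w1"], ["P1"]
        )
        groups = make_groups({
            "k1": ("KO", "D1"), "k2": ("KO", "D1"), "w1": ("WT", "D1"),
        })
        with caplog.at_level("WARNING", logger="stpheno"):
            pdi = sp.compute_pdi(pcc, groups, [("KO", "WT")])
        assert pdi.values.loc["P1"].iloc[0] == pytest.approx(0.4)
        assert any("undefined" in r.message for r in caplog.records)

    def test_bounds_on_random_maps(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            rows = rng.uniform(-1, 1, size=(6, 8))
            samples = [f"s{i}" for i in range(6)]
            pcc = make_pcc(rows, samples, [f"P{i}" for i in range(8)])
            groups = make_groups(
                {s: ("KO" if i < 3 else "WT", "D1")
                 for i, s in enumerate(samples)}
            )
            pdi = sp.compute_pdi(pcc, groups, [("KO", "WT")])
            arr = pdi.values.to_numpy()
            assert (np.abs(arr) <= 2.0).all()


class TestPooledProfileAggregation:
    def test_pooled_equals_mean_for_identical_replicates(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        atlas_vals = rng.uniform(0, 6, size=(20, 3))
        expr = sp.ExpressionMatrix(
            pd.DataFrame(atlas_vals, index=genes, columns=["P1", "P2", "P3"]),
            "log2TPM1",
        )
        meta = pd.DataFrame(
            {
                "stage": "E7.5", "section_index": [0, 1, 2],
                "domain_code": ["A", "P", "MA"],
                "layout_row": [0, 1, 2], "layout_col": 0,
            },
            index=pd.Index(["P1", "P2", "P3"], name="position_id"),
        )
        atlas = sp.AtlasReference(expr, meta)
        features = sp.FeatureGeneSet(frozenset(genes), "t")
        prof_k = rng.uniform(0, 6, 20)
        prof_w = rng.uniform(0, 6, 20)
        bulk_vals = np.column_stack([prof_k, prof_k, prof_w, prof_w])
        ann = pd.DataFrame(
            {"condition": ["KO", "KO", "WT", "WT"],
             "timepoint": "D1", "replicate": ["r1", "r2", "r1", "r2"]},
            index=["k1", "k2", "w1", "w2"],
        )
        bulk = sp.ExpressionMatrix(
            pd.DataFrame(bulk_vals, index=genes,
                         columns=["k1", "k2", "w1", "w2"]),
            "log2TPM1", ann,
        )
        pcc = sp.map_samples(bulk, atlas, features, min_overlap=5)
        mean_pdi = sp.compute_pdi(pcc, ann, [("KO", "WT")])
        pooled_pdi = sp.compute_pdi(
            pcc, ann, [("KO", "WT")], "pooled_profile",
            bulk=bulk, atlas=atlas, features=features, min_overlap=5,
        )
        np.testing.assert_allclose(
            mean_pdi.values.to_numpy(), pooled_pdi.values.to_numpy(), atol=1e-12
        )

    def test_pooled_requires_expression_inputs(self):
        pcc = make_pcc([[0.5], [0.1]], ["k1", "w1"], ["P1"])
        groups = make_groups({"k1": ("KO", "D1"), "w1": ("WT", "D1")})
        with pytest.raises(sp.StphenoError, match="pooled_profile"):
            sp.compute_pdi(pcc, groups, [("KO", "WT")], "pooled_profile")


class TestClassifyPdi:
    def test_sign_convention(self):
        values = pd.DataFrame(
            {"KO_D1_vs_WT_D1": [0.4, -0.4, 0.0]},
            index=["P1", "P2", "P3"],
        )
        comparisons = pd.DataFrame(
            [{"label": "KO_D1_vs_WT_D1", "case": "KO", "control": "WT",
              "timepoint": "D1", "n_case": 1, "n_control": 1}]
        ).set_index("label")
        pdimap = sp.PDIMap(values=values, comparisons=comparisons)
        labels = sp.classify_pdi(pdimap)
        col = labels["KO_D1_vs_WT_D1"]
        assert col.tolist() == ["enhanced", "attenuated", "unchanged"]

    def test_epsilon_widens_unchanged_band(self):
        values = pd.DataFrame({"c": [0.05, -0.05, 0.2]}, index=["P1", "P2", "P3"])
        comparisons = pd.DataFrame(
            [{"label": "c", "case": "KO", "control": "WT", "timepoint": "D1",
              "n_case": 1, "n_control": 1}]
        ).set_index("label")
        labels = sp.classify_pdi(sp.PDIMap(values, comparisons), epsilon=0.1)
        assert labels["c"].tolist() == ["unchanged", "unchanged", "enhanced"]
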