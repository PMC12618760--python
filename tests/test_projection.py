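"""Pearson-correlation mapping of bulk samples onto atlas positions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import stpheno as sp
from stpheno.projection import UndefinedCorrelationError

from conftest import make_matrix


def brute_force_pearson(x, y):
    """Direct Cov/(σσ) with population moments — the independent oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (x.std() * y.std())


class TestPearson:
    def test_self_correlation_is_one(self):
        assert sp.pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_reversal_is_minus_one(self):
        assert sp.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # Cov/(σσ) for (1,2,3) vs (1,2,4) is sqrt(27/28)
        expected = math.sqrt(27 / 28)  # 0.9819805060619659
        assert sp.pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_signals_distinctly(self):
        with pytest.raises(UndefinedCorrelationError):
            sp.pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sp.pearson([1, 2], [3, 4])

    def test_matches_brute_force_and_scipy_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = rng.integers(3, 51)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            got = sp.pearson(x, y)
            assert got == pytest.approx(brute_force_pearson(x, y), abs=1e-12)
            assert got == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=20),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, xs, a, b):
        rng = np.random.default_rng(7)
        x = np.asarray(xs)
        y = rng.normal(size=len(x))
        if x.std() == 0 or y.std() == 0:
            return
        base = sp.pearson(x, y)
        assert sp.pearson(a * x + b, y) == pytest.approx(base, abs=1e-9)
        assert sp.pearson(-a * x + b, y) == pytest.approx(-base, abs=1e-9)


def build_atlas(values, gene_ids, position_ids, stage="E7.5"):
    expr = make_matrix(values, gene_ids=gene_ids, sample_ids=position_ids)
    meta = pd.DataFrame(
        {
            "stage": stage,
            "section_index": range(len(position_ids)),
            "domain_code": [f"D{i}" for i in range(len(position_ids))],
            "layout_row": range(len(position_ids)),
            "layout_col": 0,
        },
        index=pd.Index(position_ids, name="position_id"),
    )
    return sp.AtlasReference(expr, meta)


class TestMapSamples:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.genes = [f"g{i}" for i in range(30)]
        self.atlas_vals = rng.uniform(0, 8, size=(30, 4))
        self.atlas = build_atlas(self.atlas_vals, self.genes, ["P1", "P2", "P3", "P4"])
        self.features = sp.FeatureGeneSet(frozenset(self.genes), "test")

    def test_identical_vector_maps_to_its_position(self):
        bulk = make_matrix(self.atlas_vals[:, [2]], gene_ids=self.genes,
                           sample_ids=["clone_of_P3"])
        pcc = sp.map_samples(bulk, self.atlas, self.features, min_overlap=10)
        row = pcc.values.loc["clone_of_P3"]
        assert row["P3"] == pytest.approx(1.0)
        assert row.idxmax() == "P3"

    def test_universe_size_recorded(self):
        # features 150 ids, bulk holds 120 of them, atlas 140, intersection 110
        all_ids = [f"f{i}" for i in range(150)]
        features = sp.FeatureGeneSet(frozenset(all_ids), "sets")
        rng = np.random.default_rng(0)
        bulk_genes = all_ids[:120]
        atlas_genes = all_ids[10:150]  # 120 & 140 -> overlap 110
        bulk = make_matrix(rng.uniform(0, 5, (120, 2)), gene_ids=bulk_genes)
        atlas = build_atlas(rng.uniform(0, 5, (140, 3)), atlas_genes,
                            ["P1", "P2", "P3"])
        pcc = sp.map_samples(bulk, atlas, features, min_overlap=100)
        assert pcc.n_genes_used == 110

    def test_small_universe_reports_set_sizes(self):
        features = sp.FeatureGeneSet(frozenset(self.genes[:40]), "short")
        bulk = make_matrix(self.atlas_vals[:, :1], gene_ids=self.genes)
        with pytest.raises(sp.StphenoError, match="min_overlap"):
            sp.map_samples(bulk, self.atlas, features, min_overlap=100)

    def test_scale_mismatch_rejected(self):
        bulk = make_matrix(self.atlas_vals[:, :1], gene_ids=self.genes,
                           scale="counts")
        with pytest.raises(sp.StphenoError, match="scale"):
            sp.map_samples(bulk, self.atlas, self.features, min_overlap=10)

    def test_zero_variance_sample_yields_undefined_cells(self, caplog):
        vals = self.atlas_vals[:, :1].copy()
        vals[:, 0] = 3.0  # flat profile
        bulk = make_matrix(vals, gene_ids=self.genes, sample_ids=["flat"])
        with caplog.at_level("WARNING", logger="stpheno"):
            pcc = sp.map_samples(bulk, self.atlas, self.features, min_overlap=10)
        assert pcc.undefined.loc["flat"].all()
        assert pcc.values.loc["flat"].isna().all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        bulk_vals = rng.uniform(0, 5, (30, 3))
        bulk = make_matrix(bulk_vals, gene_ids=self.genes)
        base = sp.map_samples(bulk, self.atlas, self.features, min_overlap=10)
        perm = rng.permutation(30)
        genes_p = [self.genes[i] for i in perm]
        bulk_p = make_matrix(bulk_vals[perm], gene_ids=genes_p)
        atlas_p = build_atlas(self.atlas_vals[perm], genes_p, ["P1", "P2", "P3", "P4"])
        again = sp.map_samples(bulk_p, atlas_p, self.features, min_overlap=10)
        pd.testing.assert_frame_equal(base.values, again.values)


class TestRankPositions:
    def make_pcc(self, rows, positions):
        values = pd.DataFrame(rows, columns=positions)
        values.index = [f"s{i}" for i in range(len(values))]
        return sp.PCCMap(values=values, undefined=values.isna(),
                         n_genes_used=10, min_overlap=1)

    def test_top1(self):
        pcc = self.make_pcc([[0.9, 0.2]], ["P1", "P2"])
        assert sp.rank_positions(pcc, k=1)["s0"] == [("P1", 0.9)]

    def test_ties_all_reported(self):
        pcc = self.make_pcc([[0.5, 0.5, 0.1]], ["P2", "P1", "P3"])
        got = sp.rank_positions(pcc, k=1)["s0"]
        assert got == [("P1", 0.5), ("P2", 0.5)]  # lexicographic among ties

    def test_k_exceeding_positions_no_padding(self):
        pcc = self.make_pcc([[0.4, 0.3]], ["P1", "P2"])
        assert len(sp.rank_positions(pcc, k=3)["s0"]) == 2

    def test_all_undefined_sample_is_error(self):
        pcc = self.make_pcc([[np.nan, np.nan]], ["P1", "P2"])
        with pytest.raises(sp.StphenoError, match="s0"):
            sp.rank_positions(pcc, k=1)


class TestPccSerialization:
    def test_tsv_round_trip_with_sidecar(self, tmp_path):
        values = pd.DataFrame(
            [[0.5, np.nan], [-0.25, 1.0]],
            index=["s1", "s2"], columns=["P1", "P2"],
        )
        pcc = sp.PCCMap(values=values, undefined=values.isna(),
                        n_genes_used=42, feature_provenance="fs", min_overlap=5)
        path = tmp_path / "pcc.tsv"
        sp.write_pcc_map(pcc, path)
        again = sp.read_pcc_map(path)
        pd.testing.assert_frame_equal(pcc.values, again.values)
        assert again.n_genes_used == 42
        assert again.undefined.loc["s1", "P2"]
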