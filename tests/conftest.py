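import numpy as np
import pandas as pd
import pytest

import stpheno as sp


@pytest.fixture
def tiny_expression_tsv(tmp_path):
    """3-gene x 2-sample TSV on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\ts1\ts2\n"
        "gA\t1\t2\n"
        "gB\t4\t5\n"
        "gC\t7\t8\n"
    )
    return path


@pytest.fixture
def small_atlas(tmp_path):
    """A 2-position atlas written to disk (expression + metadata)."""
    expr = tmp_path / "atlas_expr.tsv"
    expr.write_text(
        "gene_id\tP1\tP2\n"
        "gA\t1.0\t4.0\n"
        "gB\t2.0\t2.0\n"
        "gC\t3.0\t1.0\n"
    )
    meta = tmp_path / "atlas_meta.tsv"
    meta.write_text(
        "position_id\tstage\tsection_index\tdomain_code\tlayout_row\tlayout_col\n"
        "P1\tE7.5\t0\tA\t0\t0\n"
        "P2\tE7.5\t1\tP\t1\t0\n"
    )
    return expr, meta


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic scenario: atlas + fate-shift bulk + ground truth."""
    sim = sp.simulate_atlas(seed=42)
    design = sp.fate_shift_design(list(sim.atlas.position_ids))
    bulk, truth = sp.simulate_bulk(sim.signatures, design, noise_sd=0.5, seed=42)
    return sim, bulk, truth


def make_matrix(values, gene_ids=None, sample_ids=None, scale="log2TPM1", ann=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return sp.ExpressionMatrix(df, scale, ann)
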