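"""Unit tests for DEG screening, quantile normalization and set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meiocascade.diffexpr import (
    DEGRecord,
    ExpressionDataset,
    adjust_bh,
    commitment_gene_set,
    initiation_gene_set,
    quantile_normalize,
    test_differential,
)
from meiocascade.synthetic import SimulationConfig, simulate_expression


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_two_column_example():
    m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]}, index=list("abc"))
    out = quantile_normalize(m)
    expected = [2.5, 3.5, 4.5]
    assert out["s1"].tolist() == expected
    assert out["s2"].tolist() == expected


def test_quantile_identical_columns_fixed_point():
    m = pd.DataFrame({"s1": [3.0, 1.0, 2.0], "s2": [3.0, 1.0, 2.0]})
    out = quantile_normalize(m)
    pd.testing.assert_frame_equal(out, m)


def test_quantile_permuted_column():
    rng = np.random.default_rng(0)
    col = rng.normal(size=50)
    m = pd.DataFrame({"s1": col, "s2": rng.permutation(col), "s3": rng.normal(size=50)})
    out = quantile_normalize(m)
    for c in out.columns:
        np.testing.assert_allclose(
            np.sort(out[c].values), np.sort(out["s1"].values), atol=1e-12
        )


def test_quantile_idempotent():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("wxyz"))
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    pd.testing.assert_frame_equal(once, twice)


def test_quantile_rejects_single_column_and_nan():
    with pytest.raises(ValueError):
        quantile_normalize(pd.DataFrame({"s1": [1.0, 2.0]}))
    with pytest.raises(ValueError):
        quantile_normalize(pd.DataFrame({"s1": [1.0, np.nan], "s2": [1.0, 2.0]}))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_step_up_example():
    assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_trivial_cases():
    assert adjust_bh([0.5]) == [0.5]
    assert adjust_bh([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]
    assert adjust_bh([]) == []


def test_bh_bounds_and_errors():
    with pytest.raises(ValueError):
        adjust_bh([0.5, 1.5])
    with pytest.raises(ValueError):
        adjust_bh([-0.1])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.uniform(size=200)
    ours = adjust_bh(p)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(ours, ref, atol=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_bh_permutation_invariance(p):
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(p))
    adjusted = np.asarray(adjust_bh(p))
    permuted = np.asarray(adjust_bh(list(np.asarray(p)[perm])))
    np.testing.assert_allclose(adjusted[perm], permuted, atol=1e-12)
    assert np.all(adjusted >= np.asarray(p) - 1e-12)
    assert np.all(adjusted <= 1.0 + 1e-12)


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------

def test_planted_up_genes_recovered():
    cfg = SimulationConfig(seed=2, n_genes=500, n_planted_up=25,
                           planted_lfc=2.0, noise_sd=0.3, n_samples_per_condition=5)
    ds, truth = simulate_expression(cfg, "c1")
    records = test_differential(ds, "control", "treatment")
    up = {r.gene_id for r in records if r.direction == "up"}
    planted = truth.up_gene_ids["c1"]
    recall = len(up & planted) / len(planted)
    assert recall >= 0.95


def test_subthreshold_lfc_called_ns():
    # a clearly significant shift of 0.9 log2 units stays below the lfc cutoff
    rng = np.random.default_rng(3)
    n = 200
    base = rng.uniform(6, 10, n)
    log2 = np.concatenate(
        [base[:, None] + rng.normal(0, 0.05, (n, 5)),
         base[:, None] + rng.normal(0, 0.05, (n, 5))], axis=1
    )
    log2[0, 5:] += 0.9
    samples = [f"c{i}" for i in range(5)] + [f"t{i}" for i in range(5)]
    ds = ExpressionDataset(
        matrix=pd.DataFrame(np.exp2(log2), columns=samples),
        condition_of={s: ("control" if s.startswith("c") else "treatment") for s in samples},
    )
    rec = test_differential(ds, "control", "treatment")[0]
    assert rec.p_adj < 0.05
    assert 0.5 < rec.log2FC < 1.0
    assert rec.direction == "ns"


def test_direction_sign_flips_on_relabel():
    cfg = SimulationConfig(seed=4, n_genes=300, n_planted_up=20)
    ds, _ = simulate_expression(cfg)
    fwd = test_differential(ds, "control", "treatment")
    rev = test_differential(ds, "treatment", "control")
    for f, r in zip(fwd, rev):
        assert f.log2FC == pytest.approx(-r.log2FC, abs=1e-9)
        assert f.p_raw == pytest.approx(r.p_raw, abs=1e-9)
        if f.direction == "up":
            assert r.direction == "down"


def test_too_few_samples_rejected():
    m = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0], "c": [1.5, 2.5]})
    ds = ExpressionDataset(matrix=m, condition_of={"a": "x", "b": "y", "c": "y"})
    with pytest.raises(ValueError):
        test_differential(ds, "x", "y")


def test_moderation_validated():
    cfg = SimulationConfig(seed=6, n_genes=50, n_planted_up=0)
    ds, _ = simulate_expression(cfg)
    with pytest.raises(ValueError):
        test_differential(ds, "control", "treatment", moderation=1.5)
    # moderated run still returns one record per gene
    recs = test_differential(ds, "control", "treatment", moderation=0.5)
    assert len(recs) == 50


# ---------------------------------------------------------------------------
# set logic
# ---------------------------------------------------------------------------

def _rec(gene, direction):
    return DEGRecord(gene, 2.0 if direction == "up" else 0.0, 0.01, 0.01, direction)


def test_initiation_intersection():
    run1 = [_rec(g, "up") for g in "abc"]
    run2 = [_rec(g, "up") for g in "bcd"]
    assert initiation_gene_set([run1, run2]) == {"b", "c"}


def test_initiation_disjoint_warns_empty():
    run1 = [_rec("a", "up")]
    run2 = [_rec("b", "up")]
    assert initiation_gene_set([run1, run2]) == set()


def test_initiation_empty_input_errors():
    with pytest.raises(ValueError):
        initiation_gene_set([])


def test_commitment_subtraction():
    assert commitment_gene_set({"g1", "g2", "g3"}, {"g2"}) == {"g1", "g3"}
    assert commitment_gene_set({"g1"}, {"x"}) == {"g1"}


def test_commitment_reported_sizes():
    # set sizes mirroring the documented 566 / 689 / 156 -> 410 arithmetic
    up = {f"u{i}" for i in range(410)} | {f"o{i}" for i in range(156)}
    down = {f"o{i}" for i in range(156)} | {f"d{i}" for i in range(533)}
    assert len(up) == 566 and len(down) == 689
    result = commitment_gene_set(up, down)
    assert len(up & down) == 156
    assert len(result) == 410


def test_dataset_validation():
    with pytest.raises(ValueError):
        ExpressionDataset(
            matrix=pd.DataFrame({"s1": [1.0, -2.0]}), condition_of={"s1": "x"}
        )
    with pytest.raises(ValueError):
        ExpressionDataset(matrix=pd.DataFrame({"s1": [1.0]}), condition_of={})
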