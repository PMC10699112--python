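"""Unit tests for NG86 counting, selection Z-test, GESD and Mann-Whitney."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data import CodonTable
from hypothesis import given, settings
from hypothesis import strategies as st

from meiocascade.molevo import (
    CodonAlignmentPair,
    OrthologPair,
    SENSE_CODONS,
    STOP_CODONS,
    SaturationError,
    _codon_pair_diffs,
    codon_z_test,
    compare_phase_evolution,
    filter_orthologs,
    gesd_outliers,
    mann_whitney,
    ng86_codon_sites,
    ng86_pair,
)
from meiocascade.synthetic import simulate_codon_pair

_CODE = CodonTable.unambiguous_dna_by_id[1]
_AA_ORACLE = dict(_CODE.forward_table)


# ---------------------------------------------------------------------------
# site counting
# ---------------------------------------------------------------------------

def oracle_sites(codon):
    """Independent enumeration of fractional synonymous sites."""
    s = 0.0
    for pos in range(3):
        changes = []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in _CODE.stop_codons:
                continue
            changes.append(_AA_ORACLE[mut] == _AA_ORACLE[codon])
        if changes:
            s += sum(changes) / len(changes)
    return s


@pytest.mark.parametrize(
    "codon,expected_s",
    [("GGG", 1.0), ("TTT", 1 / 3), ("ATG", 0.0)],
)
def test_sites_known_codons(codon, expected_s):
    s, n = ng86_codon_sites(codon)
    assert s == pytest.approx(expected_s, abs=1e-12)
    assert s + n == pytest.approx(3.0, abs=1e-12)


def test_sites_match_enumeration_all_sense_codons():
    for codon in SENSE_CODONS:
        s, n = ng86_codon_sites(codon)
        assert s == pytest.approx(oracle_sites(codon), abs=1e-12)
        assert s + n == pytest.approx(3.0, abs=1e-12)


def test_sites_reject_stop_and_ambiguous():
    with pytest.raises(ValueError):
        ng86_codon_sites("TAA")
    with pytest.raises(ValueError):
        ng86_codon_sites("NNN")


# ---------------------------------------------------------------------------
# pairwise difference counting
# ---------------------------------------------------------------------------

def test_pair_diffs_examples():
    assert _codon_pair_diffs("TTT", "TTC") == (1.0, 0.0)
    # two pathways TTT->GTT->GTA and TTT->TTA->GTA average to (0.5, 1.5)
    sd, nd = _codon_pair_diffs("TTT", "GTA")
    assert sd == pytest.approx(0.5)
    assert nd == pytest.approx(1.5)


def test_pair_diffs_conserve_total():
    rng = np.random.default_rng(7)
    for _ in range(200):
        ca, cb = rng.choice(SENSE_CODONS, 2)
        sd, nd = _codon_pair_diffs(ca, cb)
        n_diff = sum(a != b for a, b in zip(ca, cb))
        assert sd + nd == pytest.approx(n_diff, abs=1e-12)


# ---------------------------------------------------------------------------
# pair estimates
# ---------------------------------------------------------------------------

def test_identical_sequences_zero_distances():
    seq = "ATGGCTAAAGCT" * 10
    est = ng86_pair(CodonAlignmentPair(seq, seq))
    assert est.Sd == est.Nd == 0.0
    assert est.dS == est.dN == 0.0
    assert est.omega is None


def test_single_differing_codon_in_context():
    # identical context codons keep the proportions below the JC bound
    ctx = "ATGGCTAAAGCT" * 10
    est = ng86_pair(CodonAlignmentPair(ctx + "TTT", ctx + "TTC"))
    assert est.Sd == pytest.approx(1.0)
    assert est.Nd == pytest.approx(0.0)
    est = ng86_pair(CodonAlignmentPair(ctx + "TTT", ctx + "GTA"))
    assert est.Sd == pytest.approx(0.5)
    assert est.Nd == pytest.approx(1.5)


def test_sites_sum_to_three_per_codon():
    pair, _ = simulate_codon_pair(100, 0.5, 0.3, seed=1)
    est = ng86_pair(pair)
    assert est.S + est.N == pytest.approx(3 * pair.n_codons, abs=1e-9)


def test_ng86_symmetric_under_sequence_swap():
    pair, _ = simulate_codon_pair(150, 0.4, 0.4, seed=3)
    fwd = ng86_pair(pair)
    rev = ng86_pair(CodonAlignmentPair(pair.seq_b, pair.seq_a))
    for attr in ("S", "N", "Sd", "Nd", "dS", "dN"):
        assert getattr(fwd, attr) == pytest.approx(getattr(rev, attr), abs=1e-12)


def test_gap_columns_skipped():
    ctx = "ATGGCTAAAGCT" * 5
    est_full = ng86_pair(CodonAlignmentPair(ctx + "TTTAAA", ctx + "TTCAAA"))
    est_gap = ng86_pair(CodonAlignmentPair(ctx + "TTT---AAA", ctx + "TTC---AAA"))
    assert est_gap.Sd == est_full.Sd
    assert est_gap.S == pytest.approx(est_full.S)


def test_alignment_pair_validation():
    with pytest.raises(ValueError):
        CodonAlignmentPair("ATG", "ATGATG")  # length mismatch
    with pytest.raises(ValueError):
        CodonAlignmentPair("ATGA", "ATGA")  # not codon-divisible
    with pytest.raises(ValueError):
        CodonAlignmentPair("TAAATG", "ATGATG")  # internal stop


def test_saturation_error():
    # maximally divergent columns push pN over the JC bound
    a = "GGG" * 60
    b = "CCC" * 60
    with pytest.raises(SaturationError):
        ng86_pair(CodonAlignmentPair(a, b))


# ---------------------------------------------------------------------------
# selection Z-test
# ---------------------------------------------------------------------------

def test_z_test_identical_sequences():
    seq = "ATGGCTAAAGCT" * 20
    with pytest.warns(RuntimeWarning):
        res = codon_z_test(CodonAlignmentPair(seq, seq), n_boot=200, seed=0)
    assert res.prob == 1.0


def test_z_test_purifying_pair_significant():
    pair, _ = simulate_codon_pair(300, 0.1, 0.3, seed=11)
    res = codon_z_test(pair, n_boot=500, seed=11)
    assert res.prob < 0.05
    assert res.Z > 0


def test_z_test_rejects_small_nboot():
    pair, _ = simulate_codon_pair(100, 0.5, 0.3, seed=1)
    with pytest.raises(ValueError):
        codon_z_test(pair, n_boot=100, seed=0)


def test_z_test_deterministic():
    pair, _ = simulate_codon_pair(200, 0.2, 0.3, seed=5)
    r1 = codon_z_test(pair, n_boot=300, seed=9)
    r2 = codon_z_test(pair, n_boot=300, seed=9)
    assert r1.Z == r2.Z and r1.prob == r2.prob


# ---------------------------------------------------------------------------
# GESD
# ---------------------------------------------------------------------------

def test_gesd_all_equal():
    with pytest.warns(RuntimeWarning):
        scan = gesd_outliers([1.0] * 10, alpha=0.05, k_max=2)
    assert scan.n_outliers == 0


def test_gesd_single_gross_outlier():
    values = [1.0, 1.1, 0.9, 1.05, 0.95, 8.0]
    scan = gesd_outliers(values, alpha=0.05, k_max=1)
    # independent check of R_1 and lambda_1 by the defining formulas
    import scipy.stats as ss

    x = np.array(values)
    r1 = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
    n = len(values)
    t = ss.t.ppf(1 - 0.05 / (2 * n), n - 2)
    lam1 = (n - 1) * t / math.sqrt((n - 2 + t**2) * n)
    assert scan.R_stats[0] == pytest.approx(r1)
    assert scan.lambdas[0] == pytest.approx(lam1)
    assert scan.n_outliers == 1
    assert scan.outlier_indices == (5,)


def test_gesd_planted_recovery():
    rng = np.random.default_rng(21)
    for k in (1, 2, 3):
        x = rng.normal(0, 1, 100)
        x[:k] += 8.0
        scan = gesd_outliers(x, alpha=0.05, k_max=5)
        assert scan.n_outliers == k
        assert set(scan.outlier_indices) == set(range(k))


def test_gesd_preconditions():
    with pytest.raises(ValueError):
        gesd_outliers([1.0, 2.0, 3.0], alpha=0.05, k_max=5)
    with pytest.raises(ValueError):
        gesd_outliers([1.0, np.inf] + [0.0] * 10, alpha=0.05, k_max=2)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mw_exact_small_example():
    res = mann_whitney([1, 2], [3, 4], alternative="two_sided")
    assert res.U == 0
    assert res.p_value == pytest.approx(2 / 6)
    assert res.method == "exact"


def test_mw_identical_samples_p_one():
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.p_value == pytest.approx(1.0)


def test_mw_u_range_and_mirror():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.normal(size=rng.integers(2, 12))
        b = rng.normal(size=rng.integers(2, 12))
        res = mann_whitney(a, b)
        mirror = mann_whitney(b, a)
        assert 0 <= res.U <= res.n_a * res.n_b
        assert res.U + mirror.U == pytest.approx(res.n_a * res.n_b)
        assert res.p_value == pytest.approx(mirror.p_value, abs=1e-9)


def test_mw_against_scipy_normal_path():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(8)
    a = rng.normal(size=30)
    b = rng.normal(0.5, 1, size=25)
    res = mann_whitney(a, b)
    ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert res.U == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_mw_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])
    with pytest.raises(ValueError):
        mann_whitney([1.0], [2.0], alternative="greater")
    with pytest.raises(ValueError):
        mann_whitney([1, 1, 2], [1, 3], method="exact")  # ties


# ---------------------------------------------------------------------------
# ortholog filtering & phase comparison
# ---------------------------------------------------------------------------

def _pair(species="sp", identity=80.0, otype="one-to-one", conf=1.0, group="a"):
    return OrthologPair("x", "y", species, otype, conf, identity, group)


def test_filter_orthologs_thresholds():
    pairs = [
        _pair(species="ago", identity=59.0),
        _pair(species="ago", identity=61.0),
        _pair(species="ylip", identity=35.0),
        _pair(species="ylip", identity=35.0, otype="one-to-many"),
        _pair(species="ylip", identity=35.0, conf=0.5),
    ]
    kept = filter_orthologs(pairs, {"ago": 60.0}, identity_default=30.0)
    assert len(kept) == 2
    assert {p.species for p in kept} == {"ago", "ylip"}


def test_filter_orthologs_missing_species():
    with pytest.raises(KeyError):
        filter_orthologs([_pair(species="zzz")], {"ago": 60.0})


def test_compare_phase_evolution_planted_ordering():
    rng = np.random.default_rng(17)

    def make(group, omega, n):
        out = []
        for i in range(n):
            pair, _ = simulate_codon_pair(
                150, omega, 0.3, rng=rng,
                meta=_pair(species="spX", group=group),
            )
            est = ng86_pair(pair)
            sel = codon_z_test(pair, n_boot=300, seed=i)
            out.append((pair.meta, est, sel))
        return out

    init = make("initiation", 0.4, 25)
    commit = make("commitment", 0.1, 25)
    reports = compare_phase_evolution(init, commit, require_significant=True)
    assert len(reports) == 1
    rep = reports[0]
    assert rep.median_omega_b < rep.median_omega_a
    assert rep.p_value < 0.05


def test_compare_phase_evolution_skips_empty_species():
    pair, _ = simulate_codon_pair(100, 0.3, 0.3, seed=2, meta=_pair(species="only_a"))
    est = ng86_pair(pair)
    reports = compare_phase_evolution(
        [(pair.meta, est, None)], [], require_significant=False
    )
    assert reports == []


# hypothesis: exact and normal paths agree reasonably on random data
@settings(max_examples=30, deadline=None)
@given(
    st.lists(st.integers(0, 10_000), min_size=4, max_size=6, unique=True),
    st.lists(st.integers(10_001, 20_000), min_size=4, max_size=6, unique=True),
)
def test_mw_exact_vs_normal_hypothesis(a, b):
    exact = mann_whitney(a, b, method="exact")
    normal = mann_whitney(a, b, method="normal")
    assert abs(exact.p_value - normal.p_value) < 0.06
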