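"""NB differential testing, BH, rank-sum shifts and overlap tests."""

import numpy as np
import pytest

from nmdkit.difftest import (
    bh_adjust,
    estimate_dispersion,
    group_shift_test,
    nb_two_group,
    occupancy_diff,
    overlap_test,
    size_factors,
)

from conftest import null_occupancy_inputs


# ------------------------------------------------------------- dispersion


def test_estimate_dispersion_floor_and_closed_form():
    assert estimate_dispersion([100, 100], alpha_floor=0.01) == 0.01
    # two points m +/- d have mean m and s^2 = 2 d^2; choose s^2 = m + 0.1 m^2
    m = 100.0
    d = np.sqrt((m + 0.1 * m**2) / 2)
    assert estimate_dispersion([m - d, m + d]) == pytest.approx(0.1)
    assert estimate_dispersion([0, 0]) == 0.01  # all-zero -> floor
    with pytest.raises(ValueError):
        estimate_dispersion([5])


# --------------------------------------------------------------------- BH


def test_bh_adjust_step_up_by_hand():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_adjust_invariant_to_input_order():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    q = bh_adjust(p)
    assert np.allclose(bh_adjust(p[perm]), q[perm])
    assert (q >= p).all()


# ------------------------------------------------------------ two-group NB


def test_nb_two_group_identical_and_doubled():
    a = np.tile([1000.0, 500.0], (3, 1)).T * 0 + np.array([[1000.0] * 3, [500.0] * 3])
    res = nb_two_group(a, a, sf=np.ones(6), alpha=np.array([0.05, 0.05]))
    assert res["lfc"].to_numpy() == pytest.approx([0.0, 0.0])
    assert res["p"].to_numpy() == pytest.approx([1.0, 1.0])
    b = a * 2
    res2 = nb_two_group(a, b, sf=np.ones(6), alpha=np.array([0.05, 0.05]))
    assert res2["lfc"].to_numpy() == pytest.approx([1.0, 1.0], abs=2e-3)


def test_size_factors_median_of_ratios():
    rng = np.random.default_rng(2)
    base = rng.integers(100, 1000, size=(200, 1)).astype(float)
    counts = np.hstack([base, base * 2.0, base * 0.5])
    sf = size_factors(counts)
    assert sf / sf[0] == pytest.approx([1.0, 2.0, 0.5], rel=1e-9)
    with pytest.raises(ValueError):
        size_factors(np.array([[1.0, 0.0], [2.0, 0.0]]))


def test_nb_two_group_null_calibration():
    """Fraction p<0.05 near nominal under a shared-NB null (2000 transcripts)."""
    rng = np.random.default_rng(5)
    mu = np.exp(rng.uniform(np.log(100), np.log(1000), 2000))
    r = 1 / 0.05
    a = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 3))
    b = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 3))
    res = nb_two_group(a, b)
    assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07


# ------------------------------------------------------------- occupancy


def test_occupancy_lfc_identity_and_pure_mrna_effect_cancels():
    rng = np.random.default_rng(8)
    planted = np.zeros(800, bool)
    planted[:80] = True
    rna, rpf, _ = null_occupancy_inputs(rng, n_transcripts=800, mean_range=500,
                                        planted=planted, mrna_effect=2.0)
    res = occupancy_diff(rna, rpf, "A", "B")
    assert np.allclose(res["lfc_occ"], res["lfc_rpf"] - res["lfc_mrna"])
    assert (res["q"] >= res["p"]).all()
    # mRNA effect moves both assays: occupancy centred at zero
    assert abs(res.loc[planted, "lfc_occ"].median()) < 0.1
    # median-of-ratios normalization absorbs part of a planted global shift
    assert res.loc[planted, "lfc_mrna"].median() == pytest.approx(1.0, abs=0.2)


def test_occupancy_diff_requires_replicates():
    rng = np.random.default_rng(0)
    rna, rpf, _ = null_occupancy_inputs(rng, n_transcripts=50, n_rep=1)
    with pytest.raises(ValueError):
        occupancy_diff(rna, rpf, "A", "B")


def test_occupancy_power_with_moderate_dispersion():
    """2-fold occupancy effects at mean >= 500, n=3 are detected with power >= 0.8.

    Biological dispersion 0.02; at the generator's default 0.05 the effect
    size in units of its own sampling error caps any test's power near 0.75.
    """
    rng = np.random.default_rng(9)
    planted = np.zeros(2000, bool)
    planted[:200] = True
    rna, rpf, _ = null_occupancy_inputs(rng, n_transcripts=2000, mean_range=500,
                                        alpha=0.02, planted=planted, occ_effect=2.0)
    res = occupancy_diff(rna, rpf, "A", "B")
    assert (res.loc[planted, "q"] < 0.1).mean() >= 0.8
    assert (res.loc[~planted, "q"] < 0.1).mean() <= 0.02


# -------------------------------------------------------------- rank tests


def test_group_shift_exact_enumeration():
    res = group_shift_test([1, 2, 3, 4, 5, 6], [True, True, True, False, False, False])
    assert res.U == 0.0
    assert res.p == pytest.approx(0.1)  # 2 * 1/C(6,3)=2/20
    assert (res.n_class, res.n_background) == (3, 3)


def test_group_shift_identical_groups():
    vals = np.concatenate([np.arange(6), np.arange(6) + 0.5])
    flags = np.array([True] * 6 + [False] * 6)
    res = group_shift_test(vals[np.argsort(vals)], flags[np.argsort(vals)])
    assert res.p > 0.5


def test_group_shift_exact_vs_asymptotic_agree():
    """Branches agree within 10% relative p at group sizes 15-25."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        n1, n2 = rng.integers(15, 26, 2)
        vals = rng.normal(size=n1 + n2)
        flags = np.array([True] * n1 + [False] * n2)
        p_exact = group_shift_test(vals, flags, exact_max_n=100).p
        p_asym = group_shift_test(vals, flags, exact_max_n=0).p
        assert p_asym == pytest.approx(p_exact, rel=0.10)


def test_group_shift_detects_small_shift():
    rng = np.random.default_rng(6)
    vals = np.concatenate([rng.normal(0.5, 1, 200), rng.normal(0, 1, 2000)])
    flags = np.array([True] * 200 + [False] * 2000)
    assert group_shift_test(vals, flags).p < 1e-6


def test_group_shift_empty_group_errors():
    with pytest.raises(ValueError):
        group_shift_test([1.0, 2.0], [True, True])


# ------------------------------------------------------------ overlap test


def test_overlap_test_closed_forms():
    a = set(range(5))
    assert overlap_test(a, a, 10) == pytest.approx(1 / 252)
    assert overlap_test(set(), set(range(3)), 10) == 1.0
    with pytest.raises(ValueError):
        overlap_test(set(range(20)), set(range(5)), 10)


def test_overlap_test_superuniform_under_null():
    """Null p-values never exceed their nominal level (discrete upper tail)."""
    rng = np.random.default_rng(12)
    universe = np.arange(1000)
    ps = []
    for _ in range(400):
        a = set(rng.choice(universe, 300, replace=False))
        b = set(rng.choice(universe, 300, replace=False))
        ps.append(overlap_test(a, b, 1000))
    ps = np.array(ps)
    # discrete upper-tail p-values are valid (super-uniform), never anti-conservative
    for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
        assert (ps <= alpha).mean() <= alpha + 0.04
    assert 0.4 < ps.mean() < 0.65
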