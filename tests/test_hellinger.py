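"""Histogramming, the Hellinger statistic, the x^3 reference, and trait ranking."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdqtl.hellinger import (
    Histogram,
    bin_sweep,
    hd_table,
    hd_tails,
    hellinger_distance,
    make_histogram,
    reference_histogram,
    reference_values,
    significance_scores,
    trait_hd,
)
from hdqtl.io_model import CorrectedPValueMatrix, ValidationError


def brute_force_hd(p_counts, q_counts, formula):
    """Direct summation oracle, plain Python floats."""
    ps, qs = sum(p_counts), sum(q_counts)
    total = 0.0
    for a, b in zip(p_counts, q_counts):
        if formula == "hellinger":
            total += (math.sqrt(a / ps) - math.sqrt(b / qs)) ** 2
        else:
            total += (a / ps - b / qs) ** 2
    return math.sqrt(total) if formula == "hellinger" else total


# --- significance scores ---------------------------------------------------

def test_significance_scores_orientation():
    scores = significance_scores([1.0, 0.001, 0.5])
    np.testing.assert_allclose(scores, [0.0, 0.999, 0.5])
    neglog = significance_scores([1.0, 0.001], transform="neglog10")
    np.testing.assert_allclose(neglog, [0.0, 3.0])


@pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2, 0.5], [np.nan, 0.5], []])
def test_significance_scores_rejects_invalid(bad):
    with pytest.raises(ValidationError):
        significance_scores(bad)


# --- histograms ------------------------------------------------------------

def test_make_histogram_rule():
    # half-open bins, last bin closed: 0.5 belongs to [0.5, 1]
    h = make_histogram([0.0, 0.5, 1.0], n_bins=2)
    np.testing.assert_array_equal(h.counts, [1, 2])
    assert h.binwidth == pytest.approx(0.5)
    assert h.total == 3


def test_make_histogram_degenerate_constant():
    h = make_histogram([2.0] * 7, n_bins=5)
    np.testing.assert_array_equal(h.counts, [7, 0, 0, 0, 0])
    with pytest.raises(ValidationError):
        make_histogram([], n_bins=3)


def test_make_histogram_uniform_counts_binomial():
    rng = np.random.default_rng(1)
    h = make_histogram(rng.uniform(0, 1, 1000), n_bins=30)
    expected = 1000 / 30
    sd = math.sqrt(1000 * (1 / 30) * (29 / 30))
    assert np.all(np.abs(h.counts - expected) < 5 * sd)
    assert h.total == 1000


# --- Hellinger distance ----------------------------------------------------

def test_hd_identity_and_disjoint_extremes():
    p = Histogram(np.array([4, 0]), 0, 1)
    q = Histogram(np.array([0, 9]), 0, 1)
    assert hellinger_distance(p, p) == 0.0
    assert hellinger_distance(p, q) == pytest.approx(math.sqrt(2))
    assert hellinger_distance(p, q, formula="printed") == pytest.approx(2.0)


def test_hd_direct_formula_oracle():
    p = Histogram(np.array([3, 1]), 0, 1)
    q = Histogram(np.array([1, 3]), 0, 1)
    expected = math.sqrt((math.sqrt(0.75) - math.sqrt(0.25)) ** 2 * 2)
    assert hellinger_distance(p, q) == pytest.approx(expected, abs=1e-12)
    assert hellinger_distance(p, q) == pytest.approx(
        brute_force_hd([3, 1], [1, 3], "hellinger"), abs=1e-12
    )


def test_hd_errors():
    p = Histogram(np.array([1, 1]), 0, 1)
    with pytest.raises(ValidationError):
        hellinger_distance(p, Histogram(np.array([1, 1, 1]), 0, 1))
    with pytest.raises(ValidationError):
        hellinger_distance(p, Histogram(np.array([0, 0]), 0, 1))


counts_pair = st.integers(2, 10).flatmap(
    lambda k: st.tuples(
        st.lists(st.integers(0, 50), min_size=k, max_size=k),
        st.lists(st.integers(0, 50), min_size=k, max_size=k),
    ).filter(lambda pq: sum(pq[0]) > 0 and sum(pq[1]) > 0)
)


@settings(max_examples=300, derandomize=True)
@given(counts_pair)
def test_hd_symmetry_and_bounds(pq):
    p = Histogram(np.array(pq[0]), 0, 1)
    q = Histogram(np.array(pq[1]), 0, 1)
    for formula, bound in (("hellinger", math.sqrt(2)), ("printed", 2.0)):
        d_pq = hellinger_distance(p, q, formula=formula)
        d_qp = hellinger_distance(q, p, formula=formula)
        assert d_pq == pytest.approx(d_qp, abs=1e-12)
        assert -1e-12 <= d_pq <= bound + 1e-12


@settings(max_examples=300, derandomize=True)
@given(counts_pair)
def test_hd_zero_iff_same_proportions(pq):
    p, q = pq
    sp, sq = sum(p), sum(q)
    same = all(a * sq == b * sp for a, b in zip(p, q))
    d = hellinger_distance(Histogram(np.array(p), 0, 1), Histogram(np.array(q), 0, 1))
    assert (d < 1e-12) == same


@settings(max_examples=200, derandomize=True)
@given(counts_pair, st.integers(2, 7))
def test_hd_scale_invariance(pq, k):
    """Multiplying all counts by a constant leaves both variants unchanged:
    the statistic compares shape, not scale."""
    p, q = pq
    for formula in ("hellinger", "printed"):
        d1 = hellinger_distance(
            Histogram(np.array(p), 0, 1), Histogram(np.array(q), 0, 1), formula=formula
        )
        d2 = hellinger_distance(
            Histogram(np.array(p) * k, 0, 1), Histogram(np.array(q), 0, 1), formula=formula
        )
        assert d1 == pytest.approx(d2, abs=1e-12)


def test_squared_hd_lower_bounds_kl():
    rng = np.random.default_rng(2)
    for _ in range(50):
        k = rng.integers(2, 10)
        p = rng.integers(1, 50, k).astype(float)
        q = rng.integers(1, 50, k).astype(float)
        p /= p.sum()
        q /= q.sum()
        kl = float(np.sum(p * np.log(p / q)))
        h2 = hellinger_distance(
            Histogram((p * 2520).astype(int) + 1, 0, 1),
            Histogram((q * 2520).astype(int) + 1, 0, 1),
        )
        # compare on the same discretized pair
        pd_ = ((p * 2520).astype(int) + 1) / (((p * 2520).astype(int) + 1).sum())
        qd = ((q * 2520).astype(int) + 1) / (((q * 2520).astype(int) + 1).sum())
        kl_d = float(np.sum(pd_ * np.log(pd_ / qd)))
        assert h2**2 <= kl_d + 1e-12


# --- reference distribution ------------------------------------------------

def test_reference_enumeration_small():
    np.testing.assert_array_equal(reference_values(3), [1, 8, 27])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        h = reference_histogram(3, n_bins=3)
    # edges 1, 9.67, 18.33, 27: both 1 and 8 fall in the first bin
    np.testing.assert_array_equal(h.counts, [2, 0, 1])
    assert h.range_min == 1 and h.range_max == 27
    with pytest.raises(ValidationError):
        reference_histogram(0)


def test_reference_first_bin_limit_and_taper():
    h = reference_histogram(3000, n_bins=30)
    assert abs(h.proportions()[0] - (1 / 30) ** (1 / 3)) < 0.01
    assert np.all(np.diff(h.counts) <= 0)


@pytest.mark.parametrize("L,n_bins", [(1000, 10), (3000, 30)])
def test_reference_taper_strictly_monotone_when_dense(L, n_bins):
    h = reference_histogram(L, n_bins=n_bins)
    assert np.all(np.diff(h.counts) <= 0)
    assert h.total == L


@pytest.mark.parametrize("L,n_bins", [(100, 10), (300, 30), (500, 50)])
def test_reference_taper_monotone_up_to_rounding(L, n_bins):
    """At ~10 loci per bin the ideal bin masses still decrease, but integer
    counts jitter by one; the taper must hold up to that rounding."""
    h = reference_histogram(L, n_bins=n_bins)
    assert np.all(np.diff(h.counts) <= 1)
    assert h.counts[0] == h.counts.max()
    # integer counts track the strictly-decreasing continuous bin masses
    edges = np.linspace(1, L**3, n_bins + 1)
    ideal = np.diff(np.cbrt(edges))
    assert np.all(np.diff(ideal) < 0)
    assert np.all(np.abs(h.counts - ideal) < 1.0)
    assert h.total == L


def test_reference_warns_when_sparse():
    with pytest.warns(UserWarning, match="sparse"):
        reference_histogram(5, n_bins=30)


# --- per-trait statistic ---------------------------------------------------

def test_trait_hd_degenerate_row_equals_bin1_distance():
    """An all-equal p row collapses to the all-mass-in-bin-1 histogram."""
    row = np.full(300, 0.7)
    res = trait_hd(row, n_bins=30)
    counts = np.zeros(30, dtype=int)
    counts[0] = 300
    expected = hellinger_distance(
        Histogram(counts, 0, 0), reference_histogram(300, 30)
    )
    assert res.hd == pytest.approx(expected, abs=1e-12)
    assert res.n_ties == 300


def test_trait_hd_exceptional_row_below_degenerate():
    """One exceptional association gives structure, so its distance falls
    below the flat-profile (degenerate) value; this ordering is what lets
    single-locus traits outrank null traits."""
    flat = trait_hd(np.ones(900) * 1.0, n_bins=30)
    row = np.ones(900)
    row[450] = 0.001
    exceptional = trait_hd(row, n_bins=30)
    assert exceptional.hd < flat.hd


def test_trait_hd_marker_order_invariance():
    rng = np.random.default_rng(4)
    row = rng.uniform(0.01, 1.0, 120)
    perm = rng.permutation(120)
    assert trait_hd(row).hd == pytest.approx(trait_hd(row[perm]).hd, abs=1e-12)


def test_trait_hd_best_marker_tie_rule():
    row = np.array([0.5, 0.2, 0.2, 1.0])
    res = trait_hd(row, n_bins=2, marker_ids=("a", "b", "c", "d"))
    assert res.best_marker == "b"  # lowest index among the tied minima
    assert res.best_p == pytest.approx(0.2)
    assert res.n_ties == 2


def test_trait_hd_ignores_missing_pvalues():
    row = np.array([0.9, np.nan, 0.4, 1.0])
    res = trait_hd(row, n_bins=2, marker_ids=("a", "b", "c", "d"))
    assert res.best_marker == "c"
    ref = trait_hd(np.array([0.9, 0.4, 1.0]), n_bins=2)
    assert res.hd == pytest.approx(ref.hd, abs=1e-15)


# --- tails and bin sweep ---------------------------------------------------

def _hd_frame(values):
    import pandas as pd

    return pd.DataFrame(
        {"trait": [f"t{i:03d}" for i in range(len(values))], "hd": values}
    )


def test_hd_tails_quantile_counts():
    frame = _hd_frame(np.linspace(0, 1, 100))
    small, large = hd_tails(frame, tail_fraction=0.05)
    assert len(small) == 5 and len(large) == 5
    assert small == {f"t{i:03d}" for i in range(5)}
    assert large == {f"t{i:03d}" for i in range(95, 100)}


def test_hd_tails_all_equal_warns():
    frame = _hd_frame(np.full(20, 0.5))
    with pytest.warns(UserWarning, match="overlap"):
        small, large = hd_tails(frame, tail_fraction=0.1)
    assert small == large == set(frame["trait"])


def test_hd_tails_count_matched():
    frame = _hd_frame(np.array([0.3, 0.1, 0.1, 0.9, 0.9, 0.5]))
    small, large = hd_tails(frame, count=2)
    assert small == {"t001", "t002"}  # tie at 0.1 broken by trait id
    assert large == {"t003", "t004"}


def test_bin_sweep_identity_and_degenerate():
    rng = np.random.default_rng(6)
    pv = CorrectedPValueMatrix(
        ("t1", "t2", "t3"),
        tuple(f"m{i}" for i in range(60)),
        rng.uniform(0.01, 1.0, (3, 60)),
    )
    _, rho = bin_sweep(pv, bins=[30, 30])
    assert rho.loc[30, 30] == 1.0
    single = CorrectedPValueMatrix(("t1",), pv.markers, pv.values[:1])
    with pytest.warns(UserWarning, match="undefined"):
        _, rho1 = bin_sweep(single, bins=[10, 20])
    assert rho1.isna().all().all()


def test_hd_table_matches_trait_hd(recovery_study):
    pv = recovery_study["pvals"]
    table = hd_table(pv).set_index("trait")
    for i in (0, 57, 199):
        res = trait_hd(pv.values[i], trait_id=pv.traits[i], marker_ids=pv.markers)
        assert table.loc[pv.traits[i], "hd"] == pytest.approx(res.hd)
        assert table.loc[pv.traits[i], "best_marker"] == res.best_marker
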