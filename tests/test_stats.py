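"""Ordinal agreement statistics against independent rank-based oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from tibdefect import reference, stats as ts

# ---------------------------------------------------------------------------
# independent oracles (plain formula / midrank implementations)


def kappa_oracle(counts):
    t = np.asarray(counts, float)
    n = t.sum()
    po = np.trace(t) / n
    pe = (t.sum(1) / n) @ (t.sum(0) / n)
    return (po - pe) / (1 - pe)


def midranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def spearman_oracle(a, b):
    ra, rb = midranks(a), midranks(b)
    return np.corrcoef(ra, rb)[0, 1]


def friedman_oracle(m):
    """Tie-corrected Friedman chi-square from within-row midranks."""
    m = np.asarray(m, float)
    n, k = m.shape
    R = np.vstack([midranks(row) for row in m])
    col_sums = R.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    corr = 1.0 - ties / (n * k * (k**2 - 1))
    return 0.0 if corr == 0 else stat / corr


def kruskal_oracle(groups):
    pooled = np.concatenate(groups)
    ranks = midranks(pooled)
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start: start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    corr = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    return h / corr


# ---------------------------------------------------------------------------
# published 99-knee values

CT_PAIRS = ts.ContingencyTable(reference.INTRAOP_CT_COUNTS).to_pairs()
XR_PAIRS = ts.ContingencyTable(reference.INTRAOP_XRAY_COUNTS).to_pairs()


def test_build_table_reproduces_published_margins():
    t_ct = ts.build_table(*CT_PAIRS)
    assert t_ct.row_totals.tolist() == [21, 29, 35, 14]
    assert t_ct.col_totals.tolist() == [28, 31, 20, 20]
    t_xr = ts.build_table(*XR_PAIRS)
    assert t_xr.col_totals.tolist() == [50, 24, 8, 17]
    np.testing.assert_array_equal(t_ct.counts, reference.INTRAOP_CT_COUNTS)


def test_build_table_rejects_bad_input():
    with pytest.raises(ValueError):
        ts.build_table([1, 2], [1])
    with pytest.raises(ValueError):
        ts.build_table([1, 5], [1, 2])


@pytest.mark.parametrize(
    "counts,kappa3,interp",
    [
        (reference.INTRAOP_CT_COUNTS, 0.663, "substantial"),
        (reference.INTRAOP_XRAY_COUNTS, 0.304, "fair"),
    ],
)
def test_cohens_kappa_published_tables(counts, kappa3, interp):
    r = ts.cohens_kappa(ts.ContingencyTable(counts))
    assert round(r.kappa, 3) == kappa3
    assert r.interpretation == interp
    assert r.p_value < 0.01
    # closed-form check for the CT table: (74/99 - 2467/9801) / (1 - 2467/9801)
    if kappa3 == 0.663:
        assert r.kappa == pytest.approx((74 / 99 - 2467 / 9801) / (1 - 2467 / 9801))


def test_cohens_kappa_diagonal_table_is_one():
    r = ts.cohens_kappa(ts.ContingencyTable(np.diag([5, 3, 2, 4])))
    assert r.kappa == pytest.approx(1.0)


def test_cohens_kappa_matches_statsmodels():
    from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

    for counts in (reference.INTRAOP_CT_COUNTS, reference.INTRAOP_XRAY_COUNTS):
        ours = ts.cohens_kappa(ts.ContingencyTable(counts)).kappa
        theirs = sm_kappa(counts, return_results=True).kappa
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_kappa_symmetry_and_permutation_invariance():
    rng = np.random.default_rng(42)
    for _ in range(20):
        t = rng.integers(0, 10, size=(4, 4))
        t[0, 0] += 1  # non-empty
        k = ts.cohens_kappa(ts.ContingencyTable(t)).kappa
        assert ts.cohens_kappa(ts.ContingencyTable(t.T)).kappa == pytest.approx(k)
        perm = rng.permutation(4)
        tp = t[np.ix_(perm, perm)]
        assert ts.cohens_kappa(ts.ContingencyTable(tp)).kappa == pytest.approx(k)


@pytest.mark.parametrize(
    "pairs,rho2",
    [(CT_PAIRS, 0.75), (XR_PAIRS, 0.56)],
)
def test_spearman_published_pairs(pairs, rho2):
    rho, p = ts.spearman_tied(*pairs)
    assert round(rho, 2) == rho2
    assert p < 0.001


def test_spearman_monotone_no_ties_is_one():
    rho, _ = ts.spearman_tied([1, 2, 5, 9], [2, 4, 11, 30])
    assert rho == pytest.approx(1.0)


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(st.integers(1, 4), min_size=4, max_size=30),
    st.data(),
)
def test_spearman_matches_midrank_pearson_oracle(a, data):
    b = data.draw(st.lists(st.integers(1, 4), min_size=len(a), max_size=len(a)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        with pytest.raises(ZeroDivisionError):
            ts.spearman_tied(a, b)
        return
    rho, _ = ts.spearman_tied(a, b)
    assert rho == pytest.approx(spearman_oracle(a, b), abs=1e-12)


@pytest.mark.parametrize(
    "margins,expected",
    [
        ((50, 24, 8, 17), (1, 1, 2)),  # X-ray
        ((21, 29, 35, 14), (2, 2, 3)),  # intraoperative
        ((28, 31, 20, 20), (2, 1, 3)),  # CT
    ],
)
def test_ordinal_median_iqr_published_margins(margins, expected):
    grades = np.repeat([1, 2, 3, 4], margins)
    assert ts.ordinal_median_iqr(grades) == expected


def test_friedman_identical_columns_zero():
    r = ts.friedman_test(np.tile([2, 2, 2], (5, 1)))
    assert r.statistic == 0.0
    assert r.p_value == 1.0


def test_friedman_perfect_ordering_closed_form():
    # three strictly ordered treatments, n=10: statistic = 2n = 20
    m = np.tile([1, 2, 3], (10, 1))
    r = ts.friedman_test(m, posthoc=False)
    assert r.statistic == pytest.approx(20.0)
    assert r.statistic == pytest.approx(friedman_oracle(m))


def test_friedman_matches_oracle_on_exhaustive_small_configurations():
    """All 3^4 matrices of 4 subjects x 3 canonical within-row patterns."""
    patterns = [(1, 2, 3), (2, 1, 3), (1, 1, 2)]
    from itertools import product

    for rows in product(range(3), repeat=4):
        m = np.array([patterns[i] for i in rows], dtype=float)
        got = ts.friedman_test(m, posthoc=False).statistic
        assert got == pytest.approx(friedman_oracle(m), abs=1e-10), rows


def test_friedman_posthoc_detects_lenient_method():
    # simulated cohort: X-ray grades stochastically lower than intraop
    from tibdefect.phantom import CohortSpec, simulate_cohort

    df = simulate_cohort(CohortSpec(n_knees=400, seed=11))
    m = df[["intraop", "ct", "xray"]].to_numpy()
    r = ts.friedman_test(m)
    assert r.p_value < 0.05
    assert df["xray"].mean() < df["intraop"].mean()
    # intraop-vs-xray pairwise comparison significant
    assert r.posthoc[(0, 2)][1] < 0.05


def test_kruskal_identical_groups_zero():
    r = ts.kruskal_wallis([[3, 3, 3], [3, 3], [3, 3, 3, 3]])
    assert r.statistic == 0.0


def test_kruskal_hand_computed_value():
    # ranks 1..6 with no ties: H = 3.857 (3 dp)
    r = ts.kruskal_wallis([[1, 2, 3], [4, 5, 6]], posthoc=False)
    assert round(r.statistic, 3) == 3.857
    assert r.statistic == pytest.approx(kruskal_oracle([[1, 2, 3], [4, 5, 6]]))


def test_kruskal_matches_oracle_with_ties():
    rng = np.random.default_rng(3)
    for _ in range(25):
        groups = [rng.integers(1, 5, size=rng.integers(3, 9)) for _ in range(3)]
        if np.ptp(np.concatenate(groups)) == 0:
            continue
        got = ts.kruskal_wallis(groups, posthoc=False).statistic
        assert got == pytest.approx(kruskal_oracle(groups), abs=1e-10)


def test_kruskal_requires_two_groups():
    with pytest.raises(ValueError):
        ts.kruskal_wallis([[1, 2, 3]])


@pytest.mark.parametrize(
    "kappa,band",
    [
        (-0.2, "poor"), (0.0, "poor"),
        (0.01, "slight"), (0.20, "slight"), (0.21, "fair"),
        (0.40, "fair"), (0.41, "moderate"),
        (0.60, "moderate"), (0.61, "substantial"),
        (0.80, "substantial"), (0.81, "almost perfect"), (1.0, "almost perfect"),
    ],
)
def test_landis_koch_band_edges(kappa, band):
    assert ts.landis_koch(kappa) == band


def test_spearman_sensitivity_published_design():
    # n = 99, alpha = .05 two-tailed, 80% power -> minimal detectable rho 0.28
    assert round(ts.spearman_sensitivity(99, 0.05, 0.80), 2) == 0.28


def test_sensitivity_and_power_are_mutual_inverses():
    for n in (10, 50, 99, 500):
        for power in (0.5, 0.8, 0.95):
            rho = ts.spearman_sensitivity(n, 0.05, power)
            assert ts.power_at(n, rho, 0.05) == pytest.approx(power, abs=1e-10)


def test_power_at_null_is_half_alpha():
    assert ts.power_at(99, 0.0, 0.05) == pytest.approx(0.025, abs=1e-6)


def test_power_monotone_in_n_and_rho():
    powers_n = [ts.power_at(n, 0.3) for n in (10, 30, 90, 300)]
    assert all(a < b for a, b in zip(powers_n, powers_n[1:]))
    powers_r = [ts.power_at(99, r) for r in (0.1, 0.2, 0.3, 0.5)]
    assert all(a < b for a, b in zip(powers_r, powers_r[1:]))


def test_power_input_validation():
    with pytest.raises(ValueError):
        ts.power_at(3, 0.3)
    with pytest.raises(ValueError):
        ts.spearman_sensitivity(99, alpha=1.5)
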