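"""DI, lifespan pairing, exact signed-rank testing, windows and correlations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repeatlens import density_stats as ds
from repeatlens.landscape import TEInsertion
from repeatlens.rmsk_io import GeneFeatureSet


def make_ins(start, cls="LINE", div=0.01, chrom="chr1", bp=100):
    return TEInsertion(query_name=chrom, span=(start, start + bp), total_bp=bp,
                       te_class=cls, family="X", divergence=div,
                       insertion_id=start + 1, n_fragments=1)


def profile(name, years):
    return ds.SpeciesProfile(name, years, 100.0, 2.0)


# -- recent selection and DI -------------------------------------------------

def test_select_recent_strict_boundary_and_class_filter():
    ins = [make_ins(0, div=0.029), make_ins(100, div=0.030),
           make_ins(200, cls="LTR", div=0.01), make_ins(300, cls="SINE", div=0.0)]
    kept = ds.select_recent(ins)
    assert [i.start for i in kept] == [0, 300]


def test_select_recent_matches_simulator_truth(truth):
    ins = truth.as_te_insertions()
    assert len(ds.select_recent(ins)) == truth.recent_count()


def test_density_of_insertion():
    assert ds.density_of_insertion(9000, 2.0) == 4500
    assert ds.density_of_insertion(0, 2.0) == 0
    with pytest.raises(ValueError):
        ds.density_of_insertion(10, 0.0)


@given(st.integers(0, 10**6), st.floats(0.1, 10))
def test_di_scale_consistency(n, gb):
    """Doubling both the count and the assembly size leaves DI unchanged."""
    assert ds.density_of_insertion(2 * n, 2 * gb) == \
        pytest.approx(ds.density_of_insertion(n, gb))


# -- lifespan pairing --------------------------------------------------------

def test_make_pairs_examples():
    a, b = profile("A", 31), profile("B", 3.8)
    (p,) = ds.make_pairs([a, b])
    assert p.long_species is a and p.short_species is b
    # boundary: ratio exactly two-fold is included
    (p2,) = ds.make_pairs([profile("A", 8), profile("B", 4)])
    assert p2.lifespan_ratio == 2


def test_bundled_cohort_yields_25_pairs():
    profiles = ds.bundled_species_table()
    assert len(profiles) == 10
    assert len(ds.make_pairs(profiles)) == 25


@given(st.lists(st.floats(1, 100), min_size=2, max_size=8, unique=True))
def test_make_pairs_equals_brute_force(lifespans):
    profiles = [profile(f"s{i}", y) for i, y in enumerate(lifespans)]
    got = {(p.long_species.species_name, p.short_species.species_name)
           for p in ds.make_pairs(profiles)}
    want = {(a.species_name, b.species_name)
            for a in profiles for b in profiles
            if a is not b and a.max_lifespan_years >= 2 * b.max_lifespan_years}
    assert got == want


# -- signed-rank test --------------------------------------------------------

def enumerate_signed_rank_p(diffs, alternative):
    """Full 2^n enumeration over sign assignments; oracle for the DP."""
    d = np.array([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    p_less = sum(w <= w_obs + 1e-9 for w in ws) / 2 ** n
    p_greater = sum(w >= w_obs - 1e-9 for w in ws) / 2 ** n
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def test_signed_rank_small_examples():
    _, p = ds.wilcoxon_signed_rank([-1, -2, -3], alternative="less")
    assert p == pytest.approx(0.125)
    _, p1 = ds.wilcoxon_signed_rank([-5], alternative="less")
    assert p1 == pytest.approx(0.5)
    with pytest.raises(ValueError):
        ds.wilcoxon_signed_rank([0.0, 0.0])


def test_signed_rank_headline_n25():
    d = -np.arange(1, 26, dtype=float)
    _, p_one = ds.wilcoxon_signed_rank(d, alternative="less")
    _, p_two = ds.wilcoxon_signed_rank(d, alternative="two_sided")
    assert p_one == pytest.approx(1 / 2**25)
    assert p_two == pytest.approx(2 / 2**25)


@pytest.mark.parametrize("n", range(1, 13))
def test_signed_rank_exact_equals_enumeration(n):
    rng = np.random.default_rng(100 + n)
    for _ in range(3):
        d = rng.normal(size=n)
        while len(np.unique(np.abs(d))) != n:
            d = rng.normal(size=n)
        for alt in ("less", "greater", "two_sided"):
            _, p = ds.wilcoxon_signed_rank(d, alternative=alt, method="exact")
            assert p == pytest.approx(enumerate_signed_rank_p(d, alt), abs=1e-12)


def test_signed_rank_agrees_with_scipy():
    rng = np.random.default_rng(1)
    d = rng.normal(size=14)
    for alt, scipy_alt in [("less", "less"), ("greater", "greater"),
                           ("two_sided", "two-sided")]:
        _, p = ds.wilcoxon_signed_rank(d, alternative=alt)
        ref = stats.wilcoxon(d, alternative=scipy_alt, mode="exact").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


def test_signed_rank_normal_approx_with_ties():
    d = [1.0, -1.0, 2.0, 2.0, -3.0, 4.0, -4.0, 5.0, 6.0, -6.0]
    _, p = ds.wilcoxon_signed_rank(d, alternative="two_sided")
    ref = stats.wilcoxon(d, alternative="two-sided", mode="approx",
                         correction=True).pvalue
    assert p == pytest.approx(ref, rel=1e-6)


def test_signed_rank_type_i_calibration_independent_differences():
    """On iid null differences the exact test rejects at ~alpha."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        d = rng.normal(size=25)
        _, p = ds.wilcoxon_signed_rank(d, alternative="less")
        rejections += p < 0.05
    assert abs(rejections / n_rep - 0.05) < 0.03


def test_paired_di_test_power_at_twofold_contrast():
    """Cohorts with ~2x lower recent rates in long-lived species are detected."""
    profiles = ds.bundled_species_table()
    long_lived = {p.species_name for p in profiles
                  if p.phenotype.startswith("long_lived")}
    rng = np.random.default_rng(9)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        di = {p.species_name:
              rng.poisson(30 if p.species_name in long_lived else 60) / 2.0
              for p in profiles}
        res = ds.paired_di_test(di, profiles, alternative="less")
        hits += res["p_value"] < 0.05
    assert hits / n_rep >= 0.99


# -- windows -----------------------------------------------------------------

def test_window_density_counts_example():
    ins = [make_ins(100_000), make_ins(1_200_000), make_ins(1_300_000)]
    track = ds.window_density(ins, {"chr1": 3_000_000}, 1_000_000)
    assert list(track.counts) == [1, 2, 0]
    assert track.mean_density == pytest.approx(1.0)


def test_window_density_empty_and_sum_invariant(truth):
    track = ds.window_density([], {"chr1": 3_000_000}, 1_000_000)
    assert track.counts.sum() == 0
    ins = truth.as_te_insertions()
    t2 = ds.window_density(ins, {c: len(s) for c, s in truth.genome.items()},
                           50_000)
    assert t2.counts.sum() == len(ins)


def test_window_density_partial_window_normalized():
    ins = [make_ins(2_500_000)]
    track = ds.window_density(ins, {"chr1": 2_500_100}, 1_000_000)
    assert track.windows[-1] == ("chr1", 2_000_000, 2_500_100)
    assert track.density[-1] == pytest.approx(1 / 0.5001)


def test_window_density_uniform_rate_poisson():
    rng = np.random.default_rng(12)
    lam = 5.0  # per Mb
    n = rng.poisson(lam * 100)
    ins = [make_ins(int(p)) for p in
           np.sort(rng.integers(0, 100_000_000, size=n))]
    track = ds.window_density(ins, {"chr1": 100_000_000}, 1_000_000)
    se = math.sqrt(lam / len(track.windows))
    assert abs(track.mean_density - lam) < 3 * se


def test_feature_density_and_gene_free_chromosome():
    fs = GeneFeatureSet(
        genes={"chr1": [(10_000, 20_000), (50_000, 60_000)], "chr2": []},
        exons={"chr1": [(10_000, 12_000)], "chr2": []},
        chrom_lengths={"chr1": 2_000_000, "chr2": 1_000_000})
    track = ds.window_density([], {"chr1": 2_000_000, "chr2": 1_000_000},
                              1_000_000)
    table = ds.feature_density(fs, track)
    chr1w1 = table[(table.chrom == "chr1") & (table.start == 0)].iloc[0]
    assert chr1w1.gene_density == pytest.approx(2.0)
    # gene-free chromosome: a single intergenic interval covering it
    assert fs.intergenic["chr2"] == [(0, 1_000_000)]
    chr2 = table[table.chrom == "chr2"].iloc[0]
    assert chr2.intergenic_density == pytest.approx(1.0)


# -- correlations and rich/poor contrast -------------------------------------

def test_spearman_monotone_and_exact_enumeration():
    x = np.arange(1.0, 7.0)
    rho, _ = ds.spearman_corr(x, x**2)
    assert rho == pytest.approx(1.0)
    rho2, _ = ds.spearman_corr(x, -x)
    assert rho2 == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        ds.spearman_corr(x, np.ones(6))

    rng = np.random.default_rng(5)
    y = rng.normal(size=6)
    rho3, p_exact = ds.spearman_corr(x, y, exact=True)
    # oracle: full 6! enumeration done independently here
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rcorr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return a @ b / math.sqrt((a @ a) * (b @ b))

    obs = abs(rcorr(rx, ry))
    hits = sum(abs(rcorr(rx, np.array(p))) >= obs - 1e-12
               for p in itertools.permutations(ry))
    assert p_exact == pytest.approx(hits / math.factorial(6))
    assert rho3 == pytest.approx(stats.spearmanr(x, y).statistic)


def test_classify_windows_worked_example():
    labels = ds.classify_windows([1, 2, 3, 4, 5, 6, 7, 8])
    assert np.quantile([1, 2, 3, 4, 5, 6, 7, 8], 0.25) == pytest.approx(2.75)
    assert list(labels) == ["gene_poor", "gene_poor", "neither", "neither",
                            "neither", "neither", "gene_rich", "gene_rich"]


def test_classify_windows_degenerate_all_equal():
    assert list(ds.classify_windows([3, 3, 3, 3])) == ["neither"] * 4
    with pytest.raises(ValueError):
        ds.classify_windows([1, 2, 3])


def test_compare_rich_poor_exact_and_identical():
    _, p = ds.compare_rich_poor([5, 6, 7], [1, 2, 3])
    assert p == pytest.approx(0.1)  # 2 / C(6,3)
    _, p_same = ds.compare_rich_poor([1, 2, 3], [1, 2, 3])
    assert p_same == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ds.compare_rich_poor([], [1.0])


def test_compare_rich_poor_power():
    rng = np.random.default_rng(17)
    hits = 0
    for _ in range(200):
        a = rng.normal(2.0, 1.0, size=50)
        b = rng.normal(0.0, 1.0, size=50)
        _, p = ds.compare_rich_poor(a, b)
        hits += p < 0.05
    assert hits / 200 >= 0.95
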