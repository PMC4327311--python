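import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from heterosiskit.core_io import MISSING, TrioRecord
from heterosiskit.heterosis import (
    ClassMeans,
    combination_census,
    correlate,
    count_overdominant,
    define_superior_allele,
    dominance_at_site,
    dominance_degree,
    genotype_class_means,
    rare_allele_enrichment_ratio,
    superior_profiles,
    top2_share,
    trio_heterosis,
)
from heterosiskit.synthetic_data import QTL, SimConfig, simulate
from conftest import hwe_panel, make_matrix, pheno_vector


def means(m_rr, m_ra, m_aa, n=100):
    return ClassMeans(m_rr=m_rr, m_ra=m_ra, m_aa=m_aa, n_rr=n, n_ra=n, n_aa=n)


# ---------------------------------------------------------------------------
# class means and dominance degree
# ---------------------------------------------------------------------------

def test_genotype_class_means_basics():
    gm = make_matrix([[0], [0], [1], [2], [MISSING]])
    y = np.array([10.0, 12.0, 20.0, 30.0, 99.0])
    cm = genotype_class_means(y, 0, gm)
    assert cm.m_rr == 11.0 and cm.m_ra == 20.0 and cm.m_aa == 30.0
    assert (cm.n_rr, cm.n_ra, cm.n_aa) == (2, 1, 1)
    # constant phenotype -> equal means; empty class -> NaN, not zero
    cm2 = genotype_class_means(np.full(5, 7.0), 0, gm)
    assert cm2.m_rr == cm2.m_ra == cm2.m_aa == 7.0
    gm3 = make_matrix([[0], [0], [2]])
    cm3 = genotype_class_means(np.array([1.0, 2.0, 3.0]), 0, gm3)
    assert np.isnan(cm3.m_ra) and cm3.n_ra == 0


def test_class_means_recover_planted_values():
    rng = np.random.default_rng(0)
    codes = rng.choice([0, 1, 2], size=(300, 1), p=[0.3, 0.5, 0.2])
    gm = make_matrix(codes)
    planted = {0: 10.0, 1: 15.0, 2: 20.0}
    y = np.array([planted[int(c)] for c in codes[:, 0]]) + rng.normal(0, 1, 300)
    cm = genotype_class_means(y, 0, gm)
    for c, attr in ((0, "m_rr"), (1, "m_ra"), (2, "m_aa")):
        n = (codes[:, 0] == c).sum()
        assert getattr(cm, attr) == pytest.approx(planted[c], abs=3 / np.sqrt(n))


@pytest.mark.parametrize(
    "m,exp_a,exp_d,exp_deg,exp_cls",
    [
        ((10, 15, 20), 5.0, 0.0, 0.0, "additive"),
        ((10, 20, 20), 5.0, 5.0, 1.0, "complete"),
        ((10, 23, 20), 5.0, 8.0, 1.6, "overdominant-positive"),
        ((20, 7, 10), 5.0, -8.0, -1.6, "overdominant-negative"),
    ],
)
def test_dominance_degree_closed_forms(m, exp_a, exp_d, exp_deg, exp_cls):
    rec = dominance_degree(means(*m))
    assert rec.a == pytest.approx(exp_a)
    assert rec.d == pytest.approx(exp_d)
    assert rec.degree == pytest.approx(exp_deg)
    assert rec.classification == exp_cls
    assert not rec.excluded


def test_dominance_degree_undefined_and_count_filter():
    rec = dominance_degree(means(10, 15, 10))  # a = 0
    assert np.isnan(rec.degree) and rec.classification == "undefined"
    # heterozygote count of exactly 15 triggers the exclusion rule
    cm = ClassMeans(10, 20, 30, n_rr=100, n_ra=15, n_aa=100)
    assert dominance_degree(cm).excluded
    cm2 = ClassMeans(10, 20, 30, n_rr=100, n_ra=16, n_aa=16)
    assert not dominance_degree(cm2).excluded
    # minor homozygote count <= 15 also excludes
    cm3 = ClassMeans(10, 20, 30, n_rr=15, n_ra=100, n_aa=100)
    assert dominance_degree(cm3).excluded


@settings(max_examples=40, deadline=None)
@given(scale=stn.floats(0.1, 50), shift=stn.floats(-100, 100))
def test_dominance_degree_affine_invariant(scale, shift):
    base = means(10.0, 23.0, 20.0)
    rec0 = dominance_degree(base)
    rec1 = dominance_degree(
        means(10.0 * scale + shift, 23.0 * scale + shift, 20.0 * scale + shift)
    )
    assert rec1.degree == pytest.approx(rec0.degree, rel=1e-9)
    assert rec1.classification == rec0.classification


def test_orientation_invariance_under_allele_swap():
    """Swapping ref/alt labels flips a's orientation and the superior allele
    but leaves |d/a|, the classification and the profiles unchanged."""
    rng = np.random.default_rng(1)
    codes = rng.choice([0, 1, 2], size=(400, 3), p=[0.4, 0.4, 0.2])
    gm = make_matrix(codes)
    gm_sw = make_matrix(2 - codes)
    y = codes[:, 0] * 2.0 + (codes[:, 0] == 1) * 3.0 + rng.normal(0, 1, 400)
    rec = dominance_at_site(y, 0, gm, n_boot=0)
    rec_sw = dominance_at_site(y, 0, gm_sw, n_boot=0)
    assert abs(rec_sw.degree) == pytest.approx(abs(rec.degree))
    assert rec_sw.classification == rec.classification
    al = define_superior_allele(genotype_class_means(y, 0, gm))
    al_sw = define_superior_allele(genotype_class_means(y, 0, gm_sw))
    assert {al, al_sw} == {"ref", "alt"}
    sites = [0, 1, 2]
    prof = superior_profiles(gm, sites, [al, "alt", "ref"])
    prof_sw = superior_profiles(gm_sw, sites, [al_sw, "ref", "alt"])
    assert prof["n_superior_alleles"].equals(prof_sw["n_superior_alleles"])
    assert prof["n_het_superior"].equals(prof_sw["n_het_superior"])


def test_planted_effects_recovered_without_bias():
    """Across 20 seeds at n=800 the mean estimated (a, d) are within 5% of a
    of the planted values."""
    a_est, d_est = [], []
    for s in range(20):
        cfg = SimConfig(seed=100 + s, n_hybrids=800, n_snps=500, n_maternal=40,
                        n_paternal=40,
                        qtls=[QTL(250, "yield", a=3.0, d=1.5, superior_freq=0.3)],
                        heritability={"yield": 0.8}, sweep=None,
                        error_rate=0.0, missing_rate=0.0)
        res = simulate(cfg)
        y = pheno_vector(res, "yield", "envA")
        rec = dominance_degree(genotype_class_means(y, 250, res.hybrids))
        a_est.append(rec.a)
        d_est.append(rec.d)
    assert abs(np.mean(a_est) - 3.0) < 0.05 * 3.0
    assert abs(np.mean(d_est) - 1.5) < 0.05 * 3.0


def test_overdominant_census_recovers_planted_10_plus_3():
    """A founder-rich panel with 10 positive and 3 negative strong
    overdominant QTLs: the point-estimate census recovers at least 12 of the
    13 with correct signs and calls no additive QTL overdominant."""
    slots = (np.linspace(0.05, 0.95, 17) * 2000).astype(int)
    qtls = [QTL(int(s), "yield", a=3.0, d=6.0 if i < 10 else -6.0,
                superior_freq=0.5) for i, s in enumerate(slots[:13])]
    qtls += [QTL(int(s), "yield", a=3.0, d=0.0, superior_freq=0.5)
             for s in slots[13:]]
    cfg = SimConfig(seed=1, n_hybrids=1500, n_snps=2000, n_maternal=250,
                    n_paternal=250, usage_exponent=0.5, qtls=qtls,
                    heritability={"yield": 0.8}, sweep=None)
    res = simulate(cfg)
    y = pheno_vector(res, "yield", "envA")
    recs_od = [dominance_at_site(y, q.site_index, res.hybrids, n_boot=0)
               for q in qtls[:13]]
    recs_add = [dominance_at_site(y, q.site_index, res.hybrids, n_boot=0)
                for q in qtls[13:]]
    correct = sum(
        (q.d > 0 and r.classification == "overdominant-positive")
        or (q.d < 0 and r.classification == "overdominant-negative")
        for q, r in zip(qtls[:13], recs_od) if not r.excluded
    )
    assert correct >= 12
    assert count_overdominant(recs_add) == (0, 0)


# ---------------------------------------------------------------------------
# superior alleles
# ---------------------------------------------------------------------------

def test_define_superior_allele_directions_and_tie():
    assert define_superior_allele(means(10, 15, 20), True) == "alt"
    assert define_superior_allele(means(10, 15, 20), False) == "ref"
    assert define_superior_allele(means(10, 15, 10)) is None  # tie
    assert define_superior_allele(
        ClassMeans(np.nan, 15, 20, 0, 10, 10)) is None


def test_superior_profiles_limits_and_brute_force():
    k = 4
    gm = make_matrix(np.full((1, k), 2, np.int8))
    prof = superior_profiles(gm, list(range(k)), ["alt"] * k)
    assert prof.loc[0, "n_superior_alleles"] == 2 * k
    assert prof.loc[0, "n_het_superior"] == 0

    gm2 = make_matrix(np.ones((1, k), np.int8))
    prof2 = superior_profiles(gm2, list(range(k)), ["alt"] * k)
    assert prof2.loc[0, "n_superior_alleles"] == k
    assert prof2.loc[0, "n_het_superior"] == k

    rng = np.random.default_rng(2)
    codes = rng.choice([-1, 0, 1, 2], size=(50, 6), p=[0.05, 0.35, 0.3, 0.3])
    gm3 = make_matrix(codes)
    alleles = ["alt", "ref", "alt", None, "ref", "alt"]
    prof3 = superior_profiles(gm3, list(range(6)), alleles)
    for i in range(50):
        dose = het = 0
        for j, al in enumerate(alleles):
            c = codes[i, j]
            if al is None or c == MISSING:
                continue
            dose += c if al == "alt" else 2 - c
            het += c == 1
        assert prof3.loc[i, "n_superior_alleles"] == dose
        assert prof3.loc[i, "n_het_superior"] == het


def test_correlate_exact_null_and_ordering(default_sim):
    rng = np.random.default_rng(3)
    gm = hwe_panel(300, 20, rng)
    prof = superior_profiles(gm, list(range(20)), ["alt"] * 20)
    y_exact = 2.0 * prof["n_superior_alleles"].to_numpy() + 1.0
    corr = correlate(prof, y_exact).set_index("predictor")
    assert corr.loc["n_superior_alleles", "pearson_r"] == pytest.approx(1.0)
    y_noise = rng.normal(size=300)
    corr2 = correlate(prof, y_noise).set_index("predictor")
    assert abs(corr2.loc["n_superior_alleles", "pearson_r"]) < 0.2

    # on the reference panel, accumulated superior alleles out-predict
    # whole-genome heterozygosity for a rare-superior-allele trait
    qtl_sites = [q.site_index for q in default_sim.truth.qtls
                 if q.trait == "grain_number"]
    y = pheno_vector(default_sim, "grain_number", "envA")
    alleles = [
        define_superior_allele(genotype_class_means(y, s, default_sim.hybrids))
        for s in qtl_sites
    ]
    prof_h = superior_profiles(default_sim.hybrids, qtl_sites, alleles)
    corr_h = correlate(prof_h, y).set_index("predictor")
    assert (corr_h.loc["n_superior_alleles", "pearson_r"]
            > abs(corr_h.loc["heterozygosity", "pearson_r"]))


def test_correlate_zero_variance_flagged():
    gm = make_matrix(np.zeros((20, 3), np.int8))
    prof = superior_profiles(gm, [0, 1, 2], ["alt"] * 3)
    corr = correlate(prof, np.arange(20.0)).set_index("predictor")
    assert corr.loc["n_superior_alleles", "zero_variance"]
    assert np.isnan(corr.loc["n_superior_alleles", "pearson_r"])


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def _phen_df(rows):
    import pandas as pd

    return pd.DataFrame(rows, columns=["individual", "trait", "environment",
                                       "value"])


def test_trio_heterosis_arithmetic_and_classes():
    trios = [TrioRecord("H1", "M1", "F1"), TrioRecord("H2", "M2", "F2"),
             TrioRecord("H3", "M3", "F3")]
    phen = _phen_df([
        ("M1", "t", "e", 100.0), ("F1", "t", "e", 120.0), ("H1", "t", "e", 121.0),
        ("M2", "t", "e", 100.0), ("F2", "t", "e", 120.0), ("H2", "t", "e", 110.0),
        ("M3", "t", "e", -5.0), ("F3", "t", "e", 5.0), ("H3", "t", "e", 10.0),
    ])
    recs, props = trio_heterosis(trios, phen, "t", "e")
    by = {r.trio.hybrid: r for r in recs}
    assert by["H1"].mph == pytest.approx(0.1)
    assert by["H1"].over_parent_class == "positive"
    assert by["H2"].mph == pytest.approx(0.0)
    assert by["H2"].over_parent_class == "within-parental-range"
    assert np.isnan(by["H3"].mph)  # MP = 0 -> undefined index
    assert by["H3"].over_parent_class == "positive"
    assert props["positive"] == pytest.approx(2 / 3)


def test_dominance_rich_trait_shows_majority_positive_heterosis(default_sim):
    """With pervasive positive dominance, most trios show F1 above the
    better parent (and the heading-date trait, with negative dominance,
    shows the mirror image)."""
    trios = default_sim.observed_trios
    assert len(trios) > 30
    _, props = trio_heterosis(trios, default_sim.phenotypes,
                              "grain_number", "envA")
    assert props["positive"] > max(props["negative"],
                                   props["within-parental-range"])
    _, props_hd = trio_heterosis(trios, default_sim.phenotypes,
                                 "heading_date", "envA")
    assert props_hd["negative"] > props_hd["positive"]


# ---------------------------------------------------------------------------
# enrichment ratio and census
# ---------------------------------------------------------------------------

def test_rare_allele_enrichment_ratio():
    assert rare_allele_enrichment_ratio(1e-6) == pytest.approx(2.0, abs=1e-5)
    assert rare_allele_enrichment_ratio(0.5) == pytest.approx(1.0)
    assert rare_allele_enrichment_ratio(0.05) == pytest.approx(1.9)
    for bad in (0.0, 1.0, -0.1):
        with pytest.raises(ValueError):
            rare_allele_enrichment_ratio(bad)


def test_combination_census_counts_and_exclusions():
    rng = np.random.default_rng(4)
    codes = rng.choice([-1, 0, 1, 2], size=(200, 3), p=[0.04, 0.32, 0.32, 0.32])
    gm = make_matrix(codes)
    census, n_possible, n_excl = combination_census(gm, [0, 1, 2])
    assert n_possible == 27
    complete = (codes != MISSING).all(axis=1)
    assert n_excl == int((~complete).sum())
    assert census["count"].sum() == int(complete.sum())
    # brute-force tabulation matches
    from collections import Counter

    brute = Counter(tuple(int(c) for c in row) for row in codes[complete])
    for _, row in census.iterrows():
        assert brute[row["classes"]] == row["count"]
    assert 0 < top2_share(census) <= 1
    with pytest.raises(ValueError):
        combination_census(gm, [0])
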