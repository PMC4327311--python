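import numpy as np
import pytest

from heterosiskit.core_io import MISSING, site_stats
from heterosiskit.popscan import (
    flag_het_outliers,
    het_deviation,
    hudson_fst_per_site,
    individual_heterozygosity,
    sweep_scan,
    windowed_fst,
    windowed_pi,
)
from heterosiskit.synthetic_data import SimConfig, simulate_founders
from conftest import hwe_panel, make_matrix


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def test_individual_heterozygosity_limits():
    gm = make_matrix([[0, 2, 0, 2], [1, 1, 1, 1], [MISSING, MISSING, MISSING, MISSING]])
    het = individual_heterozygosity(gm)
    assert het["I1"] == 0.0
    assert het["I2"] == 1.0
    assert np.isnan(het["I3"])


def test_f1_heterozygosity_equals_parental_discordance(clean_sim):
    truth = clean_sim.truth
    het = individual_heterozygosity(clean_sim.hybrids)
    for trio in truth.trios[:10]:
        disc = (truth.maternal.genotypes_of(trio.mother)
                != truth.paternal.genotypes_of(trio.father)).mean()
        assert het[trio.hybrid] == pytest.approx(disc)


def test_het_deviation_closed_forms():
    gm = make_matrix([[1], [1]])  # all het, p = 0.5
    dev = het_deviation(site_stats(gm))
    assert dev.iloc[0] == pytest.approx(0.5)
    mono = make_matrix([[0], [0]])
    assert het_deviation(site_stats(mono)).iloc[0] == 0.0


def test_hwe_deviation_concentrates_near_zero():
    """Under random mating Ho - He stays within binomial sampling bounds."""
    rng = np.random.default_rng(4)
    gm = hwe_panel(500, 400, rng)
    stats = site_stats(gm)
    dev = het_deviation(stats).to_numpy()
    bound = 1.96 * np.sqrt(stats["he"] * (1 - stats["he"]) / 500).to_numpy()
    assert np.mean(np.abs(dev) <= bound + 1e-9) > 0.9


def test_flag_het_outliers_empty_and_merge():
    rng = np.random.default_rng(5)
    gm = hwe_panel(200, 50, rng)
    assert flag_het_outliers(site_stats(gm)) == []

    # two deficit SNPs 10 kb apart merge into one locus at 100 kb linkage
    codes = np.zeros((100, 2), np.int8)
    codes[:50] = 2  # p = 0.5, Ho = 0 at both sites -> deviation -0.5
    gm2 = make_matrix(codes, spacing=10_000)
    loci = flag_het_outliers(site_stats(gm2), merge_distance=100_000)
    assert len(loci) == 1
    assert loci[0].direction == "deficit"
    assert len(loci[0].positions) == 2
    assert loci[0].peak_deviation == pytest.approx(-0.5)


def test_incompatibility_locus_flagged_as_single_deficit(default_sim):
    """The planted heterozygote-eliminating locus shows up as the one
    Ho - He < -0.4 locus, containing the true site."""
    stats = site_stats(default_sim.hybrids)
    loci = flag_het_outliers(stats)
    deficits = [l for l in loci if l.direction == "deficit"]
    assert len(deficits) == 1
    inc = default_sim.truth.incompatibility
    pos = default_sim.hybrids.positions[inc.site_index]
    chrom = default_sim.hybrids.chroms[inc.site_index]
    assert deficits[0].chrom == chrom
    assert deficits[0].start <= pos - 1 < deficits[0].end


# ---------------------------------------------------------------------------
# windowed pi
# ---------------------------------------------------------------------------

def test_windowed_pi_closed_form_single_site():
    """One site, 2 diploids, p = 0.5: pi = 2*0.25*(4/3)/1e5."""
    gm = make_matrix([[0], [2]])
    pi = windowed_pi(gm, window=100_000)
    assert pi["value"].iloc[0] == pytest.approx(2 * 0.25 * (4 / 3) / 1e5)


def test_windowed_pi_zero_for_monomorphic_and_identical():
    gm = make_matrix(np.zeros((4, 10), np.int8), spacing=5000)
    pi = windowed_pi(gm)
    assert pi["value"].iloc[0] == 0.0
    assert not pi["excluded"].iloc[0]


def test_windowed_pi_matches_pairwise_difference_oracle():
    """Summed unbiased per-site heterozygosity equals the brute-force mean
    pairwise allele difference on an inbred (haploid-equivalent) panel."""
    rng = np.random.default_rng(6)
    cfg = SimConfig(seed=6, n_maternal=12, n_paternal=5, n_landrace=5,
                    n_snps=1000, n_diff_sites=0, qtls=[], sweep=None,
                    incompatibility=None)
    panel, _, _ = simulate_founders(cfg, rng)
    window = 100_000
    pi = windowed_pi(panel, window=window, inbred=True)
    haps = panel.codes // 2  # inbred: one allele per line
    n = haps.shape[0]
    pos0 = panel.positions - 1
    for _, row in pi.iterrows():
        if row["excluded"]:
            continue
        sel = ((panel.chroms == row["chrom"]) & (pos0 >= row["start"])
               & (pos0 < row["end"]))
        total = 0.0
        for j in np.flatnonzero(sel):
            col = haps[:, j]
            diff = sum(abs(int(col[i]) - int(col[k]))
                       for i in range(n) for k in range(i + 1, n))
            total += diff / (n * (n - 1) / 2)
        assert row["value"] == pytest.approx(total / window, abs=1e-12)


# ---------------------------------------------------------------------------
# sweep scan
# ---------------------------------------------------------------------------

def test_sweep_scan_null_ratios_near_one():
    rng = np.random.default_rng(7)
    q = rng.uniform(0.2, 0.8, 600)
    a = hwe_panel(150, 600, rng, q=q, n_chrom=3)
    b = hwe_panel(150, 600, rng, q=q, n_chrom=3)
    ratio, loci = sweep_scan(windowed_pi(a), windowed_pi(b), top_fraction=0.01)
    usable = ratio.loc[~ratio["excluded"], "value"]
    assert usable.median() == pytest.approx(1.0, abs=0.1)
    assert int(loci["n_windows"].sum()) <= int(np.ceil(0.01 * len(usable))) + 1


def test_sweep_scan_excludes_low_diversity_not_infinite():
    gm_land = make_matrix(np.zeros((10, 6), np.int8), spacing=20_000)
    gm_mod = make_matrix(np.zeros((10, 6), np.int8), spacing=20_000)
    ratio, _ = sweep_scan(windowed_pi(gm_land), windowed_pi(gm_mod),
                          diversity_floor=1e-9, min_sites=1)
    assert ratio["excluded"].iloc[0]
    assert ratio["reason"].iloc[0] == "low_diversity_both"
    assert not np.isinf(ratio["value"]).any()


def test_sweep_scan_grid_mismatch_errors():
    gm = make_matrix(np.zeros((4, 5), np.int8))
    pi_a = windowed_pi(gm, window=100_000)
    pi_b = windowed_pi(gm, window=50_000)
    with pytest.raises(ValueError, match="grid"):
        sweep_scan(pi_a, pi_b)


def test_sweep_scan_recovers_planted_sweep(default_sim):
    pi_l = windowed_pi(default_sim.landrace, inbred=True)
    pi_h = windowed_pi(default_sim.hybrids)
    _, loci = sweep_scan(pi_l, pi_h)
    sw = default_sim.truth.sweep
    hits = loci[(loci["chrom"] == sw.chrom) & (loci["start"] < sw.end)
                & (loci["end"] > sw.start)]
    assert len(hits) >= 1


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def test_fst_null_and_fixed_difference():
    rng = np.random.default_rng(8)
    q = rng.uniform(0.2, 0.8, 300)
    a = hwe_panel(200, 300, rng, q=q)
    b = hwe_panel(200, 300, rng, q=q)
    fst, loci = windowed_fst(a, b)
    assert abs(fst.loc[~fst["excluded"], "value"].mean()) < 0.02
    assert len(loci) == 0

    fixed_a = make_matrix(np.zeros((20, 10), np.int8), spacing=5000)
    fixed_b = make_matrix(np.full((20, 10), 2, np.int8), spacing=5000)
    fst2, loci2 = windowed_fst(fixed_a, fixed_b)
    assert fst2["value"].iloc[0] == pytest.approx(1.0)
    assert len(loci2) == 1


def test_fst_label_swap_symmetry():
    rng = np.random.default_rng(9)
    a = hwe_panel(50, 200, rng)
    b = hwe_panel(60, 200, rng)
    f_ab, _ = windowed_fst(a, b)
    f_ba, _ = windowed_fst(b, a)
    assert np.allclose(f_ab["value"], f_ba["value"], equal_nan=True)


def test_hudson_components_match_brute_force_formula():
    """Per-site numerator/denominator equal the hand-computed Hudson terms."""
    rng = np.random.default_rng(10)
    a = hwe_panel(80, 50, rng)
    b = hwe_panel(120, 50, rng)
    table = hudson_fst_per_site(a, b)
    for j in range(50):
        ca, cb = a.codes[:, j], b.codes[:, j]
        p1 = (2 * (ca == 0).sum() + (ca == 1).sum()) / (2 * len(ca))
        p2 = (2 * (cb == 0).sum() + (cb == 1).sum()) / (2 * len(cb))
        n1, n2 = 2 * len(ca), 2 * len(cb)
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert table["num"].iloc[j] == pytest.approx(num, abs=1e-12)
        assert table["den"].iloc[j] == pytest.approx(den, abs=1e-12)


def test_fst_window_is_ratio_of_averages():
    rng = np.random.default_rng(11)
    a = hwe_panel(60, 40, rng)
    b = hwe_panel(60, 40, rng)
    fst, _ = windowed_fst(a, b, window=10_000_000)
    per_site = hudson_fst_per_site(a, b)
    expected = np.clip(per_site["num"].sum() / per_site["den"].sum(), 0, 1)
    assert fst["value"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_differentiated_loci_found_between_pools(default_sim):
    """The planted high-divergence block exceeds the Fst > 0.3 threshold."""
    fst, loci = windowed_fst(default_sim.maternal, default_sim.paternal,
                             inbred_a=True, inbred_b=True)
    assert (loci["chrom"] == "chr7").any()
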