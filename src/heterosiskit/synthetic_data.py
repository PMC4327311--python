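"""Synthetic hybrid-rice-like populations with known ground truth.

The generator emulates the structure of a three-line hybrid rice breeding
panel:

- two partially differentiated pools of fully inbred parents (maternal
  male-sterile-like lines and paternal restorer-like lines, modest Fst),
- a pool of more diverse landraces carrying ancestral diversity inside a
  designated "genetic-improvement sweep" region where the modern pools have
  been driven toward fixation,
- F1 hybrids produced by crosses with strongly unequal parent usage (a few
  popular lines sire many hybrids, as shared male-sterile lines do),
- QTLs with additive, dominant or overdominant effects, some active in only
  one of two environments (a Sanya-like "envA" and a Hangzhou-like "envB"),
  with rare superior alleles at the yield QTLs,
- a hybrid-incompatibility locus where heterozygotes are selected against,
  producing a localized heterozygote deficit,
- symmetric genotype-code error (0<->1, 1<->2 flips) and missingness applied
  to the hybrid calls after crossing.

Every draw flows from the single seed in :class:`SimConfig`; the same seed
reproduces byte-identical outputs.  Analysis stages never see the
:class:`TruthSet` except through explicit evaluation functions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    MISSING,
    GenotypeMatrix,
    TrioRecord,
    VariantSite,
    write_genotypes,
    write_phenotypes,
    write_trios,
)


@dataclass(frozen=True)
class QTL:
    """A causal site with additive effect ``a`` and dominance effect ``d``.

    Genetic contributions per genotype relative to the superior (alt) allele
    are -a (hom-inferior), d (het), +a (hom-superior).  ``environments``
    restricts in which environments the QTL is active.
    """

    site_index: int
    trait: str
    a: float
    d: float
    superior_freq: float
    environments: tuple[str, ...] = ("envA", "envB")

    @property
    def degree(self) -> float:
        """True dominance degree d/a (nan when a == 0)."""
        return self.d / self.a if self.a != 0 else float("nan")


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int  # 0-based half-open, bp
    end: int
    reduction: float = 10.0  # diversity-reduction factor in modern pools


@dataclass(frozen=True)
class IncompatibilityLocus:
    site_index: int
    penalty: float = 0.9  # probability a heterozygote is eliminated
    span: int = 50_000  # bp on each side also affected (linked selection)


def default_qtls(n_snps: int) -> list[QTL]:
    """Default causal architecture: rare superior alleles plus a 10+3
    overdominant set.

    - grain_number: 12 QTLs with partial positive dominance (d/a = 0.5) and
      rare superior alleles (frequency 0.02-0.05, NAL1/OsSPL14-like); two of
      them are envA-only.
    - yield: 10 positive-overdominant (d/a = 1.5) and 3 negative-overdominant
      (d/a = -1.5) QTLs at moderate frequency.
    - heading_date: 4 QTLs with negative dominance, two active only in envA
      (Ehd1/Hd1-like photoperiod sensitivity).
    - plant_height: 4 additive QTLs.
    """
    # spread causal sites on a coarse grid so 500-kb GWAS windows separate them
    slots = np.linspace(0.02, 0.98, 33)
    sites = (slots * n_snps).astype(int)
    qtls: list[QTL] = []
    k = 0
    freqs = [0.05, 0.02, 0.04, 0.03, 0.05, 0.02, 0.04, 0.05, 0.03, 0.04, 0.05, 0.03]
    for i in range(12):
        env = ("envA",) if i >= 10 else ("envA", "envB")
        qtls.append(QTL(int(sites[k]), "grain_number", a=3.0, d=1.5,
                        superior_freq=freqs[i], environments=env))
        k += 1
    for i in range(10):
        qtls.append(QTL(int(sites[k]), "yield", a=2.0, d=3.0,
                        superior_freq=0.25 + 0.02 * i))
        k += 1
    for i in range(3):
        qtls.append(QTL(int(sites[k]), "yield", a=2.0, d=-3.0,
                        superior_freq=0.3 + 0.05 * i))
        k += 1
    for i in range(4):
        env = ("envA",) if i >= 2 else ("envA", "envB")
        qtls.append(QTL(int(sites[k]), "heading_date", a=2.0, d=-1.5,
                        superior_freq=0.2, environments=env))
        k += 1
    for i in range(4):
        qtls.append(QTL(int(sites[k]), "plant_height", a=2.5, d=0.0,
                        superior_freq=0.15))
        k += 1
    return qtls


@dataclass
class SimConfig:
    """Generator parameters.  Defaults are the package's reference scenario:
    60 inbred parents (30 + 30), 300 hybrids, 5,000 SNPs on 12 chromosomes,
    pool differentiation Fst = 0.08, 1% genotype error, 5% missingness, and
    half of the parents observed."""

    n_maternal: int = 30
    n_paternal: int = 30
    n_landrace: int = 40
    n_hybrids: int = 300
    n_snps: int = 5000
    n_chrom: int = 12
    chrom_length: int = 2_000_000
    fst_target: float = 0.08
    landrace_fst: float = 0.02
    n_diff_sites: int = 40  # maternal/paternal strongly differentiated sites
    qtls: list[QTL] | None = None  # None -> default_qtls(n_snps)
    heritability: dict[str, float] = field(
        default_factory=lambda: {
            "grain_number": 0.6,
            "yield": 0.5,
            "plant_height": 0.6,
            "heading_date": 0.8,
        }
    )
    trait_baseline: dict[str, float] = field(
        default_factory=lambda: {
            "grain_number": 150.0,
            "yield": 30.0,
            "plant_height": 110.0,
            "heading_date": 100.0,
        }
    )
    environments: tuple[str, ...] = ("envA", "envB")
    error_rate: float = 0.01
    missing_rate: float = 0.05
    usage_exponent: float = 1.2  # truncated power-law parent usage
    observed_parent_fraction: float = 0.5
    sweep: SweepRegion | None = SweepRegion("chr1", 500_000, 1_000_000, 10.0)
    incompatibility: IncompatibilityLocus | str | None = "auto"  # "auto" -> mid chr6
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.fst_target, self.landrace_fst, self.error_rate,
                  self.missing_rate, self.observed_parent_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates/fractions must lie in [0, 1]")
        if min(self.n_maternal, self.n_paternal, self.n_landrace) < 1:
            raise ValueError("pool sizes must be positive")
        for h in self.heritability.values():
            if not 0 < h <= 1:
                raise ValueError("heritability must lie in (0, 1]")
        if self.qtls is None:
            self.qtls = default_qtls(self.n_snps)
        for q in self.qtls:
            if not 0 <= q.site_index < self.n_snps:
                raise ValueError(f"QTL site {q.site_index} out of range")
        if self.incompatibility == "auto":
            # mid chromosome 6, S5-like
            per = self.n_snps // self.n_chrom
            self.incompatibility = IncompatibilityLocus(5 * per + per // 2)


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic data."""

    maternal: GenotypeMatrix
    paternal: GenotypeMatrix
    landrace: GenotypeMatrix
    hybrids_clean: GenotypeMatrix  # pre-error, pre-missingness F1 codes
    trios: list[TrioRecord]
    observed_parents: list[str]
    qtls: list[QTL]
    genetic_values: pd.DataFrame  # individual, trait, environment, gvalue
    sweep: SweepRegion | None
    incompatibility: IncompatibilityLocus | None

    def parent_genotypes(self, parent_id: str) -> np.ndarray:
        panel = self.maternal if parent_id.startswith("M") else self.paternal
        return panel.genotypes_of(parent_id)


@dataclass
class SimResult:
    config: SimConfig
    maternal: GenotypeMatrix
    paternal: GenotypeMatrix
    landrace: GenotypeMatrix
    hybrids: GenotypeMatrix
    phenotypes: pd.DataFrame  # hybrids + parents, long format
    truth: TruthSet

    @property
    def observed_trios(self) -> list[TrioRecord]:
        """Trios whose parents are both in the observed panel."""
        obs = set(self.truth.observed_parents)
        return [t for t in self.truth.trios if t.mother in obs and t.father in obs]


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def _make_sites(config: SimConfig, rng: np.random.Generator) -> list[VariantSite]:
    per = config.n_snps // config.n_chrom
    counts = [per] * config.n_chrom
    counts[-1] += config.n_snps - per * config.n_chrom
    sites: list[VariantSite] = []
    for c, m in enumerate(counts):
        pos = np.sort(rng.choice(np.arange(1, config.chrom_length), size=m,
                                 replace=False))
        for p in pos:
            sites.append(VariantSite(f"chr{c + 1}", int(p), "A", "G"))
    return sites


def _balding_nichols(q0: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Pool allele frequency around ancestral ``q0`` with divergence ``fst``."""
    if fst <= 0:
        return q0.copy()
    a = q0 * (1 - fst) / fst
    b = (1 - q0) * (1 - fst) / fst
    return rng.beta(np.maximum(a, 1e-3), np.maximum(b, 1e-3))


def _sample_inbreds(freq_alt: np.ndarray, n: int, prefix: str,
                    sites: Sequence[VariantSite],
                    rng: np.random.Generator) -> GenotypeMatrix:
    # one allele draw per inbred line, duplicated into a homozygous diploid
    alleles = rng.random((n, freq_alt.size)) < freq_alt
    codes = (alleles.astype(np.int8)) * 2
    ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(ids, list(sites), codes)


def simulate_founders(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, GenotypeMatrix, GenotypeMatrix]:
    """Draw the maternal, paternal and landrace inbred panels.

    Pool allele frequencies follow a Balding-Nichols divergence around a
    shared ancestral frequency, so the divergence parameter directly targets
    the realized Hudson Fst between the two modern pools.  Inside the sweep
    region the modern pools' frequencies are pushed toward fixation by the
    configured diversity-reduction factor, while landraces keep ancestral
    diversity.  Designated differentiated sites get a large maternal/paternal
    frequency gap; QTL sites get their configured superior-allele frequency
    in both pools.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites = _make_sites(config, rng)
    m = config.n_snps
    q0 = rng.uniform(0.05, 0.95, size=m)

    q_mat = _balding_nichols(q0, config.fst_target, rng)
    q_pat = _balding_nichols(q0, config.fst_target, rng)
    q_land = _balding_nichols(q0, config.landrace_fst, rng)

    # strongly differentiated maternal/paternal sites (Rf/Hd3a-like loci),
    # clustered so they form contiguous >0.3 Fst windows
    if config.n_diff_sites > 0:
        per = config.n_snps // config.n_chrom
        start = 6 * per + per // 3  # a block on chr7
        idx = np.arange(start, min(start + config.n_diff_sites, m))
        q_mat[idx] = rng.uniform(0.9, 0.98, idx.size)
        q_pat[idx] = rng.uniform(0.02, 0.1, idx.size)

    # QTL sites: superior (alt) allele at its configured frequency in both pools
    for q in config.qtls or []:
        q_mat[q.site_index] = q.superior_freq
        q_pat[q.site_index] = q.superior_freq
        q_land[q.site_index] = q.superior_freq

    # incompatibility locus: alleles segregate at intermediate frequency in
    # both pools (an S5-like sterility locus is polymorphic within the
    # breeding pools by nature), so hybrid heterozygotes are common there
    # and the post-selection heterozygote deficit is well defined
    if config.incompatibility is not None:
        inc = config.incompatibility
        chroms = np.array([s.chrom for s in sites])
        pos = np.array([s.pos for s in sites])
        near = (chroms == chroms[inc.site_index]) & (
            np.abs(pos - pos[inc.site_index]) <= inc.span
        )
        q_mat[near] = 0.5
        q_pat[near] = 0.5

    # sweep region: modern pools near fixation, landrace untouched
    if config.sweep is not None:
        sw = config.sweep
        chroms = np.array([s.chrom for s in sites])
        pos = np.array([s.pos for s in sites])
        in_sweep = (chroms == sw.chrom) & (pos - 1 >= sw.start) & (pos - 1 < sw.end)
        for qv in (q_mat, q_pat):
            low = qv[in_sweep] <= 0.5
            qv[in_sweep] = np.where(low, qv[in_sweep] / sw.reduction,
                                    1 - (1 - qv[in_sweep]) / sw.reduction)

    maternal = _sample_inbreds(q_mat, config.n_maternal, "M", sites, rng)
    paternal = _sample_inbreds(q_pat, config.n_paternal, "F", sites, rng)
    landrace = _sample_inbreds(q_land, config.n_landrace, "L", sites, rng)
    return maternal, paternal, landrace


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------

def _usage_weights(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    rng.shuffle(w)
    return w / w.sum()


def simulate_crosses(
    maternal: GenotypeMatrix,
    paternal: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, list[TrioRecord], "CrossTruth"]:
    """Cross the inbred pools into F1 hybrids.

    Parent usage follows a truncated power law (a few lines parent many
    hybrids).  The F1 code is the mean of the parental dosages; genotype
    error (adjacent-code flips) and missingness are applied afterwards.
    Returns the noisy hybrid matrix, the full trio registry, and the
    pre-noise hybrid codes plus the observed-parent subset.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if np.any(maternal.codes == 1) or np.any(paternal.codes == 1):
        raise ValueError("parental panels must be fully homozygous")
    w_m = _usage_weights(maternal.n_individuals, config.usage_exponent, rng)
    w_f = _usage_weights(paternal.n_individuals, config.usage_exponent, rng)
    mi = rng.choice(maternal.n_individuals, size=config.n_hybrids, p=w_m)
    fi = rng.choice(paternal.n_individuals, size=config.n_hybrids, p=w_f)

    clean = ((maternal.codes[mi] + paternal.codes[fi]) // 2).astype(np.int8)
    hybrid_ids = [f"H{i + 1:04d}" for i in range(config.n_hybrids)]
    trios = [
        TrioRecord(h, maternal.individuals[a], paternal.individuals[b])
        for h, a, b in zip(hybrid_ids, mi, fi)
    ]

    noisy = clean.copy()
    if config.error_rate > 0:
        flip = rng.random(noisy.shape) < config.error_rate
        up = rng.random(noisy.shape) < 0.5  # direction for het flips
        res = noisy.copy()
        res[flip & (noisy == 0)] = 1
        res[flip & (noisy == 2)] = 1
        res[flip & (noisy == 1) & up] = 2
        res[flip & (noisy == 1) & ~up] = 0
        noisy = res
    if config.missing_rate > 0:
        noisy[rng.random(noisy.shape) < config.missing_rate] = MISSING

    hybrids = GenotypeMatrix(hybrid_ids, maternal.sites, noisy)
    clean_gm = GenotypeMatrix(hybrid_ids, maternal.sites, clean)

    parents_used = sorted({t.mother for t in trios} | {t.father for t in trios})
    all_parents = maternal.individuals + paternal.individuals
    n_obs = int(round(config.observed_parent_fraction * len(all_parents)))
    observed = sorted(rng.choice(all_parents, size=n_obs, replace=False))
    return hybrids, trios, CrossTruth(clean_gm, observed, parents_used)


@dataclass
class CrossTruth:
    hybrids_clean: GenotypeMatrix
    observed_parents: list[str]
    parents_used: list[str]


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def genetic_values(
    matrix: GenotypeMatrix, qtls: Sequence[QTL], environment: str
) -> pd.DataFrame:
    """Summed QTL contributions per individual for one environment.

    Per QTL active in ``environment``, codes {0, 1, 2} contribute
    {-a, d, +a} (alt allele is the superior allele by construction).
    Missing genotypes contribute the QTL's population mean contribution 0.
    """
    g = np.zeros(matrix.n_individuals)
    for q in qtls:
        if environment not in q.environments:
            continue
        codes = matrix.codes[:, q.site_index]
        contrib = np.select(
            [codes == 0, codes == 1, codes == 2], [-q.a, q.d, q.a], default=0.0
        )
        g += contrib
    return pd.DataFrame({"individual": matrix.individuals, "gvalue": g})


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a two-environment phenotype table for the given individuals.

    Gaussian noise is scaled so the configured per-trait heritability holds
    on the realized genetic variance (noise variance 1 when a trait has no
    genetic variance in this panel).  Returns (phenotypes, genetic values),
    both long-format DataFrames.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    traits = sorted({q.trait for q in config.qtls or []})
    pheno_rows = []
    gv_rows = []
    for trait in traits:
        h2 = config.heritability.get(trait, 0.5)
        base = config.trait_baseline.get(trait, 100.0)
        qtls = [q for q in config.qtls or [] if q.trait == trait]
        for env in config.environments:
            gv = genetic_values(matrix, qtls, env)["gvalue"].to_numpy()
            var_g = float(np.var(gv))
            var_e = var_g * (1 - h2) / h2 if var_g > 0 else 1.0
            y = base + gv + rng.normal(0.0, np.sqrt(var_e), size=gv.size)
            for ind, gval, val in zip(matrix.individuals, gv, y):
                pheno_rows.append((ind, trait, env, float(val)))
                gv_rows.append((ind, trait, env, float(gval)))
    cols = ["individual", "trait", "environment", "value"]
    phen = pd.DataFrame(pheno_rows, columns=cols)
    gvdf = pd.DataFrame(gv_rows, columns=["individual", "trait", "environment", "gvalue"])
    return phen, gvdf


# ---------------------------------------------------------------------------
# Incompatibility locus
# ---------------------------------------------------------------------------

def apply_incompatibility(
    hybrids: GenotypeMatrix,
    site_index: int,
    penalty: float,
    rng: np.random.Generator | int | None = None,
    span: int = 0,
) -> GenotypeMatrix:
    """Select against heterozygotes at an incompatibility locus.

    Each heterozygote at the focal site (and, when ``span`` > 0, at linked
    sites within ``span`` bp) is, with probability ``penalty``, replaced by a
    surviving homozygote drawn from the local allele frequency — emulating
    S5-like hybrid-sterility selection that leaves a localized Ho - He
    deficit.  ``penalty`` 0 returns the matrix unchanged; 1 removes all
    heterozygotes at the locus.
    """
    if not 0 <= penalty <= 1:
        raise ValueError("penalty must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if penalty == 0:
        return hybrids
    codes = hybrids.codes.copy()
    chrom = hybrids.chroms[site_index]
    pos = hybrids.positions[site_index]
    target = np.flatnonzero(
        (hybrids.chroms == chrom) & (np.abs(hybrids.positions - pos) <= span)
    )
    for j in target:
        col = codes[:, j]
        het = np.flatnonzero(col == 1)
        if het.size == 0:
            continue
        hit = het[rng.random(het.size) < penalty]
        called = col[col != MISSING]
        n_alt = float((called == 1).sum() + 2 * (called == 2).sum())
        q = n_alt / (2 * called.size) if called.size else 0.5
        col[hit] = np.where(rng.random(hit.size) < q, 2, 0).astype(np.int8)
    return GenotypeMatrix(hybrids.individuals, hybrids.sites, codes)


# ---------------------------------------------------------------------------
# One-shot generation + serialization
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: founders -> crosses -> incompatibility ->
    phenotypes, all driven by ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(5)]
    maternal, paternal, landrace = simulate_founders(config, rngs[0])
    hybrids, trios, ct = simulate_crosses(maternal, paternal, config, rngs[1])
    if config.incompatibility is not None and config.incompatibility.penalty > 0:
        inc = config.incompatibility
        hybrids = apply_incompatibility(hybrids, inc.site_index, inc.penalty,
                                        rngs[2], span=inc.span)
    parents = GenotypeMatrix(
        maternal.individuals + paternal.individuals,
        maternal.sites,
        np.vstack([maternal.codes, paternal.codes]),
    )
    phen_h, gv_h = simulate_phenotypes(hybrids, config, rngs[3])
    phen_p, gv_p = simulate_phenotypes(parents, config, rngs[4])
    phenotypes = pd.concat([phen_h, phen_p], ignore_index=True)
    gvalues = pd.concat([gv_h, gv_p], ignore_index=True)
    truth = TruthSet(
        maternal=maternal,
        paternal=paternal,
        landrace=landrace,
        hybrids_clean=ct.hybrids_clean,
        trios=trios,
        observed_parents=ct.observed_parents,
        qtls=list(config.qtls or []),
        genetic_values=gvalues,
        sweep=config.sweep,
        incompatibility=config.incompatibility,
    )
    return SimResult(config, maternal, paternal, landrace, hybrids, phenotypes, truth)


def observed_panel(result: SimResult) -> GenotypeMatrix:
    """The subset of parents whose genotypes are 'sequenced' (observed)."""
    all_parents = GenotypeMatrix(
        result.maternal.individuals + result.paternal.individuals,
        result.maternal.sites,
        np.vstack([result.maternal.codes, result.paternal.codes]),
    )
    return all_parents.subset_individuals(result.truth.observed_parents)


def write_outputs(result: SimResult, outdir: str | Path) -> None:
    """Emit hybrids/maternal/paternal/landrace VCFs, phenotypes.tsv,
    trios.tsv (observed trios only) and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(result.hybrids, outdir / "hybrids.vcf")
    write_genotypes(result.maternal, outdir / "maternal.vcf")
    write_genotypes(result.paternal, outdir / "paternal.vcf")
    write_genotypes(result.landrace, outdir / "landrace.vcf")
    write_phenotypes(result.phenotypes, outdir / "phenotypes.tsv")
    write_trios(result.truth.trios, outdir / "trios.tsv")
    truth = {
        "observed_parents": result.truth.observed_parents,
        "qtls": [dataclasses.asdict(q) for q in result.truth.qtls],
        "sweep": dataclasses.asdict(result.truth.sweep)
        if result.truth.sweep
        else None,
        "incompatibility": dataclasses.asdict(result.truth.incompatibility)
        if result.truth.incompatibility
        else None,
        "seed": result.config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
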