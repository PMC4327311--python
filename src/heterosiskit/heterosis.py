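"""Dominance and superior-allele analysis at associated loci.

For an associated peak SNP with genotype-class phenotype means m_rr, m_ra,
m_aa, the additive effect is a = |m_aa - m_rr| / 2 (the high homozygote
orients the sign, so a >= 0) and the dominance deviation is
d = m_ra - (m_rr + m_aa) / 2.  The dominance degree d/a classifies the
locus: ~0 additive, ~1 complete dominance, |d/a| > 1 overdominance (the
heterozygote falls outside the parental homozygote range).  Classes whose
heterozygote or minor-homozygote count is <= 15 individuals are excluded as
too noisy.

The superior allele of a locus is the allele whose homozygote performs
better in the trait's beneficial direction (more grains, taller plants,
longer heading date by default; lower chalkiness, etc. when declared).
Per-hybrid tallies of heterozygous superior genotypes and of total superior
allele dosage across the top associated loci quantify how much of a
hybrid's performance comes from accumulating rare superior alleles rather
than from heterozygosity per se.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, TrioRecord
from .popscan import individual_heterozygosity

#: |d/a| bands for the point-estimate classification.
CLASS_BANDS = {"additive": 0.2, "partial": 0.8, "complete": 1.2}

COUNT_FILTER = 15  # minimum class count (strictly greater required)


@dataclass
class ClassMeans:
    """Raw phenotype means of the three genotype classes at one site."""

    m_rr: float
    m_ra: float
    m_aa: float
    n_rr: int
    n_ra: int
    n_aa: int


@dataclass
class DominanceRecord:
    """Additive/dominance decomposition at one locus."""

    m_rr: float
    m_ra: float
    m_aa: float
    n_rr: int
    n_ra: int
    n_aa: int
    a: float
    d: float
    degree: float  # d/a; nan when undefined
    classification: str
    excluded: bool
    boot_lower: float | None = None  # lower 95% bootstrap bound on d/a
    site_index: int | None = None
    trait: str | None = None
    environment: str | None = None


@dataclass
class TrioHeterosis:
    """Mid-parent and over-parent heterosis for one parent-child trio."""

    trio: TrioRecord
    trait: str
    environment: str
    p1: float
    p2: float
    f1: float
    mid_parent: float
    mph: float  # (F1 - MP) / MP; nan when MP == 0
    over_parent_class: str  # positive | negative | within-parental-range


# ---------------------------------------------------------------------------
# Class means and dominance degree
# ---------------------------------------------------------------------------

def genotype_class_means(
    y: np.ndarray, site_index: int, matrix: GenotypeMatrix
) -> ClassMeans:
    """Raw phenotype means per genotype class at one site.

    Empty classes are flagged with NaN means (never silently zero);
    individuals with NaN phenotype are ignored.
    """
    y = np.asarray(y, float)
    codes = matrix.codes[:, site_index]
    out = {}
    for code, name in ((0, "rr"), (1, "ra"), (2, "aa")):
        sel = (codes == code) & np.isfinite(y)
        out[f"n_{name}"] = int(sel.sum())
        out[f"m_{name}"] = float(y[sel].mean()) if sel.any() else float("nan")
    return ClassMeans(**out)


def dominance_degree(
    means: ClassMeans,
    count_filter: int = COUNT_FILTER,
    a_tolerance: float = 1e-9,
) -> DominanceRecord:
    """Compute a, d and d/a from genotype-class means and classify.

    The high homozygote orients the additive effect, so a >= 0 and the sign
    of d/a is the sign of d.  Loci whose heterozygote or minor-homozygote
    class count is <= ``count_filter`` are marked excluded; loci with a
    below ``a_tolerance`` get degree NaN and classification "undefined".
    """
    m_rr, m_ra, m_aa = means.m_rr, means.m_ra, means.m_aa
    n_minor_hom = min(means.n_rr, means.n_aa)
    excluded = min(means.n_ra, n_minor_hom) <= count_filter
    a = abs(m_aa - m_rr) / 2.0
    d = m_ra - (m_rr + m_aa) / 2.0
    if not np.isfinite(a) or not np.isfinite(d):
        degree, classification = float("nan"), "undefined"
    elif a < a_tolerance:
        degree, classification = float("nan"), "undefined"
    else:
        degree = d / a
        ad = abs(degree)
        if ad <= CLASS_BANDS["additive"]:
            classification = "additive"
        elif ad <= CLASS_BANDS["partial"]:
            classification = "partial"
        elif ad <= CLASS_BANDS["complete"]:
            classification = "complete"
        else:
            classification = (
                "overdominant-positive" if d > 0 else "overdominant-negative"
            )
    return DominanceRecord(
        m_rr=m_rr, m_ra=m_ra, m_aa=m_aa,
        n_rr=means.n_rr, n_ra=means.n_ra, n_aa=means.n_aa,
        a=a, d=d, degree=degree, classification=classification,
        excluded=excluded,
    )


def dominance_at_site(
    y: np.ndarray,
    site_index: int,
    matrix: GenotypeMatrix,
    count_filter: int = COUNT_FILTER,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> DominanceRecord:
    """Dominance record at one site with a bootstrap bound on d/a.

    Individuals are resampled with replacement ``n_boot`` times;
    ``boot_lower`` is the 2.5% quantile of the signed d/a distribution when
    d > 0 and the (sign-flipped) 2.5% quantile of -d/a when d < 0, so a
    confident overdominance call requires ``boot_lower > 1``.
    """
    rec = dominance_degree(
        genotype_class_means(y, site_index, matrix), count_filter=count_filter
    )
    rec.site_index = site_index
    if rec.excluded or not np.isfinite(rec.degree) or n_boot <= 0:
        return rec
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    y = np.asarray(y, float)
    codes = matrix.codes[:, site_index]
    usable = np.flatnonzero(np.isfinite(y) & (codes != MISSING))
    sign = 1.0 if rec.d > 0 else -1.0
    degrees = []
    for _ in range(n_boot):
        idx = rng.choice(usable, size=usable.size, replace=True)
        c, yy = codes[idx], y[idx]
        ms = []
        ok = True
        for code in (0, 1, 2):
            sel = c == code
            if not sel.any():
                ok = False
                break
            ms.append(yy[sel].mean())
        if not ok:
            continue
        a_b = abs(ms[2] - ms[0]) / 2.0
        if a_b < 1e-9:
            continue
        d_b = ms[1] - (ms[0] + ms[2]) / 2.0
        degrees.append(sign * d_b / a_b)
    if degrees:
        rec.boot_lower = float(np.quantile(degrees, 0.025))
    return rec


def count_overdominant(records: list[DominanceRecord]) -> tuple[int, int]:
    """Point-estimate overdominance census over dominance records.

    Counts non-excluded records classified overdominant-positive and
    overdominant-negative (|d/a| beyond the complete-dominance band).
    Returns (n_positive, n_negative).
    """
    pos = sum(r.classification == "overdominant-positive" and not r.excluded
              for r in records)
    neg = sum(r.classification == "overdominant-negative" and not r.excluded
              for r in records)
    return pos, neg


def is_confident_overdominant(rec: DominanceRecord) -> bool:
    """Overdominance call: |d/a| > 1 with bootstrap lower bound above 1."""
    return (
        not rec.excluded
        and np.isfinite(rec.degree)
        and abs(rec.degree) > 1.0
        and rec.boot_lower is not None
        and rec.boot_lower > 1.0
    )


# ---------------------------------------------------------------------------
# Superior alleles
# ---------------------------------------------------------------------------

def define_superior_allele(
    means: ClassMeans, higher_is_better: bool = True
) -> str | None:
    """The allele whose homozygote class performs better for the trait.

    Returns "ref", "alt", or None when a homozygote mean is missing or the
    two homozygote means tie exactly.
    """
    if not (np.isfinite(means.m_rr) and np.isfinite(means.m_aa)):
        return None
    if means.m_rr == means.m_aa:
        return None
    alt_better = means.m_aa > means.m_rr
    if not higher_is_better:
        alt_better = not alt_better
    return "alt" if alt_better else "ref"


def superior_profiles(
    matrix: GenotypeMatrix,
    loci: list[int],
    superior_alleles: list[str | None],
) -> pd.DataFrame:
    """Per-individual superior-allele tallies over the top associated loci.

    Loci with an undefined superior allele are skipped.  Missing genotypes
    contribute no dosage.  Returns a DataFrame with n_het_superior (count of
    loci heterozygous), n_superior_alleles (summed 0/1/2 superior dosage)
    and whole-genome heterozygosity.
    """
    if len(loci) != len(superior_alleles):
        raise ValueError("loci and superior_alleles must align")
    n = matrix.n_individuals
    n_het = np.zeros(n, dtype=int)
    dosage = np.zeros(n, dtype=int)
    n_used = 0
    for site, allele in zip(loci, superior_alleles):
        if allele is None:
            continue
        n_used += 1
        codes = matrix.codes[:, site]
        called = codes != MISSING
        n_het += ((codes == 1) & called).astype(int)
        dose = np.where(allele == "alt", codes, 2 - codes)
        dosage += np.where(called, dose, 0)
    return pd.DataFrame(
        {
            "individual": matrix.individuals,
            "n_het_superior": n_het,
            "n_superior_alleles": dosage,
            "heterozygosity": individual_heterozygosity(matrix).to_numpy(),
            "n_loci_used": n_used,
        }
    )


def correlate(profiles: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Correlate trait values with heterozygosity and superior-allele tallies.

    Pearson r is primary; Spearman rho is reported alongside as a
    robustness column.  Zero-variance predictors yield NaN with a flag.
    """
    y = np.asarray(y, float)
    if y.size != len(profiles):
        raise ValueError("phenotype vector does not match profiles")
    if np.isfinite(y).sum() < 10:
        raise ValueError("need >= 10 phenotyped individuals")
    rows = []
    for col in ("heterozygosity", "n_het_superior", "n_superior_alleles"):
        x = profiles[col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if np.std(x[ok]) == 0:
            rows.append((col, np.nan, np.nan, np.nan, np.nan, True))
            continue
        pr, pp = stats.pearsonr(x[ok], y[ok])
        sr, sp = stats.spearmanr(x[ok], y[ok])
        rows.append((col, pr, pp, sr, sp, False))
    return pd.DataFrame(
        rows,
        columns=["predictor", "pearson_r", "pearson_p", "spearman_rho",
                 "spearman_p", "zero_variance"],
    )


# ---------------------------------------------------------------------------
# Trio heterosis
# ---------------------------------------------------------------------------

def trio_heterosis(
    trios: list[TrioRecord],
    phenotypes: pd.DataFrame,
    trait: str,
    environment: str,
) -> tuple[list[TrioHeterosis], dict[str, float]]:
    """Mid-parent heterosis index and over-parent class per trio.

    MPH = (F1 - MP) / MP with MP the parental mean; when MP == 0 the index
    is NaN but the over-parent class (F1 above both parents, below both, or
    within the parental range) is still assigned.  Returns the per-trio
    records and the population proportions of the three classes.
    """
    sub = phenotypes[
        (phenotypes["trait"] == trait) & (phenotypes["environment"] == environment)
    ]
    values = dict(zip(sub["individual"], sub["value"]))
    records = []
    for t in trios:
        if not all(i in values for i in (t.hybrid, t.mother, t.father)):
            continue
        p1, p2, f1 = values[t.mother], values[t.father], values[t.hybrid]
        mp = (p1 + p2) / 2.0
        mph = (f1 - mp) / mp if mp != 0 else float("nan")
        if f1 > max(p1, p2):
            cls = "positive"
        elif f1 < min(p1, p2):
            cls = "negative"
        else:
            cls = "within-parental-range"
        records.append(
            TrioHeterosis(t, trait, environment, p1, p2, f1, mp, mph, cls)
        )
    n = len(records)
    props = {
        c: sum(r.over_parent_class == c for r in records) / n if n else float("nan")
        for c in ("positive", "negative", "within-parental-range")
    }
    return records, props


# ---------------------------------------------------------------------------
# Rare-allele enrichment & combination census
# ---------------------------------------------------------------------------

def rare_allele_enrichment_ratio(q: float) -> float:
    """Heterozygote-carrier vs homozygote-carrier enrichment, 2(1-q)q / q.

    Under Hardy-Weinberg proportions a superior allele at frequency q is
    carried heterozygously by 2(1-q)q of random-cross F1s but homozygously
    by only q of inbred lines; the ratio 2(1-q) approaches 2 for rare
    alleles — hybrid breeding deploys a rare superior allele roughly twice
    as often as inbred breeding can.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    return 2.0 * (1.0 - q)


def combination_census(
    matrix: GenotypeMatrix, loci: list[int]
) -> tuple[pd.DataFrame, int, int]:
    """Tabulate multi-locus genotype classes over >= 2 census loci.

    Returns (census table sorted by count with a ``share`` column, number of
    possible classes 3**k, count of individuals excluded for a missing
    genotype at any census locus).
    """
    if len(loci) < 2:
        raise ValueError("census needs at least two loci")
    codes = matrix.codes[:, loci]
    complete = (codes != MISSING).all(axis=1)
    n_excluded = int((~complete).sum())
    counts: dict[tuple[int, ...], int] = {}
    for row in codes[complete]:
        key = tuple(int(c) for c in row)
        counts[key] = counts.get(key, 0) + 1
    n_obs = int(complete.sum())
    table = pd.DataFrame(
        [("/".join(_CLASS_NAMES[c] for c in k), k, v) for k, v in counts.items()],
        columns=["label", "classes", "count"],
    ).sort_values(["count", "label"], ascending=[False, True]).reset_index(drop=True)
    table["share"] = table["count"] / n_obs if n_obs else np.nan
    return table, 3 ** len(loci), n_excluded


_CLASS_NAMES = {0: "rr", 1: "ra", 2: "aa"}


def top2_share(census: pd.DataFrame) -> float:
    """Combined share of the two most common multi-locus classes."""
    return float(census["share"].head(2).sum()) if len(census) else float("nan")
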