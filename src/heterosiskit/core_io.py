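"""Domain types and genotype/phenotype I/O shared by every pipeline stage.

Genotypes are held as an ``individuals x sites`` matrix of diploid codes

=======  ==========================================
code     meaning
=======  ==========================================
``0``    homozygous reference ("rr")
``1``    heterozygous ("ra")
``2``    homozygous alternative ("aa")
``-1``   missing / uncalled (``MISSING``)
=======  ==========================================

Only biallelic SNPs are represented.  External coordinates are VCF-style
1-based positions; windowed statistics elsewhere in the package use 0-based
half-open intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype.
MISSING: int = -1

VALID_CODES = frozenset({0, 1, 2, MISSING})


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


class EmptyMatrixError(ValueError):
    """Raised when no biallelic SNP records survive parsing."""


class UndefinedKinshipError(ValueError):
    """Raised when two individuals share no pairwise-called site."""


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic SNP site (1-based position)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class TrioRecord:
    """An F1 hybrid together with its female (mother) and male (father) parent."""

    hybrid: str
    mother: str
    father: str

    def __post_init__(self) -> None:
        if len({self.hybrid, self.mother, self.father}) != 3:
            raise ValueError("hybrid, mother and father IDs must be distinct")


class GenotypeMatrix:
    """Diploid genotype codes for a panel of individuals at biallelic SNPs.

    Parameters
    ----------
    individuals
        Ordered unique individual identifiers.
    sites
        Ordered :class:`VariantSite` records, sorted by (chrom, pos) with the
        chromosome order given by first appearance.
    codes
        ``(n_individuals, n_sites)`` integer array over {0, 1, 2, MISSING}.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        sites: Sequence[VariantSite],
        codes: np.ndarray,
    ) -> None:
        individuals = list(individuals)
        if len(set(individuals)) != len(individuals):
            raise ValueError("individual IDs must be unique")
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(individuals), len(sites)):
            raise ValueError(
                f"codes shape {codes.shape} inconsistent with "
                f"{len(individuals)} individuals x {len(sites)} sites"
            )
        bad = set(np.unique(codes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        self.individuals = individuals
        self._sites = list(sites)
        self.codes = codes
        self.chroms = np.array([s.chrom for s in sites], dtype=object)
        self.positions = np.array([s.pos for s in sites], dtype=np.int64)
        self._check_sorted()

    def _check_sorted(self) -> None:
        order: dict[str, int] = {}
        for c in self.chroms:
            if c not in order:
                order[c] = len(order)
        prev = (-1, -1)
        for c, p in zip(self.chroms, self.positions):
            key = (order[c], int(p))
            if key < prev:
                raise ValueError("sites must be sorted by (chrom, pos)")
            prev = key

    # -- basic introspection ------------------------------------------------
    @property
    def sites(self) -> list[VariantSite]:
        return self._sites

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self._sites)

    def individual_index(self, individual: str) -> int:
        return self.individuals.index(individual)

    def genotypes_of(self, individual: str) -> np.ndarray:
        return self.codes[self.individual_index(individual)]

    # -- subsetting ---------------------------------------------------------
    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.individuals,
            [self._sites[i] for i in index],
            self.codes[:, index],
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_index(i) for i in ids]
        return GenotypeMatrix(list(ids), self._sites, self.codes[idx])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x "
            f"{self.n_sites} sites)"
        )


@dataclass
class KinshipMatrix:
    """Pairwise simple-matching coefficients among individuals.

    ``values[i, j]`` is the fraction of pairwise-called sites where the two
    diploid codes are identical; the corresponding genetic distance is
    ``1 - values[i, j]``.
    """

    individuals: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if v.shape != (n, n):
            raise ValueError("kinship matrix shape inconsistent with IDs")
        self.values = v

    def distance(self) -> np.ndarray:
        """Simple-matching distance matrix (1 - coefficient)."""
        return 1.0 - self.values


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP variants are skipped (a summary count is
    logged).  Raises :class:`EmptyMatrixError` if no biallelic SNPs remain.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    try:
        for rec in vcf:
            if (not rec.is_snp) or len(rec.ALT) != 1:
                n_skipped += 1
                continue
            sites.append(
                VariantSite(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
            )
            if samples:
                g = rec.gt_types.astype(np.int8)
                g[g == 3] = MISSING  # gts012: 3 == unknown
                rows.append(g)
    except Exception as exc:
        raise VCFParseError(f"malformed VCF record in {path}: {exc}") from exc
    finally:
        vcf.close()

    if n_skipped:
        logger.info("read_genotypes: skipped %d non-biallelic-SNP records", n_skipped)
    if not sites:
        raise EmptyMatrixError(f"no biallelic SNP records in {path}")
    if samples:
        codes = np.column_stack(rows) if rows else np.empty((len(samples), 0), np.int8)
    else:
        codes = np.empty((0, len(sites)), dtype=np.int8)
    return GenotypeMatrix(samples, sites, codes)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as an unphased VCF v4.2 text file."""
    path = Path(path)
    # contig lengths: round the max observed position up generously
    contig_max: dict[str, int] = {}
    for c, p in zip(matrix.chroms, matrix.positions):
        contig_max[c] = max(contig_max.get(c, 0), int(p))
    lines = ["##fileformat=VCFv4.2", "##source=heterosiskit"]
    for c, mx in contig_max.items():
        lines.append(f"##contig=<ID={c},length={mx + 1}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if matrix.individuals:
        header += ["FORMAT"] + matrix.individuals
    lines.append("\t".join(header))
    for j, site in enumerate(matrix.sites):
        row = [
            site.chrom,
            str(site.pos),
            ".",
            site.ref_allele,
            site.alt_allele,
            ".",
            "PASS",
            ".",
        ]
        if matrix.individuals:
            row.append("GT")
            row.extend(_GT_STRINGS[int(c)] for c in matrix.codes[:, j])
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Phenotype / trio tables
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["individual", "trait", "environment", "value"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV with columns individual/trait/environment/value."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["individual", "trait", "environment"])
    if dup.any():
        raise ValueError("duplicate (individual, trait, environment) records")
    return df


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trios(path: str | Path) -> list[TrioRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"hybrid", "mother", "father"}
    if not needed.issubset(df.columns):
        raise ValueError("trio table needs columns hybrid, mother, father")
    return [
        TrioRecord(r.hybrid, r.mother, r.father) for r in df.itertuples(index=False)
    ]


def write_trios(trios: Iterable[TrioRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(t.hybrid, t.mother, t.father) for t in trios],
        columns=["hybrid", "mother", "father"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-site allele statistics
# ---------------------------------------------------------------------------

def site_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site allele frequencies and heterozygosity.

    Returns a DataFrame indexed like the site list with columns

    - ``p_ref`` / ``q_alt``: reference / alternative allele frequency among
      called alleles,
    - ``maf``: minor allele frequency,
    - ``ho``: observed heterozygote frequency n_ra / n_called,
    - ``he``: Hardy-Weinberg expected heterozygosity 2 p q,
    - ``n_called``: number of non-missing genotypes.

    Sites with no called genotype carry NaN statistics (never silently zero).
    """
    codes = matrix.codes
    n_rr = (codes == 0).sum(axis=0).astype(float)
    n_ra = (codes == 1).sum(axis=0).astype(float)
    n_aa = (codes == 2).sum(axis=0).astype(float)
    n_called = n_rr + n_ra + n_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, (2 * n_rr + n_ra) / (2 * n_called), np.nan)
        ho = np.where(n_called > 0, n_ra / n_called, np.nan)
    q = 1.0 - p
    he = 2.0 * p * q
    maf = np.minimum(p, q)
    return pd.DataFrame(
        {
            "chrom": matrix.chroms,
            "pos": matrix.positions,
            "p_ref": p,
            "q_alt": q,
            "maf": maf,
            "ho": ho,
            "he": he,
            "n_called": n_called.astype(int),
        }
    )


def maf_filter(matrix: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Retain sites with minor allele frequency strictly above ``min_maf``.

    Sites with no called genotype (undefined MAF) are dropped.
    """
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must lie in [0, 0.5)")
    maf = site_stats(matrix)["maf"].to_numpy()
    keep = maf > min_maf  # NaN compares False -> dropped
    return matrix.subset_sites(keep)


# ---------------------------------------------------------------------------
# Simple-matching kinship
# ---------------------------------------------------------------------------

def matching_kinship(a: np.ndarray, b: np.ndarray) -> float:
    """Simple-matching coefficient between two diploid code vectors.

    The fraction of pairwise-called sites where the codes {0,1,2} are
    identical.  Raises :class:`UndefinedKinshipError` when no site is called
    in both individuals.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        raise UndefinedKinshipError("no pairwise-called sites")
    return float((a[both] == b[both]).sum() / n)


def kinship_matrix(matrix: GenotypeMatrix) -> KinshipMatrix:
    """Pairwise simple-matching kinship over all individuals.

    Diagonal entries are 1 by definition (self-match over called sites).
    """
    if matrix.n_individuals < 2:
        raise ValueError("kinship needs >= 2 individuals")
    K = cross_matching(matrix.codes, matrix.codes)
    if np.isnan(K).any():
        raise UndefinedKinshipError("some pair shares no called site")
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(list(matrix.individuals), K)


def cross_matching(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Matrix of simple-matching coefficients between two code matrices.

    ``codes_a`` is (n_a, m) and ``codes_b`` (n_b, m); the result is
    (n_a, n_b).  Pairs with no shared called site yield NaN.
    """
    codes_a = np.asarray(codes_a)
    codes_b = np.asarray(codes_b)
    matches = np.zeros((codes_a.shape[0], codes_b.shape[0]))
    for c in (0, 1, 2):
        ia = (codes_a == c).astype(np.float64)
        ib = (codes_b == c).astype(np.float64)
        matches += ia @ ib.T
    called = (codes_a != MISSING).astype(np.float64) @ (codes_b != MISSING).T.astype(
        np.float64
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(called > 0, matches / called, np.nan)
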