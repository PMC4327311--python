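"""Meiosis and cross-design simulation for superior-allele pyramiding.

Crossovers follow the Haldane model: per chromosome of genetic length L cM
the crossover count is Poisson(L/100) with positions uniform along the
chromosome and no interference, so the recombination fraction between two
markers d cM apart is the Haldane map function (1 - exp(-2d/100)) / 2.

Two neutral breeding designs are provided: recombinant inbred lines (an F1
selfed by single-seed descent to near-fixation, default F8) and repeated
backcrosses to a recurrent parent followed by selfing (e.g. BC5F3).  The
pyramiding summary then asks how many lines fix the superior allele at all
tracked loci at once — for k unlinked loci a RIL fixes all of them with
probability (1/2)^k, which is the quantitative core of why stacking many
rare superior alleles into one inbred line needs very large populations or
many cross-selection cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, VariantSite

#: synthetic bp-per-cM scale used when emitting populations as VCF
BP_PER_CM = 25_000


@dataclass
class GeneticMap:
    """Marker positions in centimorgans on named chromosomes."""

    lengths: dict[str, float]  # chrom -> length in cM
    markers: pd.DataFrame  # columns: chrom, cm (non-decreasing per chrom)

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        for chrom, length in self.lengths.items():
            if length < 0:
                raise ValueError(f"negative length for {chrom}")
        for chrom, grp in self.markers.groupby("chrom"):
            cm = grp["cm"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"marker positions decrease on {chrom}")
            if chrom not in self.lengths:
                raise ValueError(f"marker chromosome {chrom} not in map")
            if cm.size and cm.max() > self.lengths[chrom]:
                raise ValueError(f"marker beyond chromosome end on {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @classmethod
    def rice_like(cls, markers_per_chrom: int = 3, n_chrom: int = 12,
                  length_cm: float = 150.0) -> "GeneticMap":
        """A 12-chromosome rice-like map with evenly spaced markers."""
        lengths = {f"chr{i + 1}": length_cm for i in range(n_chrom)}
        rows = []
        for i in range(n_chrom):
            for cm in np.linspace(0, length_cm, markers_per_chrom + 2)[1:-1]:
                rows.append((f"chr{i + 1}", float(cm)))
        return cls(lengths, pd.DataFrame(rows, columns=["chrom", "cm"]))


@dataclass
class CrossDesign:
    """A neutral breeding scheme.

    ``scheme`` is "RIL" (F1 then ``n_self`` selfing meioses by single-seed
    descent; default 7, i.e. to F8) or "BC" (``n_backcross`` backcrosses to
    the recurrent parent, then ``n_self`` selfings; BC5F3 means
    n_backcross=5, n_self=2).  Parent genotypes are homozygous code vectors
    over the map's markers.
    """

    scheme: str  # "RIL" | "BC"
    n_lines: int
    parent_a: np.ndarray  # recurrent parent for BC
    parent_b: np.ndarray  # donor parent for BC
    n_backcross: int = 0
    n_self: int = 7

    def __post_init__(self) -> None:
        if self.scheme not in ("RIL", "BC"):
            raise ValueError("scheme must be RIL or BC")
        if self.n_lines < 1:
            raise ValueError("population size must be >= 1")
        if self.scheme == "BC" and self.n_backcross < 1:
            raise ValueError("BC scheme needs n_backcross >= 1")
        for p in (self.parent_a, self.parent_b):
            if np.any((np.asarray(p) != 0) & (np.asarray(p) != 2)):
                raise ValueError("parents must be fully homozygous (codes 0/2)")

    @classmethod
    def ril(cls, n_lines: int, parent_a: np.ndarray, parent_b: np.ndarray,
            n_self: int = 7) -> "CrossDesign":
        return cls("RIL", n_lines, np.asarray(parent_a), np.asarray(parent_b),
                   n_self=n_self)

    @classmethod
    def bc(cls, n_lines: int, recurrent: np.ndarray, donor: np.ndarray,
           n_backcross: int = 5, n_self: int = 2) -> "CrossDesign":
        return cls("BC", n_lines, np.asarray(recurrent), np.asarray(donor),
                   n_backcross=n_backcross, n_self=n_self)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _chrom_blocks(gmap: GeneticMap) -> list[tuple[str, float, np.ndarray, np.ndarray]]:
    """Per-chromosome (name, length, marker cM, marker index) blocks."""
    blocks = []
    idx = np.arange(gmap.n_markers)
    for chrom, grp in gmap.markers.groupby("chrom", sort=False):
        blocks.append(
            (chrom, gmap.lengths[chrom], grp["cm"].to_numpy(),
             idx[grp.index.to_numpy()])
        )
    return blocks


def simulate_gamete(
    hap0: np.ndarray,
    hap1: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a haplotype pair under Haldane meiosis.

    Crossover counts are Poisson(length/100) per chromosome with uniform
    positions; the gamete alternates between the two parental haplotypes at
    each crossover, starting from a random one.
    """
    hap0 = np.asarray(hap0)
    hap1 = np.asarray(hap1)
    if hap0.shape != hap1.shape or hap0.size != gmap.n_markers:
        raise ValueError("haplotypes must match the map's marker count")
    gamete = np.empty_like(hap0)
    for chrom, length, cm, idx in _chrom_blocks(gmap):
        n_x = rng.poisson(length / 100.0) if length > 0 else 0
        start = rng.integers(2)
        if n_x == 0:
            phase = np.full(cm.size, start)
        else:
            xpos = np.sort(rng.uniform(0.0, length, size=n_x))
            phase = (start + np.searchsorted(xpos, cm, side="right")) % 2
        gamete[idx] = np.where(phase == 0, hap0[idx], hap1[idx])
    return gamete


def _meiosis_batch(
    hap0: np.ndarray, hap1: np.ndarray, gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per row of a (n_lines, n_markers) haplotype-pair batch.

    Uses the Markov property of the Poisson (Haldane) crossover process:
    observed at the marker grid, phase switches between adjacent markers are
    independent Bernoulli draws with the Haldane recombination fraction —
    the exact marginal of the uniform-position crossover model.
    """
    n = hap0.shape[0]
    gam = np.empty_like(hap0)
    for _, _, cm, idx in _chrom_blocks(gmap):
        k = cm.size
        phase = np.empty((n, k), dtype=np.int8)
        phase[:, 0] = rng.integers(2, size=n)
        if k > 1:
            r = haldane_recombination_fraction(np.diff(cm))
            switches = rng.random((n, k - 1)) < r
            phase[:, 1:] = np.cumsum(switches, axis=1) % 2
            phase[:, 1:] = (phase[:, [0]] + phase[:, 1:]) % 2
        gam[:, idx] = np.where(phase == 0, hap0[:, idx], hap1[:, idx])
    return gam


def make_population(
    design: CrossDesign,
    gmap: GeneticMap,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Simulate a RIL or backcross population over the map's markers.

    Returns a GenotypeMatrix on a synthetic bp grid (1 cM = 25 kb).  RILs
    are built by single-seed descent, so residual heterozygosity
    (~(1/2)^n_self per locus) remains visible rather than being idealized
    away.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hap_a = (np.asarray(design.parent_a) // 2).astype(np.int8)
    hap_b = (np.asarray(design.parent_b) // 2).astype(np.int8)
    n, m = design.n_lines, gmap.n_markers
    h0 = np.tile(hap_a, (n, 1))  # F1 haplotype pair, all lines
    h1 = np.tile(hap_b, (n, 1))
    if design.scheme == "BC":
        for _ in range(design.n_backcross):
            h0, h1 = _meiosis_batch(h0, h1, gmap, rng), np.tile(hap_a, (n, 1))
    for _ in range(design.n_self):
        g1 = _meiosis_batch(h0, h1, gmap, rng)
        g2 = _meiosis_batch(h0, h1, gmap, rng)
        h0, h1 = g1, g2
    lines = (h0 + h1).astype(np.int8)
    sites = [
        VariantSite(chrom, int(round(cm * BP_PER_CM)) + 1, "A", "G")
        for chrom, cm in zip(gmap.markers["chrom"], gmap.markers["cm"])
    ]
    ids = [f"{design.scheme}{i + 1:05d}" for i in range(design.n_lines)]
    return GenotypeMatrix(ids, sites, lines)


# ---------------------------------------------------------------------------
# Pyramiding summary
# ---------------------------------------------------------------------------

@dataclass
class PyramidingSummary:
    counts: pd.DataFrame  # per-line dosage tallies
    fraction_fixed_all: float
    n_fixed_all: int
    n_loci: int
    expected_unlinked: float | None  # analytic expectation, RIL only


def pyramiding_summary(
    population: GenotypeMatrix,
    tracked_loci: list[int],
    superior_allele: str = "alt",
) -> PyramidingSummary:
    """Superior-allele tallies and the fraction of lines fixed at all loci.

    ``superior_allele`` "alt" counts code dosage directly, "ref" counts
    2 - code.  The unlinked-RIL expectation (1/2)^k is annotated for
    reference (None-ed out for BC designs, where it depends on the scheme).
    """
    codes = population.codes[:, tracked_loci]
    dose = codes if superior_allele == "alt" else 2 - codes
    n_fixed = (dose == 2).sum(axis=1)
    total = dose.sum(axis=1)
    fixed_all = n_fixed == len(tracked_loci)
    counts = pd.DataFrame(
        {
            "line": population.individuals,
            "n_superior_alleles": total,
            "n_loci_fixed": n_fixed,
            "fixed_all": fixed_all,
        }
    )
    is_ril = population.individuals[0].startswith("RIL") if population.individuals else False
    return PyramidingSummary(
        counts=counts,
        fraction_fixed_all=float(fixed_all.mean()),
        n_fixed_all=int(fixed_all.sum()),
        n_loci=len(tracked_loci),
        expected_unlinked=0.5 ** len(tracked_loci) if is_ril else None,
    )


def haldane_recombination_fraction(d_cm: float) -> float:
    """Haldane map function r = (1 - exp(-2 d / 100)) / 2 for distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
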