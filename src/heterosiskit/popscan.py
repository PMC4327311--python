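"""Population-genetic scans: heterozygosity, HWE deviation, windowed pi,
pi-ratio sweep detection, and windowed Hudson Fst.

Window coordinates are 0-based half-open in bp on a fixed grid (default
100 kb), so a 1-based SNP position ``pos`` falls in the window containing
``pos - 1``.  Window tables carry an ``excluded`` flag plus ``reason`` rather
than silently dropping windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, site_stats

WINDOW_COLUMNS = ["chrom", "start", "end", "stat", "value", "n_sites",
                  "excluded", "reason"]


@dataclass(frozen=True)
class HetOutlierLocus:
    """A run of SNPs beyond a heterozygosity-deviation threshold."""

    chrom: str
    start: int  # bp, 0-based half-open over member SNPs
    end: int
    direction: str  # "excess" | "deficit"
    positions: tuple[int, ...]  # member SNP positions (1-based)
    peak_deviation: float


# ---------------------------------------------------------------------------
# Per-individual / per-site heterozygosity
# ---------------------------------------------------------------------------

def individual_heterozygosity(matrix: GenotypeMatrix) -> pd.Series:
    """Fraction of called sites that are heterozygous, per individual.

    Individuals with no called site get NaN.
    """
    called = (matrix.codes != MISSING).sum(axis=1).astype(float)
    het = (matrix.codes == 1).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(called > 0, het / called, np.nan)
    return pd.Series(frac, index=matrix.individuals, name="heterozygosity")


def het_deviation(stats: pd.DataFrame) -> pd.Series:
    """Ho - He per site from a :func:`heterosiskit.core_io.site_stats` table.

    Positive values mean heterozygote excess over the Hardy-Weinberg
    expectation, negative values a deficit; NaN propagates from sites with no
    called genotype.
    """
    return (stats["ho"] - stats["he"]).rename("ho_minus_he")


def flag_het_outliers(
    stats: pd.DataFrame,
    hi: float = 0.4,
    lo: float = -0.4,
    merge_distance: int = 100_000,
) -> list[HetOutlierLocus]:
    """Group SNPs beyond the Ho - He thresholds into outlier loci.

    SNPs with deviation > ``hi`` (excess) or < ``lo`` (deficit) are clustered
    per chromosome and direction by single linkage within
    ``merge_distance`` bp.
    """
    if not hi > lo:
        raise ValueError("hi threshold must exceed lo")
    dev = het_deviation(stats)
    loci: list[HetOutlierLocus] = []
    for direction, mask in (
        ("excess", dev > hi),
        ("deficit", dev < lo),
    ):
        sel = stats.loc[mask.fillna(False)]
        for chrom, grp in sel.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy()
            d = dev.loc[grp.index].to_numpy()
            brk = np.flatnonzero(np.diff(pos) > merge_distance)
            for seg in np.split(np.arange(pos.size), brk + 1):
                peak = d[seg][np.argmax(np.abs(d[seg]))]
                loci.append(
                    HetOutlierLocus(
                        chrom=str(chrom),
                        start=int(pos[seg[0]]) - 1,
                        end=int(pos[seg[-1]]),
                        direction=direction,
                        positions=tuple(int(p) for p in pos[seg]),
                        peak_deviation=float(peak),
                    )
                )
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def _window_frame(matrix: GenotypeMatrix, window: int) -> pd.DataFrame:
    """Site table with the enclosing window of each SNP."""
    if window <= 0:
        raise ValueError("window must be positive")
    return pd.DataFrame(
        {
            "chrom": matrix.chroms,
            "pos": matrix.positions,
            "start": ((matrix.positions - 1) // window) * window,
        }
    )


def windowed_pi(
    matrix: GenotypeMatrix, window: int = 100_000, inbred: bool = False
) -> pd.DataFrame:
    """Nucleotide diversity per window, in per-bp units.

    Per site, the unbiased heterozygosity ``2 p q * n / (n - 1)`` (with n the
    number of called alleles) is summed over the window's SNPs and divided by
    the window span.  For fully inbred panels pass ``inbred=True`` so each
    individual counts as a single allele draw (its two copies are identical
    by descent).  Windows with no genotyped SNP are flagged excluded.
    """
    stats = site_stats(matrix)
    wf = _window_frame(matrix, window)
    n_alleles = stats["n_called"].to_numpy(dtype=float)
    if not inbred:
        n_alleles = 2 * n_alleles
    p = stats["p_ref"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = 2 * p * (1 - p) * np.where(n_alleles > 1,
                                              n_alleles / (n_alleles - 1), np.nan)
    wf["contrib"] = per_site
    wf["has_data"] = n_alleles > 1
    rows = []
    for (chrom, start), grp in wf.groupby(["chrom", "start"], sort=False):
        usable = grp.loc[grp["has_data"]]
        n_sites = len(usable)
        if n_sites == 0:
            rows.append((chrom, start, start + window, "pi", np.nan, 0, True,
                         "no_genotyped_sites"))
        else:
            val = float(usable["contrib"].sum()) / window
            rows.append((chrom, start, start + window, "pi", val, n_sites,
                         False, ""))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def sweep_scan(
    pi_landrace: pd.DataFrame,
    pi_modern: pd.DataFrame,
    top_fraction: float = 0.005,
    diversity_floor: float | None = None,
    min_sites: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Landrace/modern pi-ratio scan for genetic-improvement sweeps.

    Windows are excluded (with a recorded reason) when either input window is
    excluded, has fewer than ``min_sites`` genotyped SNPs (too much missing
    data), or when *both* populations fall below ``diversity_floor`` (a
    ratio between two near-zero diversities is meaningless).  The default
    floor is 10% of the median landrace pi.  The top ``top_fraction`` of
    usable ratios are flagged and contiguous flagged windows merged into
    sweep loci.

    Returns (window table with ``pi_ratio`` values, sweep locus table).
    """
    key = ["chrom", "start", "end"]
    if not pi_landrace[key].reset_index(drop=True).equals(
        pi_modern[key].reset_index(drop=True)
    ):
        raise ValueError("window grids of the two populations do not match")
    land = pi_landrace.reset_index(drop=True)
    mod = pi_modern.reset_index(drop=True)
    if diversity_floor is None:
        med = float(land.loc[~land["excluded"], "value"].median())
        diversity_floor = 0.1 * med

    out = land[key].copy()
    out["stat"] = "pi_ratio"
    ratio = np.full(len(out), np.nan)
    excluded = np.zeros(len(out), dtype=bool)
    reason = np.array([""] * len(out), dtype=object)

    for i in range(len(out)):
        if land.loc[i, "excluded"] or mod.loc[i, "excluded"]:
            excluded[i], reason[i] = True, "no_genotyped_sites"
            continue
        if min(land.loc[i, "n_sites"], mod.loc[i, "n_sites"]) < min_sites:
            excluded[i], reason[i] = True, "too_few_sites"
            continue
        pl, pm = float(land.loc[i, "value"]), float(mod.loc[i, "value"])
        if pl < diversity_floor and pm < diversity_floor:
            excluded[i], reason[i] = True, "low_diversity_both"
            continue
        ratio[i] = np.inf if pm == 0 else pl / pm
    out["value"] = ratio
    out["n_sites"] = np.minimum(land["n_sites"], mod["n_sites"])
    out["excluded"] = excluded
    out["reason"] = reason

    usable = out.loc[~out["excluded"]].copy()
    n_top = max(1, int(np.ceil(top_fraction * len(usable)))) if len(usable) else 0
    top = usable.nlargest(n_top, "value") if n_top else usable.iloc[:0]
    loci = _merge_windows(out, out.index.isin(top.index), "max_pi_ratio")
    return out[WINDOW_COLUMNS], loci


def windowed_fst(
    pop_a: GenotypeMatrix,
    pop_b: GenotypeMatrix,
    window: int = 100_000,
    threshold: float = 0.3,
    inbred_a: bool = False,
    inbred_b: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hudson Fst per window between two populations on the same site grid.

    Per site the Hudson estimator numerator
    ``(p1 - p2)^2 - p1 q1/(n1 - 1) - p2 q2/(n2 - 1)`` and denominator
    ``p1 q2 + p2 q1`` are computed (n = called allele count, halved for
    declared inbred pools), then combined per window as a ratio of averages
    and clamped to [0, 1].  Windows above ``threshold`` are merged into
    differentiated loci.

    Returns (window table, differentiated locus table).
    """
    if [(s.chrom, s.pos) for s in pop_a.sites] != [
        (s.chrom, s.pos) for s in pop_b.sites
    ]:
        raise ValueError("populations must share an identical site grid")
    sa, sb = site_stats(pop_a), site_stats(pop_b)
    n1 = sa["n_called"].to_numpy(float) * (1 if inbred_a else 2)
    n2 = sb["n_called"].to_numpy(float) * (1 if inbred_b else 2)
    p1, p2 = sa["p_ref"].to_numpy(), sb["p_ref"].to_numpy()
    q1, q2 = 1 - p1, 1 - p2
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * q1 / (n1 - 1) - p2 * q2 / (n2 - 1)
    den = p1 * q2 + p2 * q1
    usable = (n1 > 1) & (n2 > 1) & np.isfinite(num)

    wf = _window_frame(pop_a, window)
    wf["num"] = np.where(usable, num, 0.0)
    wf["den"] = np.where(usable, den, 0.0)
    wf["use"] = usable
    rows = []
    for (chrom, start), grp in wf.groupby(["chrom", "start"], sort=False):
        n_sites = int(grp["use"].sum())
        dsum = float(grp["den"].sum())
        if n_sites == 0 or dsum == 0:
            rows.append((chrom, start, start + window, "fst", np.nan, n_sites,
                         True, "no_polymorphic_sites"))
            continue
        fst = float(np.clip(grp["num"].sum() / dsum, 0.0, 1.0))
        rows.append((chrom, start, start + window, "fst", fst, n_sites, False, ""))
    table = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    flagged = (~table["excluded"]) & (table["value"] > threshold)
    loci = _merge_windows(table, flagged.to_numpy(), "max_fst")
    return table, loci


def hudson_fst_per_site(
    pop_a: GenotypeMatrix, pop_b: GenotypeMatrix,
    inbred_a: bool = False, inbred_b: bool = False,
) -> pd.DataFrame:
    """Per-site Hudson numerator/denominator (used by tests and plots)."""
    sa, sb = site_stats(pop_a), site_stats(pop_b)
    n1 = sa["n_called"].to_numpy(float) * (1 if inbred_a else 2)
    n2 = sb["n_called"].to_numpy(float) * (1 if inbred_b else 2)
    p1, p2 = sa["p_ref"].to_numpy(), sb["p_ref"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return pd.DataFrame(
        {"chrom": sa["chrom"], "pos": sa["pos"], "num": num, "den": den}
    )


def _merge_windows(
    table: pd.DataFrame, flagged: np.ndarray, value_name: str
) -> pd.DataFrame:
    """Merge contiguous flagged windows (same chrom, touching spans) into loci."""
    rows = []
    current = None
    for i in np.flatnonzero(flagged):
        chrom = table.loc[i, "chrom"]
        start, end = int(table.loc[i, "start"]), int(table.loc[i, "end"])
        val = float(table.loc[i, "value"])
        if current and current["chrom"] == chrom and current["end"] == start:
            current["end"] = end
            current[value_name] = max(current[value_name], val)
            current["n_windows"] += 1
        else:
            if current:
                rows.append(current)
            current = {"chrom": chrom, "start": start, "end": end,
                       value_name: val, "n_windows": 1}
    if current:
        rows.append(current)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", value_name,
                                       "n_windows"])
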