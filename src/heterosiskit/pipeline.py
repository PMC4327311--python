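"""End-to-end orchestration: simulate -> scans -> parental inference ->
GWAS -> heterosis -> breeding simulation.

A single :class:`RunConfig` carries every stage threshold (MAF 0.03,
genome-wide p 1e-6, suggestive p 1e-4, Fst 0.3, Ho-He +/-0.4, 100-kb scan
windows, 500-kb locus windows, class-count filter 15, top-100 loci, four
reconstruction iterations) and one root seed from which each stage draws a
named substream.  Stages write plain TSV/VCF/JSON into the run directory; a
manifest records seeds, stage wall times and output hashes.  Stages can be
toggled for partial reruns — a stage whose inputs are absent fails fast
naming the missing upstream stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    GenotypeMatrix,
    kinship_matrix,
    maf_filter,
    read_genotypes,
    read_phenotypes,
    read_trios,
    site_stats,
    write_genotypes,
)
from . import breeding_sim, gwas_lmm, heterosis, parental_inference, popscan
from .synthetic_data import SimConfig, SimResult, observed_panel, simulate, write_outputs

ALL_STAGES = ("simulate", "popscan", "parents", "gwas", "heterosis", "breedsim")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the reference synthetic run."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    maf: float = 0.03
    genomewide_p: float = 1e-6
    suggestive_p: float = 1e-4
    fst_threshold: float = 0.3
    het_hi: float = 0.4
    het_lo: float = -0.4
    scan_window: int = 100_000
    locus_window: int = 500_000
    count_filter: int = 15
    top_n: int = 100
    max_iter: int = 4
    accept_ceiling: float = 0.02
    n_perm: int = 0
    gwas_analyses: tuple[tuple[str, str, str], ...] = (
        ("grain_number", "envA", "additive"),
        ("yield", "envA", "het_vs_hom"),
        ("heading_date", "envA", "additive"),
    )
    trait_directions: dict = field(
        default_factory=lambda: {
            "grain_number": "higher",
            "yield": "higher",
            "plant_height": "higher",
            "heading_date": "higher",
        }
    )
    breedsim_n_lines: int = 1000
    breedsim_scheme: str = "RIL"
    breedsim_n_loci: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "gwas_analyses" in data:
            data["gwas_analyses"] = tuple(tuple(a) for a in data["gwas_analyses"])
        return cls(**data)


class MissingStageError(RuntimeError):
    """An enabled stage is missing an upstream stage's outputs."""


def _need(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"stage '{stage}' requires {path.name} produced by stage "
            f"'{upstream}'; enable '{upstream}' or provide the file"
        )
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _pheno_vector(phen: pd.DataFrame, individuals: list[str], trait: str,
                  env: str) -> np.ndarray:
    sub = phen[(phen["trait"] == trait) & (phen["environment"] == env)]
    lut = dict(zip(sub["individual"], sub["value"]))
    return np.array([lut.get(i, np.nan) for i in individuals], float)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "timings_s": {},
        "outputs": {},
    }
    sim_result: SimResult | None = None

    def finish(stage: str, t0: float, *files: Path) -> None:
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        sim_result = simulate(sim_cfg)
        write_outputs(sim_result, outdir)
        finish("simulate", t0, *(outdir / n for n in (
            "hybrids.vcf", "maternal.vcf", "paternal.vcf", "landrace.vcf",
            "phenotypes.tsv", "trios.tsv", "truth.json")))

    def load(name: str, stage: str) -> GenotypeMatrix:
        return read_genotypes(_need(outdir / name, stage, "simulate"))

    def hybrids_for(stage: str) -> GenotypeMatrix:
        if sim_result is not None:
            return sim_result.hybrids
        return load("hybrids.vcf", stage)

    def phenotypes_for(stage: str) -> pd.DataFrame:
        if sim_result is not None:
            return sim_result.phenotypes
        return read_phenotypes(_need(outdir / "phenotypes.tsv", stage, "simulate"))

    if "popscan" in config.stages:
        t0 = time.perf_counter()
        hybrids = hybrids_for("popscan")
        maternal = sim_result.maternal if sim_result else load("maternal.vcf", "popscan")
        paternal = sim_result.paternal if sim_result else load("paternal.vcf", "popscan")
        landrace = sim_result.landrace if sim_result else load("landrace.vcf", "popscan")

        stats = site_stats(hybrids)
        stats["ho_minus_he"] = popscan.het_deviation(stats)
        stats.to_csv(outdir / "hetscan.tsv", sep="\t", index=False)
        out_loci = popscan.flag_het_outliers(stats, config.het_hi, config.het_lo,
                                             merge_distance=config.scan_window)
        pd.DataFrame(
            [(l.chrom, l.start, l.end, l.direction, l.peak_deviation,
              len(l.positions)) for l in out_loci],
            columns=["chrom", "start", "end", "direction", "peak_deviation",
                     "n_snps"],
        ).to_csv(outdir / "het_outlier_loci.tsv", sep="\t", index=False)

        ih = popscan.individual_heterozygosity(hybrids)
        ih.rename_axis("individual").reset_index().to_csv(
            outdir / "individual_heterozygosity.tsv", sep="\t", index=False)

        pi_h = popscan.windowed_pi(hybrids, config.scan_window)
        pi_l = popscan.windowed_pi(landrace, config.scan_window, inbred=True)
        pi_h.to_csv(outdir / "pi_hybrids.tsv", sep="\t", index=False)
        pi_l.to_csv(outdir / "pi_landrace.tsv", sep="\t", index=False)
        ratio, sweeps = popscan.sweep_scan(pi_l, pi_h)
        ratio.to_csv(outdir / "pi_ratio.tsv", sep="\t", index=False)
        sweeps.to_csv(outdir / "sweep_loci.tsv", sep="\t", index=False)

        fst, diff_loci = popscan.windowed_fst(
            maternal, paternal, config.scan_window, config.fst_threshold,
            inbred_a=True, inbred_b=True)
        fst.to_csv(outdir / "fst_windows.tsv", sep="\t", index=False)
        diff_loci.to_csv(outdir / "differentiated_loci.tsv", sep="\t", index=False)
        finish("popscan", t0, *(outdir / n for n in (
            "hetscan.tsv", "het_outlier_loci.tsv", "pi_ratio.tsv",
            "sweep_loci.tsv", "fst_windows.tsv", "differentiated_loci.tsv")))

    if "parents" in config.stages:
        t0 = time.perf_counter()
        hybrids = hybrids_for("parents")
        if sim_result is not None:
            panel = observed_panel(sim_result)
        else:
            panel = load("panel.vcf", "parents")
        assignments, inferred = parental_inference.iterate_reconstruction(
            hybrids, panel, max_iter=config.max_iter,
            accept_ceiling=config.accept_ceiling)
        pd.DataFrame([dataclasses.asdict(a) for a in assignments]).to_csv(
            outdir / "assignments.tsv", sep="\t", index=False)
        inferred_only = [i for i in inferred.ids
                         if inferred.provenance.get(i) == "inferred"]
        if inferred_only:
            gm = GenotypeMatrix(
                inferred_only, hybrids.sites,
                np.vstack([inferred.genotypes_of(i) for i in inferred_only]))
            write_genotypes(gm, outdir / "inferred_parents.vcf")
        report = {
            "n_hybrids": hybrids.n_individuals,
            "n_resolved": len(assignments),
            "resolved_fraction": len(assignments) / hybrids.n_individuals,
            "n_inferred_parents": len(inferred_only),
        }
        if sim_result is not None:
            _, overall = parental_inference.evaluate_agreement(
                inferred, sim_result.truth)
            report["truth_agreement"] = overall
        (outdir / "parent_report.json").write_text(json.dumps(report, indent=1))
        finish("parents", t0, outdir / "assignments.tsv",
               outdir / "parent_report.json")

    if "gwas" in config.stages:
        t0 = time.perf_counter()
        hybrids = hybrids_for("gwas")
        phen = phenotypes_for("gwas")
        filtered = maf_filter(hybrids, config.maf)
        K = kinship_matrix(filtered)
        gwas_files = []
        for trait, env, encoding in config.gwas_analyses:
            y = _pheno_vector(phen, filtered.individuals, trait, env)
            res = gwas_lmm.scan(y, filtered, K, encoding=encoding)
            loci = gwas_lmm.group_loci(res, window=config.locus_window,
                                       suggestive=config.suggestive_p,
                                       top_n=config.top_n)
            tag = f"{trait}_{env}_{encoding}"
            res.to_csv(outdir / f"gwas_{tag}.tsv", sep="\t", index=False)
            loci.to_csv(outdir / f"loci_{tag}.tsv", sep="\t", index=False)
            gwas_files += [outdir / f"gwas_{tag}.tsv", outdir / f"loci_{tag}.tsv"]
            if config.n_perm > 0:
                n_sig = int((loci["peak_p"] < config.genomewide_p).sum())
                fdr = gwas_lmm.permutation_fdr(
                    y, filtered, K, threshold=config.genomewide_p,
                    n_perm=config.n_perm, encoding=encoding,
                    observed_signals=n_sig or None,
                    rng=np.random.default_rng(config.seed + 7))
                (outdir / f"fdr_{tag}.json").write_text(json.dumps({
                    "mean_false_signals": fdr.mean_false_signals,
                    "observed_signals": n_sig, "fdr": fdr.fdr,
                    "n_perm": fdr.n_perm}, indent=1))
        finish("gwas", t0, *gwas_files)

    if "heterosis" in config.stages:
        t0 = time.perf_counter()
        hybrids = hybrids_for("heterosis")
        phen = phenotypes_for("heterosis")
        filtered = maf_filter(hybrids, config.maf)
        rng = np.random.default_rng(config.seed + 11)
        dom_rows, profile_frames, corr_rows = [], [], []
        census_sites: list[int] = []
        for trait, env, encoding in config.gwas_analyses:
            tag = f"{trait}_{env}_{encoding}"
            loci_path = _need(outdir / f"loci_{tag}.tsv", "heterosis", "gwas")
            loci = pd.read_csv(loci_path, sep="\t")
            y = _pheno_vector(phen, filtered.individuals, trait, env)
            sites = loci["site_index"].astype(int).tolist()
            census_sites.extend(sites[:1])
            superior = []
            for s in sites:
                rec = heterosis.dominance_at_site(
                    y, s, filtered, count_filter=config.count_filter,
                    n_boot=200, rng=rng)
                rec.trait, rec.environment = trait, env
                dom_rows.append(dataclasses.asdict(rec))
                cm = heterosis.genotype_class_means(y, s, filtered)
                higher = config.trait_directions.get(trait, "higher") == "higher"
                superior.append(heterosis.define_superior_allele(cm, higher))
            prof = heterosis.superior_profiles(filtered, sites, superior)
            prof.insert(1, "trait", trait)
            prof.insert(2, "environment", env)
            profile_frames.append(prof)
            corr = heterosis.correlate(prof, y)
            corr.insert(0, "trait", trait)
            corr.insert(1, "environment", env)
            corr_rows.append(corr)
        pd.DataFrame(dom_rows).to_csv(outdir / "dominance.tsv", sep="\t",
                                      index=False)
        pd.concat(profile_frames).to_csv(outdir / "profiles.tsv", sep="\t",
                                         index=False)
        pd.concat(corr_rows).to_csv(outdir / "correlations.tsv", sep="\t",
                                    index=False)
        trios = (sim_result.observed_trios if sim_result is not None
                 else read_trios(_need(outdir / "trios.tsv", "heterosis",
                                       "simulate")))
        trio_frames = []
        for trait, env, _ in config.gwas_analyses:
            recs, props = heterosis.trio_heterosis(trios, phen, trait, env)
            trio_frames.append(pd.DataFrame(
                [(r.trio.hybrid, trait, env, r.mph, r.over_parent_class)
                 for r in recs],
                columns=["hybrid", "trait", "environment", "mph", "class"]))
            manifest.setdefault("trio_class_proportions", {})[
                f"{trait}_{env}"] = props
        pd.concat(trio_frames).to_csv(outdir / "trio_heterosis.tsv", sep="\t",
                                      index=False)
        census_sites = sorted(set(census_sites))[:3]
        if len(census_sites) >= 2:
            census, n_possible, n_excl = heterosis.combination_census(
                filtered, census_sites)
            census.to_csv(outdir / "census.tsv", sep="\t", index=False)
            manifest["census"] = {
                "n_possible_classes": n_possible,
                "n_observed_classes": int(len(census)),
                "n_excluded": n_excl,
                "top2_share": heterosis.top2_share(census),
            }
        finish("heterosis", t0, outdir / "dominance.tsv",
               outdir / "profiles.tsv", outdir / "correlations.tsv",
               outdir / "trio_heterosis.tsv")

    if "breedsim" in config.stages:
        t0 = time.perf_counter()
        k = config.breedsim_n_loci
        gmap = breeding_sim.GeneticMap.rice_like(markers_per_chrom=1,
                                                 n_chrom=max(k, 3))
        p_a = np.zeros(gmap.n_markers, dtype=np.int8)
        p_b = np.full(gmap.n_markers, 2, dtype=np.int8)
        if config.breedsim_scheme == "RIL":
            design = breeding_sim.CrossDesign.ril(config.breedsim_n_lines, p_a, p_b)
        else:
            design = breeding_sim.CrossDesign.bc(config.breedsim_n_lines, p_a, p_b)
        pop = breeding_sim.make_population(
            design, gmap, np.random.default_rng(config.seed + 13))
        summ = breeding_sim.pyramiding_summary(pop, list(range(k)))
        summ.counts.to_csv(outdir / "pyramiding.tsv", sep="\t", index=False)
        manifest["breedsim"] = {
            "scheme": config.breedsim_scheme,
            "n_lines": config.breedsim_n_lines,
            "n_loci": k,
            "fraction_fixed_all": summ.fraction_fixed_all,
            "expected_unlinked": summ.expected_unlinked,
        }
        finish("breedsim", t0, outdir / "pyramiding.tsv")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
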