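# heterosiskit

Tools for dissecting heterosis (hybrid vigour) in F1 hybrid crop panels,
built around the genetics of three-line hybrid rice: every commercial
hybrid is an F1 between a male-sterile female line and a restorer male
line, both fully inbred, so the hybrid genome is the union of two
homozygous parental genomes. The package answers three questions on such
panels:

1. **Whose child is this hybrid?** The seeds of most parental lines are
   unavailable, but because an F1 carries one allele from each parent at
   every site, an observed parent plus the hybrid determines the other
   parent's genome. `heterosiskit` implements the iterative kinship-based
   reconstruction: match each hybrid to its best panel candidate (top
   simple-matching kinship, opposite-homozygote conflict rate <= 2%),
   deduce the other parent, add it to the panel, repeat — cascades through
   shared female lines resolve hybrids whose parents were both unknown.
2. **Which loci matter, and how do heterozygotes behave there?** An
   EMMAX-style variance-component mixed model (simple-matching kinship as
   the covariance of the random effect; REML by spectral decomposition and
   1-D search over delta = sigma_e^2/sigma_g^2; per-SNP GLS with fixed
   components) under additive, dominant, recessive and het-vs-hom
   encodings, with fixed 500-kb locus grouping and permutation-based FDR.
   At each associated peak the dominance degree d/a is computed from
   genotype-class means (a = half the homozygote difference, d = the
   heterozygote's deviation from the homozygote midpoint); |d/a| > 1 is
   overdominance.
3. **Does heterosis come from heterozygosity or from superior alleles?**
   Per-hybrid tallies of heterozygous superior genotypes and accumulated
   superior-allele dosage over the top loci, correlated with the traits;
   mid-parent and over-parent heterosis in parent-child trios; the
   2(1-q)q/q ≈ 2 carrier-enrichment identity for rare alleles; and a
   Haldane-meiosis breeding simulator (RIL and BC5F3 designs) quantifying
   how hard it is to pyramid many superior alleles into one inbred line.

Population-genetic scans round out the toolkit: per-individual
heterozygosity, Ho - He screening for Hardy–Weinberg outliers (hybrid
incompatibility loci show up as localized heterozygote deficits), windowed
nucleotide diversity, landrace/modern pi-ratio sweep scans, and windowed
Hudson Fst between the parental pools.

Everything is validated on a synthetic panel generator with full ground
truth (founder pools with controlled Fst, power-law parent usage, QTLs
with additive/dominant/overdominant effects and environment-specific
activity, a sweep region, an incompatibility locus, genotype error and
missingness). See `docs/methods.md` for estimators, defaults and
limitations.

## Worked example

```python
import numpy as np
from heterosiskit import SimConfig, simulate, kinship_matrix, maf_filter
from heterosiskit.synthetic_data import observed_panel
from heterosiskit.parental_inference import iterate_reconstruction, evaluate_agreement
from heterosiskit import gwas_lmm
from heterosiskit.heterosis import dominance_at_site

res = simulate(SimConfig(seed=1))
assignments, panel = iterate_reconstruction(res.hybrids, observed_panel(res))
per_parent, overall = evaluate_agreement(panel, res.truth)

gm = maf_filter(res.hybrids, 0.03)
K = kinship_matrix(gm)
phen = res.phenotypes
sub = phen[(phen.trait == "grain_number") & (phen.environment == "envA")]
y = np.array([dict(zip(sub.individual, sub.value))[i] for i in gm.individuals])
scan = gwas_lmm.scan(y, gm, K)
loci = gwas_lmm.group_loci(scan, suggestive=1e-4)
rec = dominance_at_site(y, int(loci.iloc[0]["site_index"]), gm, rng=0)
```

printed (seed 1):

```
panel: 300 hybrids x 5000 SNPs, 30 of 60 parents observed
resolved 300/300 hybrids in 2 iterations; inferred-parent agreement with truth: 99.8%
grain number (envA): 3 associated loci at p < 1e-4; top peak chr1:145762 (p = 3.8e-05)
dominance at peak: a = 3.48, d = -0.11, d/a = -0.03 (additive)
```

Reading the output: half the parents were hidden, yet all 300 hybrids are
resolved — hybrids whose parents were both hidden resolve in round 2 after
a shared parent was deduced from a half-sib in round 1 — and the inferred
parental genomes agree with the hidden truth at 99.8% of sites despite 1%
genotype error and 5% missingness. The grain-number scan finds loci at the
suggestive threshold; the top peak behaves additively (d/a ≈ 0), which is
typical — the planted rare superior alleles have partial dominance, and
the peak SNP need not be the causal one.

A command-line interface mirrors the library
(`heterosiskit simulate|hetscan|pi|sweep|fst|infer-parents|gwas|dominance|
superior|trios|census|breedsim|run`); `heterosiskit run --out dir/ --seed 1`
executes the full pipeline and writes per-stage TSV/VCF/JSON outputs plus
a manifest with seeds, timings and output hashes.

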