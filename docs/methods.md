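# Methods

This note documents the models, estimators and design choices behind
`heterosiskit`, and what the synthetic benchmark does and does not show
about real hybrid panels.

## The scientific setting

Hybrid rice is bred by crossing two inbred pools — male-sterile female
lines and restorer male lines — so every commercial variety is an F1 whose
genome is the union of two homozygous parental genomes. Three questions
drive the toolkit: (i) can the unobserved parental genomes be reconstructed
from the hybrids themselves, (ii) which loci are associated with agronomic
traits and how do their heterozygous genotypes behave (dominance vs
overdominance), and (iii) how much of hybrid vigour is explained by the
accumulation of rare superior alleles rather than by heterozygosity per se.

## Genotype representation

Biallelic SNPs only; diploid codes 0 (hom-ref "rr"), 1 (het "ra"),
2 (hom-alt "aa"), -1 missing. External coordinates are 1-based VCF
positions; all windowed statistics use 0-based half-open bp intervals on a
fixed grid (100 kb for scans, 500 kb for association loci). Missing data
are excluded pairwise in all statistics and never imputed — imputation is
deliberately out of scope, and the parental-inference consensus (below)
stands in for it where the original workflow would have used phased data.

Kinship is the simple-matching coefficient on diploid codes: the fraction
of pairwise-called sites with identical codes. Heterozygote/homozygote
mismatches are not weighted differently from homozygote/homozygote
mismatches; the matching is flat.

## Synthetic panel generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated.

- **Founders.** Pool allele frequencies follow a Balding–Nichols draw
  around a shared ancestral frequency (Uniform(0.05, 0.95)); the divergence
  parameter equals the expected Hudson Fst between pools, so the default
  0.08 reproduces the modest maternal/paternal differentiation typical of
  three-line breeding pools. Inbreds are one allele draw per line,
  duplicated into a homozygous diploid. A block of sites on chr7 gets a
  large frequency gap (0.9+ vs <0.1) to emulate fertility-restorer-type
  differentiated loci; an S5-like incompatibility locus segregates at
  frequency 0.5 in both pools (such loci are by nature polymorphic within
  the breeding pools, otherwise no incompatible heterozygotes would arise).
- **Sweep.** Inside a declared region (chr1:500k–1M by default) modern-pool
  frequencies are divided by a diversity-reduction factor (default 10)
  toward fixation; landraces keep ancestral diversity, giving a
  pi_landrace/pi_modern contrast of roughly that factor.
- **Crosses.** Mother and father are drawn with truncated power-law usage
  weights (exponent 1.2) — a few popular lines parent many hybrids, which
  is exactly the cascade structure the parental-inference iteration
  exploits. F1 codes are the mean parental dosage. Genotype error is a
  symmetric adjacent-code flip (0↔1, 1↔2) at 1%, mimicking under-called
  heterozygotes at low coverage; missingness is 5%.
- **Phenotypes.** Per QTL the codes {hom-inferior, het, hom-superior}
  contribute {-a, d, +a}; environment-scoped QTLs contribute only in their
  environment (two environments, a short-day "envA" and long-day "envB",
  with photoperiod-sensitive heading-date QTLs active only in envA).
  Gaussian noise is scaled to the configured per-trait heritability on the
  realized genetic variance. Default architecture: 12 grain-number QTLs
  with partial dominance and rare superior alleles (frequencies 0.02–0.05),
  10 positive- and 3 negative-overdominant yield QTLs at moderate
  frequency, negative-dominance heading-date QTLs, additive plant-height
  QTLs.
- **Incompatibility.** Heterozygotes at the focal locus (and linked sites
  within 50 kb) are replaced by a surviving homozygote with probability
  0.9. The expected Ho - He at the locus is then about -0.45, safely beyond
  the -0.4 screening threshold; a penalty of 0.8 would sit exactly on the
  threshold in expectation and make the screen a coin flip, which is why
  the default models a strong sterility locus.

What the generator does **not** emulate: linkage disequilibrium within
chromosomes (sites are independent given pool frequencies), genotype
likelihood uncertainty, shared pedigree among founders, epistasis, or
genotype-by-environment noise correlation. Passing tests therefore
demonstrate correctness of the estimators and the logic of the pipeline
under a faithful but LD-free population model — not calling or imputation
performance on sequence data.

## Population-genetic scans

- **Ho - He.** He = 2pq from called allele frequencies; the scan flags
  SNPs beyond +0.4 / -0.4 and merges them into loci by single linkage
  within one 100-kb window (the merge rule is ours; no canonical rule
  exists for this screen).
- **pi.** Per window, the sum over SNPs of the unbiased per-site
  heterozygosity 2pq·n/(n-1) divided by the window span, with n the number
  of called alleles. Fully inbred panels use n = number of lines (their two
  allele copies are identical by descent); this matters for the Hudson
  correction too. The estimator assumes random union of gametes within a
  pool; it is the standard frequency-based pi, chosen because the genotype
  matrix carries no phase.
- **Sweep scan.** pi_landrace/pi_modern per window; windows are excluded
  (with a recorded reason, never silently) when either input has no data,
  fewer than 5 genotyped SNPs, or both diversities fall below a floor
  (default 10% of median landrace pi — a ratio of two near-zero numbers is
  noise). The top 0.5% of usable ratios, merged when contiguous, are the
  sweep loci; the fraction is a screening default, not a significance
  statement.
- **Fst.** Hudson's estimator with sample-size correction, combined per
  window as a ratio of averages (numerators summed over denominators
  summed), clamped to [0, 1]; windows above 0.3 merge into differentiated
  loci. Hudson + ratio-of-averages is the low-bias choice for unequal pool
  sizes.

## Parental inference

Each round: score every unresolved hybrid against the current panel by
simple-matching kinship; accept the top candidate if its
opposite-homozygote conflict rate is at most 2% (conflicts are Mendelian
impossibilities for a true parent, so the ceiling is directly
interpretable as a tolerated error rate — we prefer this to a raw kinship
floor). Deduce the other parent sitewise (het hybrid + hom parent
determines the other allele; shared homozygotes propagate; conflicts and
missing stay masked), cluster the round's deductions at matching >= 0.9
into "same line" groups, and enter their majority consensus into the panel
as new inferred parents. Four rounds by default. Conflicted/missing sites
are filled by the cross-hybrid consensus — the same multiple-F1s-per-parent
information a phasing-based local haplotype fill would use, without a
phasing dependency.

Evaluation maps each inferred parent to the true parent (among the true
mothers/fathers of its supporting hybrids) with the highest matching, then
scores agreement over called, unmasked sites, site-weighted overall. On
the reference scenario this is ~99.8%, comfortably above the 98% design
bound; at error rate 0 with all parents observed, reconstruction is exact.

## Mixed-model association

The model is y = Xb + g + e with Var(g) = sigma_g^2 K and
Var(e) = sigma_e^2 I, K the simple-matching kinship standardized to unit
mean diagonal. REML variance components come from the spectral
decomposition of K and a 1-D search over log delta (delta =
sigma_e^2/sigma_g^2): an 81-point grid on [-10, 10] followed by bounded
Brent refinement; the grid-vs-fine-grid agreement is tested to 1e-3 in
log-likelihood. Each SNP is then tested by GLS with components fixed from
the null model (the one-time-rotation approximation that EMMAX-style scans
use), with a Wald t statistic; with K proportional to the identity this
reduces exactly to OLS (tested to 1e-10). Missing genotypes are
mean-imputed in the numeric design only; class counts report raw codes.

Encodings: additive (0/1/2), dominant (het folded into hom-alt), recessive
(het folded into hom-ref), het-vs-hom (both homozygote classes 0, het 1 —
the encoding that isolates overdominance; at allele frequency 0.5 it is
exactly orthogonal to the additive dosage).

Loci are defined on a fixed 500-kb window grid: the window's minimum p is
its signal, windows below the suggestive threshold 1e-4 are kept and
ranked, the top 100 retained. Adjacent significant windows are not merged;
the grid is the locus definition, applied identically to real and permuted
scans so false-signal counts are comparable. Permutation FDR: reshuffle
the phenotype (plain reshuffle; the panel has no discrete subpopulation
strata to stratify by), rerun the full scan with a re-fitted delta, count
loci passing the genome-wide threshold 1e-6; FDR = mean false signals per
permuted analysis x number of real analyses / observed signals, undefined
(not zero) when nothing was observed.

## Dominance and superior alleles

At an associated peak SNP with class means m_rr, m_ra, m_aa:
a = |m_aa - m_rr|/2 (the high homozygote orients the sign, so a >= 0),
d = m_ra - (m_rr + m_aa)/2, degree = d/a. Classification bands on |d/a|:
<= 0.2 additive, 0.2–0.8 partial, 0.8–1.2 complete, > 1.2 overdominant
with the sign of d; undefined when a is below tolerance. Sites whose
heterozygote or minor-homozygote class has <= 15 individuals are excluded.
The headline overdominance census uses these point-estimate
classifications. A bootstrap lower bound on d/a (2.5% quantile, 1,000
resamples) is attached as a confidence annotation, but it does not gate
the census: with many QTLs behind one trait, the polygenic background of
the other loci puts an irreducible floor under class-mean noise, and a
CI-above-1 gate suppresses most genuinely overdominant loci at desk-scale
panel sizes. Raw class means are also confounded by cryptic relatedness
when few founders parent many hybrids — the founder-rich recovery scenario
in the tests (500 parents, 1,500 hybrids) quantifies this.

The superior allele of a locus is the allele whose homozygote mean is
better in the trait's beneficial direction (higher-is-better by default,
including heading date, where a longer growth period feeds yield;
overridable per trait). Per-individual profiles tally heterozygous
superior genotypes and total superior-allele dosage over the top loci;
both are correlated with the trait (Pearson primary, Spearman alongside)
together with whole-genome heterozygosity. Profiles are per environment;
no cross-environment merge of superior-allele definitions is attempted,
since a locus can be superior in one environment only. Trio heterosis:
MPH = (F1 - MP)/MP, undefined when MP = 0; over-parent classes by strict
comparison against the better and worse parent.

The carrier-enrichment identity 2(1-q)q/q = 2(1-q) states why hybrid
breeding deploys rare superior alleles efficiently: heterozygous carriers
among random-cross F1s are ~2x as frequent as homozygous carriers among
inbreds when q is small.

## Breeding simulation

Meiosis follows Haldane's model: Poisson(L/100) crossovers per chromosome,
uniform positions, no interference. Populations are generated with the
exact Markov equivalent at the marker grid (independent Bernoulli phase
switches between adjacent markers with the Haldane recombination
fraction), which vectorizes across lines. RILs are built by single-seed
descent to F8 (seven selfing meioses; residual heterozygosity ~(1/2)^7 is
reported, not idealized away); BC5F3 is five backcrosses then two
selfings. The default map is rice-like — 12 chromosomes of 150 cM — with
no claim to the true rice map; 1 cM is emitted as 25 kb on a synthetic bp
grid. The pyramiding summary reports the fraction of lines homozygous for
the superior allele at all k tracked loci ((1/2)^k expected for unlinked
loci in RILs), the quantitative core of why stacking many superior alleles
into one inbred line requires very large populations or many cycles.

## Problem sizes and numerical choices

The reference scenario is 60 parents / 300 hybrids / 5,000 SNPs — large
enough that every stage's behavior is measurable, small enough that the
full pipeline runs in seconds and the whole test suite in well under half
an hour on one core. Heavier properties use dedicated scenarios: n = 800
for association power and effect-recovery checks, n = 1,500 with 500
founders for the overdominance census, 5,000–20,000 lines for breeding
arithmetic. Degenerate inputs are flagged, never zero-filled: all-missing
sites carry NaN statistics, empty genotype classes NaN means, monomorphic
sites NaN p-values, zero-variance predictors NaN correlations. Ties break
deterministically (candidate parents: kinship, then conflict rate, then
lexicographic ID; consensus votes: ties stay missing). Eigenvalues of K
are clipped at zero; a degenerate K falls back to the identity with a
warning.

## Known limitations

No LD within chromosomes in the generator (sweep and incompatibility
signals are injected at the frequency level); no genotype-likelihood or
imputation modeling; the per-SNP mixed model uses the one-time-rotation
approximation rather than exact per-SNP REML; the d/a census inherits the
confounding of raw class means under strong cryptic relatedness; breeding
simulations are neutral (no selection during line development).
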