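import numpy as np
import pytest

from heterosiskit.core_io import GenotypeMatrix, VariantSite
from heterosiskit.synthetic_data import SimConfig, simulate


def make_matrix(codes, chrom="chr1", spacing=1000, individuals=None):
    """Small genotype matrix from a codes array (rows = individuals)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    if individuals is None:
        individuals = [f"I{i + 1}" for i in range(n)]
    sites = [VariantSite(chrom, 1 + j * spacing, "A", "G") for j in range(m)]
    return GenotypeMatrix(individuals, sites, codes)


def hwe_panel(n, m, rng, q=None, chrom_length=1_000_000, n_chrom=1):
    """Random-mating diploid panel at Hardy-Weinberg proportions."""
    if q is None:
        q = rng.uniform(0.1, 0.9, m)
    codes = ((rng.random((n, m)) < q).astype(np.int8)
             + (rng.random((n, m)) < q).astype(np.int8))
    per = m // n_chrom
    sites = []
    for j in range(m):
        c = min(j // per, n_chrom - 1)
        sites.append(VariantSite(f"chr{c + 1}", 1 + (j - c * per) * (chrom_length // per),
                                 "A", "G"))
    return GenotypeMatrix([f"I{i + 1}" for i in range(n)], sites, codes)


def pheno_vector(result, trait, env, individuals=None):
    phen = result.phenotypes
    sub = phen[(phen["trait"] == trait) & (phen["environment"] == env)]
    lut = dict(zip(sub["individual"], sub["value"]))
    ids = individuals if individuals is not None else result.hybrids.individuals
    return np.array([lut[i] for i in ids], float)


@pytest.fixture(scope="session")
def default_sim():
    """The reference scenario: 60 parents, 300 hybrids, 5,000 SNPs, seed 1."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, fully observed variant of the reference scenario."""
    return simulate(SimConfig(seed=2, error_rate=0.0, missing_rate=0.0,
                              observed_parent_fraction=1.0,
                              incompatibility=None))


# derandomized hypothesis runs: property tests are reproducible across sessions
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")
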