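"""Variance-component mixed-model association scan (EMMAX-style).

The model is ``y = X b + Z g + e`` with a single random effect whose
covariance is the simple-matching kinship matrix: ``g ~ N(0, sg2 K)``,
``e ~ N(0, se2 I)``.  Variance components are fitted once by REML on the
null model (no SNP) via spectral decomposition of K and a one-dimensional
search over ``delta = se2 / sg2``; every SNP is then tested by generalized
least squares with the components held fixed — the standard one-time
rotation approximation that makes panel-scale scans cheap.

Four genotype encodings are supported: additive (0/1/2 alternative-allele
dosage), dominant and recessive (heterozygotes folded into one homozygote
class), and het-vs-hom (both homozygote classes coded 0, heterozygotes 1 —
the encoding that isolates pure overdominance signals).

Multiple testing is handled the way large hybrid panels are analysed in
practice: permutations of the phenotype vector break the genotype-phenotype
link while preserving the trait distribution and the relatedness structure
of the markers, and the count of "significant" loci in permuted scans
estimates the false-signal rate at a given threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import GenotypeMatrix, KinshipMatrix

ENCODINGS = ("additive", "dominant", "recessive", "het_vs_hom")

_ENCODE_MAP = {
    "additive": {0: 0.0, 1: 1.0, 2: 2.0},
    "dominant": {0: 0.0, 1: 2.0, 2: 2.0},
    "recessive": {0: 0.0, 1: 0.0, 2: 2.0},
    "het_vs_hom": {0: 0.0, 1: 1.0, 2: 0.0},
}


@dataclass
class VarianceComponents:
    """REML estimates of the null mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    log_reml: float

    @property
    def heritability(self) -> float:
        """Pseudo-heritability sg2 / (sg2 + se2) under unit-mean-diagonal K."""
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else float("nan")


def encode(matrix: GenotypeMatrix, encoding: str) -> np.ndarray:
    """Numeric design values per (individual, site); missing -> NaN."""
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; choose from {ENCODINGS}")
    lut = np.full(4, np.nan)
    for code, val in _ENCODE_MAP[encoding].items():
        lut[code] = val
    # codes are {-1,0,1,2}; index -1 wraps to lut[3] which stays NaN
    return lut[matrix.codes]


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

@dataclass
class _Decomposition:
    """Cached spectral pieces of a standardized kinship matrix."""

    U: np.ndarray  # eigenvectors (n, n)
    d: np.ndarray  # eigenvalues >= 0


def standardize_kinship(K: KinshipMatrix | np.ndarray) -> np.ndarray:
    """Scale K to unit mean diagonal and symmetrize."""
    V = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    V = 0.5 * (V + V.T)
    md = float(np.mean(np.diag(V)))
    if not np.isfinite(md) or md <= 0:
        warnings.warn("degenerate kinship matrix; falling back to identity")
        return np.eye(V.shape[0])
    return V / md


def _decompose(Kstd: np.ndarray) -> _Decomposition:
    d, U = np.linalg.eigh(Kstd)
    return _Decomposition(U=U, d=np.clip(d, 0.0, None))


def _reml_loglik(log_delta: float, yr: np.ndarray, Xr: np.ndarray,
                 d: np.ndarray, logdet_xtx: float) -> float:
    delta = np.exp(log_delta)
    w = d + delta
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    resid = yr - Xr @ beta
    rss = float(resid @ (resid / w))
    n, p = Xr.shape
    df = n - p
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0 or rss <= 0:
        return -np.inf
    return 0.5 * (
        df * np.log(df / (2 * np.pi))
        - df
        - df * np.log(rss)
        - float(np.sum(np.log(w)))
        + logdet_xtx
        - logdet_xtwx
    )


def _fit_delta(yr: np.ndarray, Xr: np.ndarray, d: np.ndarray
               ) -> tuple[float, float, float]:
    """Multi-start grid + bracketed refinement of the REML log-likelihood.

    Returns (delta, log_reml, sigma_g2).
    """
    _, logdet_xtx = np.linalg.slogdet(Xr.T @ Xr)
    grid = np.linspace(-10.0, 10.0, 81)
    lls = np.array([_reml_loglik(g, yr, Xr, d, logdet_xtx) for g in grid])
    i = int(np.nanargmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, yr, Xr, d, logdet_xtx),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    log_delta = float(res.x)
    if -res.fun < lls[i]:  # keep grid point if refinement went sideways
        log_delta = float(grid[i])
    delta = float(np.exp(log_delta))
    ll = _reml_loglik(log_delta, yr, Xr, d, logdet_xtx)
    w = d + delta
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    resid = yr - Xr @ beta
    sigma_g2 = float(resid @ (resid / w)) / (Xr.shape[0] - Xr.shape[1])
    return delta, float(ll), sigma_g2


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    return X


def fit_null(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
) -> VarianceComponents:
    """REML fit of the null model ``y = X b + g + e`` with Var(g) = sg2 K.

    K is standardized to unit mean diagonal before decomposition.  ``delta``
    is found by a coarse grid over ``log delta`` followed by bounded
    refinement.  Raises on non-finite phenotypes.
    """
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector contains non-finite values")
    if y.size < 10:
        raise ValueError("need at least 10 phenotyped individuals")
    Kstd = standardize_kinship(K)
    if Kstd.shape[0] != y.size:
        raise ValueError("kinship dimension does not match phenotypes")
    dec = _decompose(Kstd)
    X = _design(y.size, covariates)
    yr = dec.U.T @ y
    Xr = dec.U.T @ X
    delta, ll, sg2 = _fit_delta(yr, Xr, dec.d)
    return VarianceComponents(
        sigma_g2=sg2, sigma_e2=delta * sg2, delta=delta, log_reml=ll
    )


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

def _scan_rotated(
    y: np.ndarray,
    G: np.ndarray,
    X: np.ndarray,
    dec: _Decomposition,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """GLS association of every column of G with y under fixed components.

    Returns (beta, se, p) arrays and the fitted delta.
    """
    yr = dec.U.T @ y
    Xr = dec.U.T @ X
    delta, _, _ = _fit_delta(yr, Xr, dec.d)
    sw = np.sqrt(dec.d + delta)
    yt = yr / sw
    Xt = Xr / sw[:, None]
    Gt = (dec.U.T @ G) / sw[:, None]
    Q, _ = np.linalg.qr(Xt)
    yp = yt - Q @ (Q.T @ yt)
    Gp = Gt - Q @ (Q.T @ Gt)
    gg = np.einsum("ij,ij->j", Gp, Gp)
    gy = Gp.T @ yp
    yy = float(yp @ yp)
    n, p = Xt.shape
    df = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / np.where(gg > 0, gg, 1.0), np.nan)
        rss = yy - beta**2 * gg
        sigma2 = rss / df
        se = np.sqrt(np.where(gg > 0, sigma2 / np.where(gg > 0, gg, 1.0), np.nan))
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    # degenerate (monomorphic after encoding) columns: flag rather than p=1
    tiny = gg <= gg.max() * 1e-12 if gg.size and gg.max() > 0 else gg <= 0
    pvals[tiny] = np.nan
    beta[tiny] = np.nan
    se[tiny] = np.nan
    return beta, se, pvals, delta


def scan(
    y: np.ndarray,
    matrix: GenotypeMatrix,
    K: KinshipMatrix | np.ndarray,
    encoding: str = "additive",
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mixed-model association of one phenotype with every site.

    Individuals with NaN phenotype are dropped (with the matching K rows and
    columns).  Missing genotypes are mean-imputed in the numeric design only;
    the reported genotype-class counts come from the raw codes.

    Returns a DataFrame with chrom, pos, site_index, encoding, beta, se, p,
    n_rr, n_ra, n_aa.
    """
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 phenotyped individuals")
    Kstd = standardize_kinship(K)[np.ix_(keep, keep)]
    codes = matrix.codes[keep]
    yk = y[keep]
    G = encode(matrix, encoding)[keep]
    mu = np.nanmean(G, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    G = np.where(np.isnan(G), mu, G)
    dec = _decompose(Kstd)
    X = _design(yk.size, covariates[keep] if covariates is not None else None)
    beta, se, pvals, _ = _scan_rotated(yk, G, X, dec)
    return pd.DataFrame(
        {
            "chrom": matrix.chroms,
            "pos": matrix.positions,
            "site_index": np.arange(matrix.n_sites),
            "encoding": encoding,
            "beta": beta,
            "se": se,
            "p": pvals,
            "n_rr": (codes == 0).sum(axis=0),
            "n_ra": (codes == 1).sum(axis=0),
            "n_aa": (codes == 2).sum(axis=0),
        }
    )


# ---------------------------------------------------------------------------
# Locus grouping and permutation FDR
# ---------------------------------------------------------------------------

def group_loci(
    results: pd.DataFrame,
    window: int = 500_000,
    suggestive: float = 1e-4,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Collapse per-SNP results into fixed 500-kb-window association loci.

    Per window the minimum p is the locus signal; windows with signal below
    ``suggestive`` are kept, ranked by signal, and the ``top_n`` strongest
    returned.  Adjacent significant windows are deliberately *not* merged —
    the window grid is the locus definition.
    """
    res = results.dropna(subset=["p"]).copy()
    res["win_start"] = ((res["pos"] - 1) // window) * window
    idx = res.groupby(["chrom", "win_start"], sort=False)["p"].idxmin()
    peaks = res.loc[idx].copy()
    peaks = peaks[peaks["p"] < suggestive]
    peaks = peaks.sort_values(["p", "chrom", "win_start"]).reset_index(drop=True)
    peaks["rank"] = np.arange(1, len(peaks) + 1)
    if top_n is not None:
        peaks = peaks.head(top_n)
    out = peaks.rename(columns={"pos": "peak_pos", "p": "peak_p"})
    out["win_end"] = out["win_start"] + window
    return out[
        ["chrom", "win_start", "win_end", "peak_pos", "site_index", "encoding",
         "peak_p", "rank"]
    ]


@dataclass
class PermutationFDR:
    """Permutation estimate of the false-signal rate at a p threshold."""

    threshold: float
    n_perm: int
    signals_per_perm: list[int]
    mean_false_signals: float
    n_analyses: int
    observed_signals: int | None
    fdr: float | None  # None when no observed signal (undefined)


def permutation_fdr(
    y: np.ndarray,
    matrix: GenotypeMatrix,
    K: KinshipMatrix | np.ndarray,
    threshold: float = 1e-6,
    n_perm: int = 100,
    encoding: str = "additive",
    observed_signals: int | None = None,
    n_analyses: int = 1,
    window: int = 500_000,
    rng: np.random.Generator | int | None = None,
) -> PermutationFDR:
    """Estimate the FDR of association signals by phenotype permutation.

    Each permutation reshuffles y (breaking the genotype-phenotype link while
    preserving the trait distribution), reruns the full mixed-model scan with
    a re-fitted delta, and counts loci passing ``threshold`` after 500-kb
    grouping.  FDR = mean false signals per permuted analysis x
    ``n_analyses`` / ``observed_signals``; with zero observed signals the
    FDR is undefined and reported as None.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    Kstd = standardize_kinship(K)[np.ix_(keep, keep)]
    dec = _decompose(Kstd)
    G = encode(matrix, encoding)[keep]
    mu = np.nanmean(G, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    G = np.where(np.isnan(G), mu, G)
    X = _design(int(keep.sum()), None)
    base = pd.DataFrame({"chrom": matrix.chroms, "pos": matrix.positions,
                         "site_index": np.arange(matrix.n_sites)})
    counts = []
    for _ in range(n_perm):
        yp = rng.permutation(y[keep])
        _, _, pvals, _ = _scan_rotated(yp, G, X, dec)
        res = base.copy()
        res["p"] = pvals
        res["encoding"] = encoding
        loci = group_loci(res, window=window, suggestive=threshold)
        counts.append(int(len(loci)))
    mean_false = float(np.mean(counts))
    fdr: float | None
    if observed_signals is None or observed_signals == 0:
        fdr = None
    else:
        fdr = mean_false * n_analyses / observed_signals
    return PermutationFDR(
        threshold=threshold,
        n_perm=n_perm,
        signals_per_perm=counts,
        mean_false_signals=mean_false,
        n_analyses=n_analyses,
        observed_signals=observed_signals,
        fdr=fdr,
    )
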