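"""Kinship, chip heritability, permutation-null GWA, LD and Grantham scoring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import MISSING, HerbclockError, VariantTable
from .selection import ContingencyResult, fisher_contingency

# ---------------------------------------------------------------------------
# Grantham (1974) amino-acid distances, embedded as the published integers.
# Row order follows the original table; the matrix is symmetric, zero on the
# diagonal, and maxes at 215 (Cys-Trp).
# ---------------------------------------------------------------------------

_AA_ORDER = "SRLPTAVGIFYCHQNKDEMW"

_GRANTHAM_UPPER = [
    # S    R    L    P    T    A    V    G    I    F    Y    C    H    Q    N    K    D    E    M    W
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],  # S
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],          # R
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],              # L
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],                  # P
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],                         # T
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],                        # A
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],                               # V
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],                                 # G
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],                                      # I
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],                                         # F
    [194, 83, 99, 143, 85, 160, 122, 36, 37],                                                # Y
    [174, 154, 139, 202, 154, 170, 196, 215],                                                # C
    [24, 68, 32, 81, 40, 87, 115],                                                           # H
    [46, 53, 61, 29, 101, 130],                                                              # Q
    [94, 23, 42, 142, 174],                                                                  # N
    [101, 56, 95, 110],                                                                      # K
    [45, 160, 181],                                                                          # D
    [126, 152],                                                                              # E
    [67],                                                                                    # M
]


def _build_grantham() -> dict[tuple[str, str], int]:
    m: dict[tuple[str, str], int] = {}
    for i, aa in enumerate(_AA_ORDER):
        m[(aa, aa)] = 0
        for k, val in enumerate(_GRANTHAM_UPPER[i] if i < len(_GRANTHAM_UPPER) else []):
            bb = _AA_ORDER[i + 1 + k]
            m[(aa, bb)] = val
            m[(bb, aa)] = val
    return m


GRANTHAM: dict[tuple[str, str], int] = _build_grantham()


def grantham_score(aa_from: str, aa_to: str) -> int:
    """Grantham physico-chemical distance between two amino acids (0-215)."""
    a, b = aa_from.upper(), aa_to.upper()
    if a not in _AA_ORDER or b not in _AA_ORDER:
        raise HerbclockError(f"unknown amino acid in ({aa_from!r}, {aa_to!r})")
    return GRANTHAM[(a, b)]


def grantham_matrix() -> pd.DataFrame:
    """The full 20x20 symmetric matrix as a DataFrame."""
    letters = list(_AA_ORDER)
    arr = np.array([[GRANTHAM[(a, b)] for b in letters] for a in letters])
    return pd.DataFrame(arr, index=letters, columns=letters)


# ---------------------------------------------------------------------------
# genotype helpers
# ---------------------------------------------------------------------------

def _imputed_dosages(v: VariantTable, maf_min: float) -> tuple[np.ndarray, np.ndarray]:
    """(sites x samples) float matrix, missing -> site mean; indices of kept sites."""
    der, nm = v.derived_freqs()
    with np.errstate(invalid="ignore"):
        freq = np.where(nm > 0, der / nm, 0.0)
    maf = np.minimum(freq, 1 - freq)
    keep = np.flatnonzero((maf >= maf_min) & (nm > 0))
    X = v.calls[keep].astype(float)
    means = freq[keep]
    X = np.where(v.calls[keep] == MISSING, means[:, None], X)
    return X, keep


def kinship_matrix(v: VariantTable, maf_min: float = 0.05,
                   ridge: float = 1e-8) -> np.ndarray:
    """Centered, standardized allele cross-product kinship.

    Each passing site is centered at its derived-allele frequency p and
    scaled by sqrt(p(1-p)); K = X'X / m over the m sites used.  A small
    ridge is added if the result is not numerically PSD.
    """
    X, keep = _imputed_dosages(v, maf_min)
    if len(keep) == 0:
        raise HerbclockError(f"no sites pass MAF >= {maf_min}")
    p = X.mean(axis=1)
    sd = np.sqrt(p * (1 - p))
    sd[sd == 0] = 1.0
    Z = (X - p[:, None]) / sd[:, None]
    K = Z.T @ Z / len(keep)
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8:
        warnings.warn("kinship not PSD; adding ridge")
        K = K + (abs(w.min()) + ridge) * np.eye(K.shape[0])
    return K


# ---------------------------------------------------------------------------
# chip heritability (REML, EMMA-style eigendecomposition)
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityResult:
    sigma_g: float
    sigma_e: float
    h2: float
    loglik: float
    loglik_null: float
    lrt_p: float

    @property
    def sigma_total(self) -> float:
        return self.sigma_g + self.sigma_e


def chip_heritability(y, K: np.ndarray, min_n: int = 20) -> HeritabilityResult:
    """REML variance components for y = mu + g + e, g ~ N(0, sigma_g K).

    One-dimensional optimization over the variance ratio after projecting
    out the intercept and eigendecomposing the projected kinship; LRT
    against sigma_g = 0 uses the 0.5*chi2(1) boundary mixture.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_n:
        raise HerbclockError(f"need >= {min_n} accessions, got {n}")
    if K.shape != (n, n):
        raise HerbclockError("kinship dimension mismatch")
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8:
        warnings.warn("kinship not PSD; adding ridge")
        K = K + (abs(w.min()) + 1e-8) * np.eye(n)

    # restricted transform: eigenvectors of S(K+I)S with S projecting out 1
    S = np.eye(n) - np.ones((n, n)) / n
    vals, vecs = np.linalg.eigh(S @ (K + np.eye(n)) @ S)
    order = np.argsort(vals)[::-1]
    lam = vals[order][: n - 1] - 1.0  # eigenvalues of projected K
    lam = np.maximum(lam, 0.0)
    eta = (vecs[:, order][:, : n - 1].T @ y)
    q = n - 1

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = lam + delta
        rss = np.sum(eta**2 / denom)
        ll = 0.5 * (q * np.log(q / (2 * np.pi)) - q - q * np.log(rss) - np.sum(np.log(denom)))
        return -ll

    grid = np.linspace(-12, 12, 49)
    best = min(grid, key=neg_restricted_ll)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(best - 1.5, best + 1.5), method="bounded"
    )
    delta = float(np.exp(res.x))
    ll = -float(res.fun)
    sigma_g = float(np.sum(eta**2 / (lam + delta)) / q)
    sigma_e = delta * sigma_g
    ll_null = 0.5 * (q * np.log(q / (2 * np.pi)) - q - q * np.log(np.sum(eta**2)))
    lrt = max(0.0, 2 * (ll - ll_null))
    p = 0.5 * stats.chi2.sf(lrt, df=1) if lrt > 0 else 1.0
    h2 = float(np.clip(sigma_g / (sigma_g + sigma_e), 0.0, 1.0)) if sigma_g + sigma_e > 0 else 0.0
    return HeritabilityResult(sigma_g, sigma_e, h2, ll, float(ll_null), float(p))


# ---------------------------------------------------------------------------
# GWA scan and permutation null
# ---------------------------------------------------------------------------

def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M after regression on covariates C."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def _prepare_scan(y, v: VariantTable, covariates, maf_min: float):
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != v.n_samples:
        raise HerbclockError("phenotype length != number of samples")
    X, keep = _imputed_dosages(v, maf_min)
    poly = X.std(axis=1) > 0
    X, keep = X[poly], keep[poly]
    if len(keep) == 0:
        raise HerbclockError("no polymorphic sites pass the MAF filter")
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.hstack([C, cov])
    yr = _residualize(y[:, None], C)[:, 0]
    Xr = _residualize(X.T, C)  # n x m
    dof = n - C.shape[1] - 1
    if dof < 1:
        raise HerbclockError("not enough degrees of freedom for the scan")
    return yr, Xr, keep, dof


def _scan_stats(yr: np.ndarray, Xr: np.ndarray, dof: int):
    """Per-site OLS effect, SE and p from residualized phenotype/genotypes."""
    xnorm2 = (Xr**2).sum(axis=0)
    xnorm2[xnorm2 == 0] = np.nan
    beta = (Xr.T @ yr) / xnorm2
    rss = (yr**2).sum() - beta**2 * xnorm2
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / dof / xnorm2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(tstat), df=dof)
    return beta, se, p


def gwa_scan(y, v: VariantTable, covariates=None, maf_min: float = 0.05) -> pd.DataFrame:
    """Single-SNP OLS scan: y = Xb + e (optionally with fixed covariates)."""
    yr, Xr, keep, dof = _prepare_scan(y, v, covariates, maf_min)
    beta, se, p = _scan_stats(yr, Xr, dof)
    return pd.DataFrame(
        {
            "site_index": keep,
            "chrom": v.sites["chrom"].to_numpy()[keep],
            "pos": v.sites["pos"].to_numpy()[keep],
            "annotation_class": v.sites["annotation_class"].to_numpy()[keep],
            "beta": beta,
            "se": se,
            "p": p,
        }
    )


def permutation_null(y, v: VariantTable, n_perm: int = 1000, seed: int | None = None,
                     covariates=None, maf_min: float = 0.05) -> np.ndarray:
    """p-values from scans of ``n_perm`` permuted phenotypes (sites x perms)."""
    if n_perm < 1:
        raise HerbclockError("n_perm must be >= 1")
    yr, Xr, _, dof = _prepare_scan(y, v, covariates, maf_min)
    rng = np.random.default_rng(seed)
    n = len(yr)
    Yp = np.empty((n, n_perm))
    for k in range(n_perm):
        Yp[:, k] = yr[rng.permutation(n)]
    xnorm2 = (Xr**2).sum(axis=0)
    xnorm2[xnorm2 == 0] = np.nan
    B = (Xr.T @ Yp) / xnorm2[:, None]  # m x n_perm
    yss = (Yp**2).sum(axis=0)
    rss = np.maximum(yss[None, :] - B**2 * xnorm2[:, None], 0.0)
    se = np.sqrt(rss / dof / xnorm2[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, B / se, np.inf)
    return 2 * stats.t.sf(np.abs(tstat), df=dof)


def permutation_threshold(y, v: VariantTable, n_perm: int = 1000, alpha: float = 0.05,
                          seed: int | None = None, covariates=None,
                          maf_min: float = 0.05, mode: str = "pooled",
                          null_p: np.ndarray | None = None) -> float:
    """Raw-p significance threshold from the permutation empirical null.

    ``mode="pooled"`` (default) pools every per-site p across permutations
    and takes the alpha quantile; ``mode="minp"`` takes the alpha quantile
    of per-permutation minimum p (family-wise control).
    """
    if n_perm < 100 and null_p is None:
        raise HerbclockError("n_perm must be >= 100")
    if mode not in ("pooled", "minp"):
        raise HerbclockError(f"unknown mode {mode!r}")
    if null_p is None:
        null_p = permutation_null(y, v, n_perm=n_perm, seed=seed,
                                  covariates=covariates, maf_min=maf_min)
    if mode == "pooled":
        return float(np.quantile(null_p.ravel(), alpha))
    return float(np.quantile(null_p.min(axis=0), alpha))


def double_bonferroni(alpha: float, n_snps: int, n_phenos: int) -> float:
    """alpha / (number of SNPs + number of phenotypes tested)."""
    if n_snps + n_phenos <= 0:
        raise HerbclockError("n_snps + n_phenos must be > 0")
    return alpha / (n_snps + n_phenos)


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

def ld_statistics(v: VariantTable, site_indices=None) -> dict[str, np.ndarray]:
    """Pairwise haplotype-count LD: D, D', r^2 and partner counts at r^2 > 0.5.

    Frequencies are computed per pair over samples non-missing at both
    sites.  Monomorphic pairs get NaN.
    """
    idx = np.asarray(site_indices) if site_indices is not None else np.arange(v.n_sites)
    g = v.calls[idx]
    m = len(idx)
    valid = (g != MISSING)
    G1 = np.where(valid, (g == 1), 0).astype(float)
    V = valid.astype(float)
    nAB = G1 @ G1.T
    nA_ = G1 @ V.T  # site i derived among jointly valid
    n_B = V @ G1.T
    nn = V @ V.T
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = nA_ / nn
        pB = n_B / nn
        pAB = nAB / nn
        D = pAB - pA * pB
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(denom > 0, D**2 / denom, np.nan)
        dmax_pos = np.minimum(pA * (1 - pB), (1 - pA) * pB)
        dmax_neg = np.minimum(pA * pB, (1 - pA) * (1 - pB))
        dmax = np.where(D >= 0, dmax_pos, dmax_neg)
        dprime = np.where((denom > 0) & (dmax > 0), D / dmax, np.nan)
    for arr in (D, r2, dprime):
        np.fill_diagonal(arr, np.nan)
    partners = np.nansum((r2 > 0.5), axis=1).astype(int)
    return {"D": D, "Dprime": dprime, "r2": r2, "partners": partners, "site_indices": idx}


def hit_overlap_enrichment(hits_a, hits_b, universe: int) -> ContingencyResult:
    """Fisher test of joint membership of two hit sets within a universe."""
    if universe <= 0:
        raise HerbclockError("universe must be > 0")
    A, B = set(hits_a), set(hits_b)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = universe - a - b - c
    if d < 0:
        raise HerbclockError("hit sets exceed the universe")
    return fisher_contingency(a, b, c, d, tail="greater", labels=("hits_a", "hits_b"))


# ---------------------------------------------------------------------------
# end-to-end association for one trait
# ---------------------------------------------------------------------------

def associate(y, v: VariantTable, n_perm: int = 1000, alpha: float = 0.05,
              n_phenos: int = 0, seed: int | None = None, covariates=None,
              maf_min: float = 0.05, mode: str = "pooled") -> pd.DataFrame:
    """Scan + permutation empirical p + double-Bonferroni flags + LD partners.

    ``empirical_p`` is the add-one fraction of the pooled permutation null
    at or below each raw p (bounded below by 1/(n_perm x n_snps + 1)).
    """
    scan = gwa_scan(y, v, covariates=covariates, maf_min=maf_min)
    null_p = permutation_null(y, v, n_perm=n_perm, seed=seed,
                              covariates=covariates, maf_min=maf_min)
    thr = permutation_threshold(y, v, alpha=alpha, mode=mode, null_p=null_p, n_perm=n_perm)
    flat = np.sort(null_p.ravel())
    emp = (np.searchsorted(flat, scan["p"].to_numpy(), side="right") + 1) / (len(flat) + 1)
    scan = scan.copy()
    scan["empirical_p"] = emp
    scan["passes_permutation"] = scan["p"] < thr
    bonf = double_bonferroni(alpha, n_snps=len(scan), n_phenos=n_phenos)
    scan["passes_double_bonferroni"] = scan["p"] < bonf
    hit_idx = scan.index[scan["passes_permutation"]].to_numpy()
    partners = np.zeros(len(scan), dtype=int)
    if len(hit_idx) > 1:
        ld = ld_statistics(v, scan["site_index"].to_numpy()[hit_idx])
        partners[hit_idx] = ld["partners"]
    scan["ld_partners"] = partners
    scan.attrs["permutation_threshold"] = thr
    scan.attrs["bonferroni_threshold"] = bonf
    return scan
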