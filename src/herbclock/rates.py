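"""Tip-dated substitution-rate estimation and TMRCA dating.

The core estimator regresses net genetic distances on collection-time
deltas.  For a modern sample i and herbarium sample j, the net distance is
``D'_ij = D_ic - D_jc`` where ``D_ic`` is sample i's derived-allele count
against the lineage pseudo-reference; the slope of ``D' = a + b*T'`` over
pairs (with ``T'_ij = year_i - year_j``) is the genome-wide number of
substitutions per year, and dividing by the accessible genome length gives
the per-site rate.  Confidence intervals come from a percentile bootstrap;
pairs are the default resampling unit, with a sample-level bootstrap behind
``boot_unit="sample"`` because pair resampling does not fully remove the
dependence between pairs sharing a sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import HerbclockError, SampleMeta, VariantTable


@dataclass
class RateEstimate:
    point: float  # substitutions site^-1 per unit (year or generation)
    ci_low: float
    ci_high: float
    n_boot: int
    accessible_bp: float
    method: str  # "net_distance" | "ma_lines"
    intercept: float = float("nan")
    slope: float = float("nan")
    per: str = "year"  # "year" | "generation"

    def __post_init__(self):
        if not (self.ci_low <= self.point <= self.ci_high or
                any(math.isnan(x) for x in (self.ci_low, self.point, self.ci_high))):
            raise HerbclockError("rate CI must bracket the point estimate")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# net-distance pairs and regression
# ---------------------------------------------------------------------------

def net_distance_pairs(v: VariantTable, meta: list[SampleMeta]) -> pd.DataFrame:
    """One row per (modern, herbarium) pair: net distance and time delta.

    Columns: modern_id, herbarium_id, d_prime (signed SNP count),
    t_prime (years), callable_i, callable_j.
    """
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in v.samples if s not in by_id]
    if missing:
        warnings.warn(f"samples without metadata skipped: {missing}")
    modern = [s for s in v.samples if s in by_id and by_id[s].era == "modern"]
    herb = [s for s in v.samples if s in by_id and by_id[s].era == "herbarium"]
    if not modern or not herb:
        raise HerbclockError("need at least one modern and one herbarium sample")

    d = dict(zip(v.samples, v.derived_counts_per_sample()))
    callable_ = dict(zip(v.samples, v.callable_per_sample()))
    rows = [
        (
            i,
            j,
            float(d[i] - d[j]),
            float(by_id[i].year - by_id[j].year),
            int(callable_[i]),
            int(callable_[j]),
        )
        for i in modern
        for j in herb
    ]
    return pd.DataFrame(
        rows, columns=["modern_id", "herbarium_id", "d_prime", "t_prime", "callable_i", "callable_j"]
    )


def _ols_slope(t: np.ndarray, dp: np.ndarray) -> tuple[float, float]:
    tbar, dbar = t.mean(), dp.mean()
    sxx = float(((t - tbar) ** 2).sum())
    if sxx == 0:
        return float("nan"), float("nan")
    b = float(((t - tbar) * (dp - dbar)).sum() / sxx)
    return b, float(dbar - b * tbar)


def fit_rate(pairs: pd.DataFrame, accessible_bp: float, n_boot: int = 1000,
             seed: int | None = None, boot_unit: str = "pair") -> RateEstimate:
    """OLS slope of D' on T', scaled to a per-site rate, with bootstrap CI."""
    if accessible_bp <= 0:
        raise HerbclockError("accessible_bp must be > 0")
    if boot_unit not in ("pair", "sample"):
        raise HerbclockError(f"unknown boot_unit {boot_unit!r}")
    t = pairs["t_prime"].to_numpy(float)
    dp = pairs["d_prime"].to_numpy(float)
    if len(np.unique(t)) < 2:
        raise HerbclockError("all time deltas identical: slope undefined")

    b, a = _ols_slope(t, dp)
    rate = b / accessible_bp
    rng = np.random.default_rng(seed)

    if boot_unit == "pair":
        n = len(pairs)
        idx = rng.integers(0, n, size=(n_boot, n))
        tb, db = t[idx], dp[idx]
    else:
        # resample samples, not pairs: rebuild the modern x herbarium grid
        # from per-sample year/derived-count vectors
        piv_t = pairs.pivot(index="modern_id", columns="herbarium_id", values="t_prime")
        piv_d = pairs.pivot(index="modern_id", columns="herbarium_id", values="d_prime")
        nm_, nh_ = piv_t.shape
        tm = piv_t.to_numpy()
        dm = piv_d.to_numpy()
        mi = rng.integers(0, nm_, size=(n_boot, nm_))
        hj = rng.integers(0, nh_, size=(n_boot, nh_))
        tb = np.stack([tm[np.ix_(mi[k], hj[k])].ravel() for k in range(n_boot)])
        db = np.stack([dm[np.ix_(mi[k], hj[k])].ravel() for k in range(n_boot)])
    tc = tb - tb.mean(axis=1, keepdims=True)
    dc = db - db.mean(axis=1, keepdims=True)
    sxx = (tc**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = (tc * dc).sum(axis=1) / sxx
    boots = boots[np.isfinite(boots)]
    if len(boots):
        lo, hi = np.percentile(boots, [2.5, 97.5]) / accessible_bp
        lo, hi = min(lo, rate), max(hi, rate)
    else:
        lo = hi = rate
    return RateEstimate(rate, float(lo), float(hi), n_boot, accessible_bp,
                        "net_distance", intercept=a, slope=b)


def stratify_rates(v: VariantTable, meta: list[SampleMeta], classes: list[str],
                   n_boot: int = 1000, seed: int | None = None) -> dict[str, RateEstimate]:
    """Per-annotation-class net-distance rates, scaled by class accessible bp."""
    out: dict[str, RateEstimate] = {}
    for k, cls in enumerate(classes):
        bp = v.accessible_length.get(cls, 0)
        if not bp:
            warnings.warn(f"class {cls!r} has no accessible length; skipped")
            continue
        sub = v.subset_sites((v.sites["annotation_class"] == cls).to_numpy())
        pairs = net_distance_pairs(sub, meta)
        out[cls] = fit_rate(pairs, bp, n_boot=n_boot,
                            seed=None if seed is None else seed + k)
    return out


def per_generation_rate(r: RateEstimate, generation_time_years: float = 1.3) -> RateEstimate:
    """Rescale a per-year rate to per-generation by the mean generation time."""
    if generation_time_years <= 0:
        raise HerbclockError("generation_time_years must be > 0")
    g = generation_time_years
    return RateEstimate(r.point * g, r.ci_low * g, r.ci_high * g, r.n_boot,
                        r.accessible_bp, r.method, intercept=r.intercept,
                        slope=r.slope, per="generation")


def estimate_tmrca(mean_pairwise_d_per_site: float, mu: float,
                   mean_collection_year: float) -> tuple[float, float]:
    """Solve d = 2*L*mu for the lineage age L; root year = mean year - L."""
    if mu <= 0:
        raise HerbclockError("mu must be > 0")
    if mean_pairwise_d_per_site < 0:
        raise HerbclockError("mean pairwise distance must be >= 0")
    L = mean_pairwise_d_per_site / (2.0 * mu)
    return L, mean_collection_year - L


def mean_pairwise_distance_per_site(v: VariantTable, accessible_bp: float | None = None,
                                    sample_ids: list[str] | None = None) -> float:
    """Average over all unordered sample pairs of per-site SNP distance.

    Missing data is corrected by scaling each pair's raw difference count by
    total sites / jointly-callable sites before dividing by the accessible
    length.
    """
    from .lineage_qc import pairwise_distance_matrix

    sub = v.subset_samples(sample_ids) if sample_ids else v
    L = accessible_bp if accessible_bp is not None else sub.accessible_length.get("total")
    if not L:
        raise HerbclockError("accessible_bp unavailable")
    pd_ = pairwise_distance_matrix(sub)
    n = len(pd_.samples)
    iu = np.triu_indices(n, k=1)
    dist = pd_.distances[iu]
    joint = pd_.callable_counts[iu].astype(float)
    ok = np.isfinite(dist) & (joint > 0)
    corrected = dist[ok] * (sub.n_sites / joint[ok])
    return float(corrected.mean() / L) if len(corrected) else 0.0


# ---------------------------------------------------------------------------
# mutation-accumulation lines
# ---------------------------------------------------------------------------

def ma_mutation_rate(counts, generations, callable_bp, n_boot: int = 1000,
                     seed: int | None = None) -> RateEstimate:
    """Pooled MA-line rate: sum(counts) / sum(generations x callable bp).

    CI by percentile bootstrap over lines; a single line falls back to the
    exact Poisson (chi-square) interval.
    """
    counts = np.atleast_1d(np.asarray(counts, dtype=float))
    generations = np.broadcast_to(np.asarray(generations, dtype=float), counts.shape).copy()
    callable_bp = np.broadcast_to(np.asarray(callable_bp, dtype=float), counts.shape).copy()
    if (generations <= 0).any() or (callable_bp <= 0).any():
        raise HerbclockError("generations and callable_bp must be positive")
    exposure = generations * callable_bp
    rate = float(counts.sum() / exposure.sum())

    if len(counts) == 1:
        c = counts[0]
        lo = stats.chi2.ppf(0.025, 2 * c) / 2 if c > 0 else 0.0
        hi = stats.chi2.ppf(0.975, 2 * (c + 1)) / 2
        return RateEstimate(rate, float(lo / exposure[0]), float(hi / exposure[0]),
                            0, float(callable_bp[0]), "ma_lines", per="generation")

    rng = np.random.default_rng(seed)
    n = len(counts)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = counts[idx].sum(axis=1) / exposure[idx].sum(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(float(lo), rate), max(float(hi), rate)
    return RateEstimate(rate, lo, hi, n_boot, float(callable_bp.mean()),
                        "ma_lines", per="generation")
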