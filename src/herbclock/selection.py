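"""Purifying-selection inference: contingency tests and bootstrap KS.

Three complementary signals:

- bp-vs-SNP contingency (`annotation_depletion_test`): are there fewer SNPs
  in one class than its accessible length predicts?
- frequency-class contingency (`frequency_class_test`): are one class's
  variants enriched below the 5% frequency cutoff?  Frequencies exactly at
  the cutoff count as intermediate.
- full-spectrum shift (`sfs_ks_test`): two-sample Kolmogorov-Smirnov with a
  pooled-bootstrap p-value, which handles the heavy ties in discrete
  frequency data that invalidate the asymptotic formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diversity import SFSBundle
from .io_core import HerbclockError, VariantTable


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    tail: str  # "less" | "greater"
    labels: tuple[str, str]
    haldane_corrected: bool = False


def fisher_contingency(a: int, b: int, c: int, d: int, tail: str,
                       labels: tuple[str, str] = ("A", "B")) -> ContingencyResult:
    """One-tailed Fisher's exact test on [[a, b], [c, d]].

    OR = (a/b)/(c/d); cells get a Haldane +0.5 only when a zero cell would
    make the ratio undefined (flagged in the result).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise HerbclockError("contingency cells must be nonnegative integers")
    if tail not in ("less", "greater"):
        raise HerbclockError(f"tail must be 'less' or 'greater', got {tail!r}")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise HerbclockError("contingency table has an all-zero margin")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=tail)
    haldane = 0 in (a, b, c, d)
    if haldane:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    orr = (aa / bb) / (cc / dd)
    return ContingencyResult(((int(a), int(b)), (int(c), int(d))), float(orr),
                             float(p), tail, labels, haldane)


def annotation_depletion_test(v: VariantTable, class_a: str, class_b: str,
                              accessible: dict[str, float] | None = None) -> ContingencyResult:
    """bp-vs-SNP contingency, one-tailed toward depletion of ``class_a``.

    Table: [[SNPs_a, bp_a - SNPs_a], [SNPs_b, bp_b - SNPs_b]] using accessible
    (callable) bp per class; OR < 1 means class_a is SNP-depleted.
    """
    acc = accessible or v.accessible_length
    cls = v.sites["annotation_class"]

    def snps(c: str) -> int:
        if c == "noncoding":
            return int((cls != "coding").sum())
        return int((cls == c).sum())

    def bp(c: str) -> float:
        if c == "noncoding":
            total = acc.get("total")
            coding = acc.get("coding", 0)
            if total is None:
                raise HerbclockError("total accessible length needed for 'noncoding'")
            return total - coding
        if c not in acc or not acc[c]:
            raise HerbclockError(f"class {c!r} has no accessible length")
        return acc[c]

    sa, sb = snps(class_a), snps(class_b)
    ba, bb_ = bp(class_a), bp(class_b)
    return fisher_contingency(sa, int(ba) - sa, sb, int(bb_) - sb,
                              tail="less", labels=(class_a, class_b))


def frequency_class_test(sfs: SFSBundle, class_a: str, class_b: str,
                         cutoff: float = 0.05) -> ContingencyResult:
    """Low (< cutoff) vs intermediate (>= cutoff) frequency contingency.

    One-tailed toward low-frequency enrichment of ``class_a`` (OR > 1 means
    class_a variants sit at low frequency more often than class_b's).
    """
    fa = sfs.class_frequencies(class_a)
    fb = sfs.class_frequencies(class_b)
    if len(fa) == 0 or len(fb) == 0:
        raise HerbclockError(
            f"no sites in class {class_a if len(fa) == 0 else class_b!r}; "
            "check annotation classes"
        )
    low_a = int((fa < cutoff).sum())
    low_b = int((fb < cutoff).sum())
    return fisher_contingency(low_a, len(fa) - low_a, low_b, len(fb) - low_b,
                              tail="greater", labels=(class_a, class_b))


def sfs_ks_test(freqs_a, freqs_b, n_boot: int = 10000,
                seed: int | None = None) -> tuple[float, float]:
    """Two-sample KS D with a pooled-bootstrap p-value.

    Under H0 both samples come from the pooled distribution; ``n_boot``
    resamples of the two sample sizes give the null distribution of D.  The
    p-value uses the add-one estimator (1 + #{D* >= D}) / (n_boot + 1).
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise HerbclockError("both frequency lists must be non-empty")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse p-value")
    d_obs = float(stats.ks_2samp(a, b, method="asymp").statistic)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a, n_b = len(a), len(b)
    exceed = 0
    for _ in range(n_boot):
        ra = pooled[rng.integers(0, len(pooled), size=n_a)]
        rb = pooled[rng.integers(0, len(pooled), size=n_b)]
        if _ks_stat(ra, rb) >= d_obs - 1e-15:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return d_obs, float(p)


def _ks_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic via searchsorted (fast path for the bootstrap)."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / len(a)
    cdf_b = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.abs(cdf_a - cdf_b).max())
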