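"""Diversity statistics and the first-appearance-oriented unfolded SFS."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MISSING, HerbclockError, SampleMeta, VariantTable


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's estimator per site: S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if n < 2:
        raise HerbclockError("need n >= 2 samples")
    if L <= 0:
        raise HerbclockError("L must be > 0")
    if S == 0:
        return 0.0
    a_n = np.sum(1.0 / np.arange(1, n))
    return float(S / (a_n * L))


def nucleotide_diversity(v: VariantTable, L: float) -> float:
    """pi per site: mean pairwise difference over jointly-callable sites / L.

    With missing data each pair's raw difference count is scaled by
    total sites / jointly-callable sites before averaging, matching the
    accessible-length rescaling convention used for Watterson's theta.
    """
    from .lineage_qc import pairwise_distance_matrix

    if v.n_samples < 2:
        raise HerbclockError("need >= 2 samples")
    if L <= 0:
        raise HerbclockError("L must be > 0")
    if v.n_sites == 0:
        return 0.0
    d = pairwise_distance_matrix(v)
    n = v.n_samples
    iu = np.triu_indices(n, k=1)
    dist = d.distances[iu]
    joint = d.callable_counts[iu].astype(float)
    ok = np.isfinite(dist) & (joint > 0)
    if not ok.any():
        return 0.0
    corrected = dist[ok] * (v.n_sites / joint[ok])
    return float(corrected.mean() / L)


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(v: VariantTable) -> float:
    """Tajima's (1989) D from the variant matrix.

    pi is accumulated per site from allele counts among non-missing calls
    (unbiased 2*c1*c0/(m*(m-1)) form); the normalizing constants use the
    panel size n, the standard approximation under modest missingness.
    """
    n = v.n_samples
    if n < 4:
        raise HerbclockError("need n >= 4 samples for Tajima's D")
    der, nm = v.derived_freqs()
    seg = (der > 0) & (der < nm)
    S = int(seg.sum())
    if S == 0:
        raise HerbclockError("no segregating sites: D undefined")
    m = nm[seg].astype(float)
    c1 = der[seg].astype(float)
    c0 = m - c1
    pi = float(np.sum(2.0 * c1 * c0 / (m * (m - 1))))
    k = _tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi - theta_w) / np.sqrt(var))


# ---------------------------------------------------------------------------
# unfolded SFS oriented by order of appearance in dated samples
# ---------------------------------------------------------------------------

@dataclass
class SFSBundle:
    """Per-class unfolded spectra with orientation provenance.

    ``derived_counts``/``frequencies``/``n_used`` are aligned with the
    (filtered) site order in ``site_index``; ``flipped`` marks sites where
    the earliest herbarium call carried the VCF ALT allele and orientation
    was inverted; ``fallback`` marks sites unseen in any herbarium sample,
    where the pseudo-reference allele was taken as ancestral.
    """

    site_index: np.ndarray
    derived_counts: np.ndarray
    frequencies: np.ndarray
    n_used: np.ndarray
    annotation_class: np.ndarray
    flipped: np.ndarray
    fallback: np.ndarray
    orientation: str = "herbarium_first_appearance"

    def class_frequencies(self, cls: str) -> np.ndarray:
        if cls == "noncoding":
            mask = self.annotation_class != "coding"
        else:
            mask = self.annotation_class == cls
        return self.frequencies[mask]

    def spectrum(self, n_bins: int | None = None) -> np.ndarray:
        """Histogram of derived counts (1..max)."""
        top = n_bins or int(self.derived_counts.max(initial=1))
        return np.bincount(self.derived_counts, minlength=top + 1)[1:top + 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_index": self.site_index,
                "annotation_class": self.annotation_class,
                "derived_count": self.derived_counts,
                "n_used": self.n_used,
                "frequency": self.frequencies,
                "flipped": self.flipped,
                "fallback": self.fallback,
            }
        )


def unfolded_sfs(v: VariantTable, meta: list[SampleMeta],
                 min_call_rate: float = 0.8) -> SFSBundle:
    """Orient each site by its earliest-dated non-missing herbarium call.

    The ancestral allele at a site is the allele carried by the
    earliest-dated herbarium sample(s) with a call there; ties across the
    equally-old samples are broken by majority, then by the
    pseudo-reference (REF) allele.  Sites unseen in every herbarium sample
    fall back to REF = ancestral and are flagged.  Sites genotyped in fewer
    than ``min_call_rate`` of samples are excluded.
    """
    by_id = {m.sample_id: m for m in meta}
    herb_idx = [k for k, s in enumerate(v.samples)
                if s in by_id and by_id[s].era == "herbarium"]
    if not herb_idx:
        raise HerbclockError("no dated herbarium samples available for orientation")
    herb_years = np.array([by_id[v.samples[k]].year for k in herb_idx])

    der, nm = v.derived_freqs()
    keep = nm >= min_call_rate * v.n_samples
    if not keep.any():
        warnings.warn("no sites pass the genotyping-rate filter")

    idx = np.flatnonzero(keep)
    counts = np.empty(len(idx), dtype=np.int64)
    n_used = np.empty(len(idx), dtype=np.int64)
    flipped = np.zeros(len(idx), dtype=bool)
    fallback = np.zeros(len(idx), dtype=bool)

    herb_calls = v.calls[:, herb_idx]
    for out_i, site in enumerate(idx):
        row = herb_calls[site]
        seen = row != MISSING
        if not seen.any():
            ancestral = 0
            fallback[out_i] = True
        else:
            earliest = herb_years[seen].min()
            tied = seen & (herb_years == earliest)
            vals = row[tied]
            n1 = int((vals == 1).sum())
            n0 = int((vals == 0).sum())
            ancestral = 1 if n1 > n0 else 0  # majority; tie -> REF allele
        full = v.calls[site]
        nonmiss = full != MISSING
        n_used[out_i] = int(nonmiss.sum())
        derived = int(((full != ancestral) & nonmiss).sum())
        counts[out_i] = derived
        flipped[out_i] = ancestral == 1

    freqs = np.where(n_used > 0, counts / n_used, 0.0)
    return SFSBundle(
        site_index=idx,
        derived_counts=counts,
        frequencies=freqs,
        n_used=n_used,
        annotation_class=v.sites["annotation_class"].to_numpy()[idx],
        flipped=flipped,
        fallback=fallback,
    )


def diversity_summary(v: VariantTable, L: float | None = None) -> dict[str, float]:
    """S, Watterson's theta, pi and Tajima's D in one report-friendly dict."""
    L = L if L is not None else v.accessible_length.get("total")
    if not L:
        raise HerbclockError("accessible length unavailable")
    der, nm = v.derived_freqs()
    S = int(((der > 0) & (der < nm)).sum())
    out = {
        "n_samples": v.n_samples,
        "segregating_sites": S,
        "theta_w": watterson_theta(S, v.n_samples, L),
        "pi": nucleotide_diversity(v, L),
    }
    out["tajimas_d"] = tajimas_d(v) if S > 0 else float("nan")
    return out
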