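"""Quasi-clonality checks: distances, NJ tree, four-gamete screen, identity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .io_core import MISSING, HerbclockError, SampleMeta, VariantTable


@dataclass
class PairwiseDistances:
    """SNP-count distance matrix with jointly-callable companion counts.

    ``distances[i, j]`` is NaN where no site is callable in both samples
    (undefined, not zero).
    """

    distances: np.ndarray
    callable_counts: np.ndarray
    samples: list[str]
    eras: dict[str, str] | None = None

    def pair_category(self, i: int, j: int) -> str:
        if self.eras is None:
            return "unknown"
        a, b = sorted((self.eras[self.samples[i]], self.eras[self.samples[j]]))
        return f"{a}-{b}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.samples, columns=self.samples)


def pairwise_distance_matrix(v: VariantTable,
                             meta: list[SampleMeta] | None = None) -> PairwiseDistances:
    """Count sites at which both calls are non-missing and differ, per pair."""
    if v.n_samples < 2:
        raise HerbclockError("need at least two samples for pairwise distances")
    a1 = (v.calls == 1).astype(np.int64)
    a0 = (v.calls == 0).astype(np.int64)
    nm = (v.calls != MISSING).astype(np.int64)
    diff = a1.T @ a0 + a0.T @ a1
    joint = nm.T @ nm
    dist = diff.astype(float)
    dist[joint == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(dist, np.where(np.diag(joint) == 0, np.nan, 0.0))
    eras = {m.sample_id: m.era for m in meta} if meta else None
    return PairwiseDistances(dist, joint, list(v.samples), eras)


def nj_tree(d: PairwiseDistances) -> str:
    """Neighbor-joining tree as a Newick string (scikit-bio agglomeration)."""
    if np.isnan(d.distances).any():
        bad = [
            (d.samples[i], d.samples[j])
            for i, j in zip(*np.where(np.isnan(d.distances)))
            if i < j
        ]
        raise HerbclockError(f"undefined distances for pairs: {bad[:5]}")
    dm = DistanceMatrix(d.distances, ids=d.samples)
    tree = _skbio_nj(dm)
    return str(tree).strip()


def four_gamete_screen(v: VariantTable, maf_min: float | None = None,
                       min_minor_count: int = 2, max_removals: int = 10
                       ) -> tuple[int, list[str]]:
    """Count site pairs showing all four gametes; greedily flag recombinants.

    Singleton sites are excluded by default (``min_minor_count=2``): a
    singleton cannot complete a four-gamete violation on its own but inflates
    the pair count.  Flagging iteratively removes the sample whose removal
    most reduces the incompatible-pair count, until none remain or
    ``max_removals`` is hit; the returned count is for the full sample set.
    """
    der, nm = v.derived_freqs()
    minor = np.minimum(der, nm - der)
    keep = minor >= min_minor_count
    if maf_min is not None:
        with np.errstate(invalid="ignore"):
            freq = np.where(nm > 0, der / nm, 0.0)
        keep &= np.minimum(freq, 1 - freq) >= maf_min
    g = v.calls[keep]
    if g.shape[0] < 2:
        return 0, []

    sample_idx = np.arange(v.n_samples)

    def count_incompatible(cols: np.ndarray) -> int:
        sub = g[:, cols]
        b1 = (sub == 1).astype(np.int64)
        b0 = (sub == 0).astype(np.int64)
        n11 = b1 @ b1.T
        n10 = b1 @ b0.T
        n01 = b0 @ b1.T
        n00 = b0 @ b0.T
        bad = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
        return int(np.triu(bad, k=1).sum())

    total = count_incompatible(sample_idx)
    flagged: list[str] = []
    cols = sample_idx.copy()
    current = total
    while current > 0 and len(flagged) < max_removals:
        best_count, best_col = current, None
        for c in cols:
            trial = cols[cols != c]
            k = count_incompatible(trial)
            if k < best_count:
                best_count, best_col = k, c
        if best_col is None:
            break  # no single removal helps
        flagged.append(v.samples[int(best_col)])
        cols = cols[cols != best_col]
        current = best_count
    return total, flagged


def identity_summary(d: PairwiseDistances, accessible_bp: int) -> float:
    """Minimum pairwise percent identity: 100 x (1 - max distance / accessible bp)."""
    if accessible_bp <= 0:
        raise HerbclockError("accessible_bp must be > 0")
    dmax = np.nanmax(d.distances) if np.isfinite(d.distances).any() else 0.0
    return 100.0 * (1.0 - dmax / accessible_bp)
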