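"""Dated selfing-lineage simulator.

Generates genotype matrices with the structure the downstream estimators
assume: a founder genome at ``founder_year``, samples collected at known
years, mutations dropped as Poisson processes along genealogy branches
(counts ~ Poisson(mu x branch-years x accessible bp)), positions placed
uniformly within annotation-class blocks, coding mutations thinned by a
retention probability to mimic purifying selection, and era-dependent
missingness.  Truth needed to score any estimator is recorded in
:class:`SimTruth`.

Three genealogy modes:

- ``star``: every sample is an independent branch founder->collection year.
- ``coalescent``: Kingman coalescent with exponential growth (backwards
  shrinking population), node heights rescaled so the root sits at the
  founder year.  Large growth rates give star-like trees with excess
  singletons.
- ``forward_wf``: a small forward-in-time selfing Wright-Fisher population
  with seed-bank generation intervals (shifted geometric, mean =
  ``generation_time_years``) and viability selection against coding
  mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_core import (
    MISSING,
    HerbclockError,
    PhenotypeTable,
    SampleMeta,
    VariantTable,
)

_DEFAULT_LENGTHS = {"coding": 2.0e7, "intronic": 1.0e7, "intergenic": 7.8e7}

MUTATION_CAP = 5_000_000


@dataclass
class SimConfig:
    seed: int = 0
    founder_year: int = 1600
    sample_years: list[tuple[int, str]] = field(default_factory=list)  # (year, era)
    mu_per_site_year: float = 2.11e-9
    accessible_length: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_LENGTHS))
    genealogy: str = "star"  # star | coalescent | forward_wf
    selection_coding: float = 1.0
    generation_time_years: float = 1.3
    missing_rate_herbarium: float = 0.0
    missing_rate_modern: float = 0.0
    n_causal: int = 10
    target_h2: float = 0.5
    growth_rate: float = 10.0  # coalescent mode: star-likeness knob
    wf_pop_size: int = 100  # forward_wf mode
    n_replicates: int = 3
    replicate_noise_sd: float = 0.0

    def __post_init__(self):
        if self.mu_per_site_year < 0:
            raise HerbclockError("mu_per_site_year must be >= 0")
        if not (0 < self.selection_coding <= 1):
            raise HerbclockError("selection_coding must be in (0, 1]")
        if self.generation_time_years <= 0:
            raise HerbclockError("generation_time_years must be > 0")
        if self.sample_years and self.founder_year >= min(y for y, _ in self.sample_years):
            raise HerbclockError("founder_year must precede all sample years")
        if any(L < 0 for L in self.accessible_length.values()):
            raise HerbclockError("accessible lengths must be nonnegative")
        if self.genealogy not in ("star", "coalescent", "forward_wf"):
            raise HerbclockError(f"unknown genealogy {self.genealogy!r}")


@dataclass
class SimTruth:
    """Ground truth recorded alongside each simulated dataset."""

    true_rate: float = 0.0
    branch_years: dict[str, float] = field(default_factory=dict)  # root-to-tip, per sample
    per_class_counts: dict[str, int] = field(default_factory=dict)
    founder_year: int = 0
    causal_sites: list[int] = field(default_factory=list)
    causal_betas: list[float] = field(default_factory=list)
    realized_h2: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def historical_sampling_years(n_herbarium: int = 27, n_modern: int = 73,
                    herbarium_span: tuple[int, int] = (1863, 1993),
                    modern_span: tuple[int, int] = (1993, 2006)) -> list[tuple[int, str]]:
    """Collection-year layout mimicking a ~100-sample 1863-2006 collection."""
    hy = np.linspace(herbarium_span[0], herbarium_span[1], n_herbarium).round().astype(int)
    my = np.linspace(modern_span[0], modern_span[1], n_modern).round().astype(int)
    return [(int(y), "herbarium") for y in hy] + [(int(y), "modern") for y in my]


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

class _GenomeLayout:
    """Annotation classes laid out as contiguous blocks on one chromosome."""

    def __init__(self, lengths: dict[str, float]):
        self.classes = [c for c, L in lengths.items() if c != "total" and L > 0]
        self.lengths = np.array([lengths[c] for c in self.classes], dtype=float)
        self.total = float(self.lengths.sum())
        self.offsets = np.concatenate([[0.0], np.cumsum(self.lengths)])

    def draw_positions(self, n: int, rng: np.random.Generator,
                       used: set[int]) -> tuple[np.ndarray, list[str]]:
        """Unique 1-based positions, uniform over the genome (infinite sites)."""
        pos: list[int] = []
        while len(pos) < n:
            draw = rng.integers(1, int(self.total) + 1, size=n - len(pos))
            for p in np.unique(draw):
                p = int(p)
                if p not in used:
                    used.add(p)
                    pos.append(p)
        pos_arr = np.array(pos[:n], dtype=np.int64)
        j = np.clip(np.searchsorted(self.offsets, pos_arr, side="left") - 1,
                    0, len(self.classes) - 1)
        cls = [self.classes[int(k)] for k in j]
        return pos_arr, cls


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------

def _kingman_tree(n: int, growth: float, rng: np.random.Generator):
    """Kingman coalescent under exponential growth, N(t) = N0*exp(-growth*t)
    backwards with N0 = exp(growth).

    With this scaling the population collapses around scaled time ~1, so
    larger ``growth`` compresses coalescences towards the root and yields
    star-like trees (long terminal branches, excess singletons); growth = 0
    is the constant-size neutral coalescent.  Returns (parent, node_time)
    arrays over 2n-1 nodes; tips are 0..n-1 at time 0, times increase
    towards the root.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        pairs = k * (k - 1) / 2.0
        e = rng.exponential()
        if growth > 0:
            # hazard pairs*exp(growth*(t-1)); invert cumulative hazard analytically
            t = 1.0 + np.log(np.exp(growth * (t - 1.0)) + growth * e / pairs) / growth
        else:
            t = t + e / pairs
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return parent, time


_ROOT_HEIGHT_CACHE: dict[tuple[int, float], float] = {}


def _expected_root_height(n: int, growth: float, n_reps: int = 300) -> float:
    """Mean root height of the growth coalescent (closed form at growth = 0).

    Scaling trees by the expected rather than the realized root height keeps
    the unconditional tree shape (and so the neutral 1/i SFS) intact while
    still putting the root at the founder year on average.
    """
    if growth == 0:
        return 2.0 * (1.0 - 1.0 / n)
    key = (n, float(growth))
    if key not in _ROOT_HEIGHT_CACHE:
        rng = np.random.default_rng(987654321)
        heights = [_kingman_tree(n, growth, rng)[1][2 * n - 2] for _ in range(n_reps)]
        _ROOT_HEIGHT_CACHE[key] = float(np.mean(heights))
    return _ROOT_HEIGHT_CACHE[key]


def _tip_descendants(parent: np.ndarray, n_tips: int) -> list[list[int]]:
    """For each node, the tip indices below it."""
    n_nodes = len(parent)
    desc = [[] for _ in range(n_nodes)]
    for tip in range(n_tips):
        node = tip
        while node != -1:
            desc[node].append(tip)
            node = parent[node]
    return desc


# ---------------------------------------------------------------------------
# lineage simulation
# ---------------------------------------------------------------------------

def simulate_lineage(config: SimConfig) -> tuple[VariantTable, list[SampleMeta], SimTruth]:
    """Simulate dated genotypes for one quasi-clonal selfing lineage."""
    if not config.sample_years:
        raise HerbclockError("config.sample_years is empty")
    rng = np.random.default_rng(config.seed)
    layout = _GenomeLayout(config.accessible_length)
    mu, L = config.mu_per_site_year, layout.total
    years = np.array([y for y, _ in config.sample_years], dtype=float)
    eras = [e for _, e in config.sample_years]
    n = len(years)

    # branches as (years, member tip indices)
    if config.genealogy == "star":
        branches = [(float(years[i] - config.founder_year), [i]) for i in range(n)]
        branch_years = {i: float(years[i] - config.founder_year) for i in range(n)}
    elif config.genealogy == "coalescent":
        parent, time = _kingman_tree(n, config.growth_rate, rng)
        desc = _tip_descendants(parent, n)
        span = float(years.max() - config.founder_year)
        scale = span / _expected_root_height(n, config.growth_rate)
        # scaled node heights in years above the newest tip's year-axis
        h = time * scale
        branches = []
        for node in range(len(parent) - 1):  # root has no parent branch
            blen = h[parent[node]] - h[node]
            if node < n:  # stretch/shrink terminals to honour tip dates
                blen += years[node] - years.max()
            blen = max(blen, 0.0)
            branches.append((float(blen), desc[node]))
        branch_years = {
            i: float(sum(b for b, d in branches if i in d)) for i in range(n)
        }
    else:  # forward_wf
        return _simulate_forward_wf(config, rng, layout)

    total_branch_years = sum(b for b, _ in branches)
    if mu * L * total_branch_years > MUTATION_CAP:
        raise HerbclockError(
            f"expected mutation count {mu * L * total_branch_years:.3g} exceeds cap {MUTATION_CAP}"
        )

    counts = rng.poisson(np.array([mu * L * b for b, _ in branches]))
    used: set[int] = set()
    pos_all, cls_all, members_all = [], [], []
    per_class = {c: 0 for c in layout.classes}
    for (blen, members), m in zip(branches, counts):
        if m == 0:
            continue
        pos, cls = layout.draw_positions(int(m), rng, used)
        for p, c in zip(pos, cls):
            per_class[c] = per_class.get(c, 0) + 1
            if c == "coding" and config.selection_coding < 1.0:
                if rng.random() >= config.selection_coding:
                    per_class[c] -= 1
                    continue
            pos_all.append(p)
            cls_all.append(c)
            members_all.append(members)

    v, meta = _assemble(config, rng, pos_all, cls_all, members_all, years, eras, layout)
    truth = SimTruth(
        true_rate=mu,
        branch_years={meta[i].sample_id: branch_years[i] for i in range(n)},
        per_class_counts={c: int(k) for c, k in per_class.items()},
        founder_year=config.founder_year,
    )
    return v, meta, truth


def _assemble(config, rng, pos_all, cls_all, members_all, years, eras, layout):
    n = len(years)
    ids = [f"{'H' if eras[i] == 'herbarium' else 'M'}{i:03d}" for i in range(n)]
    meta = [
        SampleMeta(
            ids[i],
            int(years[i]),
            float(np.round(38 + 10 * rng.random(), 4)),
            float(np.round(-90 + 20 * rng.random(), 4)),
            eras[i],
        )
        for i in range(n)
    ]
    S = len(pos_all)
    calls = np.zeros((S, n), dtype=np.int8)
    for row, members in enumerate(members_all):
        calls[row, members] = 1

    miss = np.array(
        [config.missing_rate_herbarium if e == "herbarium" else config.missing_rate_modern
         for e in eras]
    )
    if miss.any():
        calls[rng.random(calls.shape) < miss[None, :]] = MISSING

    keep = (calls != MISSING).any(axis=1)
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.array(pos_all, dtype=np.int64),
            "anc": "A",
            "der": "T",
            "annotation_class": cls_all,
        }
    )
    acc = {c: float(config.accessible_length[c]) for c in layout.classes}
    acc["total"] = layout.total
    v = VariantTable(sites, calls, ids, acc).subset_sites(keep).sorted()
    return v, meta


def _simulate_forward_wf(config: SimConfig, rng: np.random.Generator, layout: _GenomeLayout):
    """Forward selfing Wright-Fisher with seed-bank generation intervals."""
    N = config.wf_pop_size
    mu, L = config.mu_per_site_year, layout.total
    s = 1.0 - config.selection_coding
    p_gen = min(1.0, 1.0 / config.generation_time_years)  # shifted geometric, mean = gt
    years = np.array([y for y, _ in config.sample_years], dtype=float)
    eras = [e for _, e in config.sample_years]
    order = np.argsort(years)

    genomes: list[frozenset[int]] = [frozenset() for _ in range(N)]
    mut_class: dict[int, str] = {}
    used: set[int] = set()
    t = float(config.founder_year)
    next_id = 0
    sampled: dict[int, frozenset[int]] = {}
    sample_queue = list(order)

    max_year = years.max()
    while t <= max_year:
        # record samples whose collection year has been reached
        while sample_queue and years[sample_queue[0]] <= t:
            i = sample_queue.pop(0)
            sampled[i] = genomes[int(rng.integers(N))]
        if t >= max_year:
            break
        interval = float(rng.geometric(p_gen))  # years until next generation
        t = min(t + interval, max_year + 0.0)
        fitness = np.array(
            [
                (1.0 - s) ** sum(1 for m in g if mut_class[m] == "coding") if s > 0 else 1.0
                for g in genomes
            ]
        )
        w = fitness / fitness.sum()
        parents = rng.choice(N, size=N, p=w)
        new_genomes = []
        n_new = rng.poisson(mu * interval * L, size=N)
        for k in range(N):
            g = set(genomes[parents[k]])
            if n_new[k]:
                pos, cls = layout.draw_positions(int(n_new[k]), rng, used)
                for p, c in zip(pos, cls):
                    mut_class[p] = c
                    g.add(int(p))
            new_genomes.append(frozenset(g))
        genomes = new_genomes
        next_id += 1
    for i in sample_queue:
        sampled[i] = genomes[int(rng.integers(N))]

    segregating = sorted(set().union(*sampled.values())) if sampled else []
    pos_all = list(segregating)
    cls_all = [mut_class[p] for p in pos_all]
    members_all = [[i for i in range(len(years)) if p in sampled[i]] for p in pos_all]
    v, meta = _assemble(config, rng, pos_all, cls_all, members_all, years, eras, layout)
    per_class = {}
    for c in cls_all:
        per_class[c] = per_class.get(c, 0) + 1
    truth = SimTruth(
        true_rate=mu,
        branch_years={meta[i].sample_id: float(years[i] - config.founder_year)
                      for i in range(len(years))},
        per_class_counts=per_class,
        founder_year=config.founder_year,
    )
    return v, meta, truth


# ---------------------------------------------------------------------------
# phenotypes, MA lines, climate
# ---------------------------------------------------------------------------

def simulate_phenotypes(v: VariantTable, config: SimConfig,
                        maf_min: float = 0.05, trait: str = "trait1"
                        ) -> tuple[PhenotypeTable, SimTruth]:
    """Additive phenotypes y = sum_k beta_k x_k + eps tuned to ``target_h2``."""
    rng = np.random.default_rng(config.seed + 101)
    der, nm = v.derived_freqs()
    with np.errstate(invalid="ignore"):
        freq = np.where(nm > 0, der / nm, 0.0)
    maf = np.minimum(freq, 1 - freq)
    eligible = np.flatnonzero(maf >= maf_min)
    truth = SimTruth(realized_h2=0.0)

    n = v.n_samples
    if config.target_h2 > 0:
        if len(eligible) < config.n_causal:
            raise HerbclockError(
                f"only {len(eligible)} sites with MAF >= {maf_min}; need {config.n_causal}. "
                "Simulate more diversity (higher mu or longer history) or lower n_causal."
            )
        causal = rng.choice(eligible, size=config.n_causal, replace=False)
        betas = rng.normal(size=config.n_causal)
        X = v.calls[causal].astype(float)
        col_mean = np.where(nm[causal] > 0, der[causal] / nm[causal], 0.0)
        X = np.where(v.calls[causal] == MISSING, col_mean[:, None], X)
        g = X.T @ betas
        var_g = float(np.var(g))
        if var_g == 0:
            raise HerbclockError("causal genotypes carry no variance; pick other sites")
        sigma_e = np.sqrt(var_g * (1 - config.target_h2) / config.target_h2)
        truth.causal_sites = [int(c) for c in causal]
        truth.causal_betas = [float(b) for b in betas]
    else:
        g = np.zeros(n)
        sigma_e = 1.0

    eps = rng.normal(scale=sigma_e, size=n) if sigma_e > 0 else np.zeros(n)
    y = g + eps
    tot = float(np.var(g) + sigma_e**2)
    truth.realized_h2 = float(np.var(g) / tot) if tot > 0 else 0.0

    rows = []
    for rep in range(config.n_replicates):
        noise = (
            rng.normal(scale=config.replicate_noise_sd, size=n)
            if config.replicate_noise_sd > 0
            else np.zeros(n)
        )
        for i, sid in enumerate(v.samples):
            rows.append((sid, trait, rep, float(y[i] + noise[i])))
    tbl = PhenotypeTable(pd.DataFrame(rows, columns=["sample_id", "trait", "replicate", "value"]))
    return tbl, truth


def simulate_ma_lines(n_lines: int, generations: int, mu_per_site_gen: float,
                      callable_bp: int, seed: int) -> np.ndarray:
    """Per-line mutation counts ~ Poisson(mu_g x generations x callable bp)."""
    if n_lines <= 0 or generations <= 0 or callable_bp <= 0 or mu_per_site_gen < 0:
        raise HerbclockError("MA-line parameters must be positive (mu >= 0)")
    rng = np.random.default_rng(seed)
    lam = mu_per_site_gen * generations * callable_bp
    return rng.poisson(lam, size=n_lines)


def simulate_climate(meta: list[SampleMeta], v: VariantTable, coupling: float,
                     seed: int, noise_sd: float = 0.1, focal_site: int | None = None
                     ) -> pd.DataFrame:
    """Climate covariate = coupling x allele signal + (1-coupling) x spatial gradient + noise.

    Returns a frame with sample_id, latitude, longitude and the climate value;
    lat/lon are retained so downstream association can use them as confounders.
    """
    if not (0 <= coupling <= 1):
        raise HerbclockError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lat = np.array([m.latitude for m in meta])
    lon = np.array([m.longitude for m in meta])

    der, nm = v.derived_freqs()
    if focal_site is None:
        with np.errstate(invalid="ignore"):
            freq = np.where(nm > 0, der / nm, 0.0)
        maf = np.minimum(freq, 1 - freq)
        focal_site = int(np.argmax(maf)) if v.n_sites else None
    if focal_site is not None and v.n_sites:
        x = v.calls[focal_site].astype(float)
        x[v.calls[focal_site] == MISSING] = np.nan
        x = np.where(np.isnan(x), np.nanmean(x), x)
        signal = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    else:
        signal = np.zeros(len(meta))

    spatial = 0.6 * lat + 0.4 * lon
    spatial = (spatial - spatial.mean()) / (spatial.std() if spatial.std() > 0 else 1.0)
    climate = coupling * signal + (1 - coupling) * spatial + rng.normal(scale=noise_sd, size=len(meta))
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "latitude": lat,
            "longitude": lon,
            "climate": climate,
            "focal_site": focal_site if focal_site is not None else -1,
        }
    )
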