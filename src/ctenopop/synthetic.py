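"""Synthetic genotype datasets with the statistical structure of the study.

The generator emulates the sampled design of the grass carp survey: six
native locations in three river systems (Heilongjiang, Yangtze, Pearl),
one admixed location (Nenjiang, a Heilongjiang site carrying substantial
Yangtze and Pearl ancestry), and three introduced locations (Malaysia,
India, Nepal) founded from an admixture of the Yangtze and Pearl clusters
through a founder bottleneck.

Allele-frequency drift along each branch of the population graph follows
the Balding–Nichols construction: a child frequency is Beta-distributed
with mean equal to the parent frequency and variance ``c * p * (1 - p)``,
so the drift parameter ``c`` of a branch is the expected F_ST across it —
which gives analytic oracle checks for free.  Founder bottlenecks add an
extra drift increment ``c_f = 1 - (1 - 1/(2*Nm))**db`` (the Wright–Fisher
expectation for a ``db``-generation bottleneck at size ``Nm``).

Selected loci can be planted on top of the neutral background:

* ``clinal`` — latitudinal cline: logit(p_pop) shifted by slope *
  standardized latitude;
* ``divergent`` — branch drift variance inflated (positive selection
  mimicry for F_ST outlier scans);
* ``balanced`` — all population frequencies drawn tightly around 0.5
  (balancing selection: high heterozygosity, low differentiation).

Truth labels are persisted per locus so power and false-discovery rates
stay computable after any filtering cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap, SiteTable, make_locus_table

# ---------------------------------------------------------------------------
# Design containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """Population graph with drift, admixture and bottleneck recipes.

    Parameters
    ----------
    branches : dict
        node -> (parent node or None for the root, drift c in [0, 1)).
        Internal (unsampled) ancestors are any nodes not listed in
        ``populations``.
    admixture : dict
        target node -> (list of source nodes, list of proportions summing
        to 1).  The target's own branch entry must have drift only
        (its parent is ignored for frequency construction).
    bottlenecks : dict
        population -> (founder size Nm, duration db in generations).
    populations : pandas.DataFrame
        One row per sampled population: columns group, native (bool),
        latitude, longitude, temp_c, n (sample size).
    """

    branches: dict
    populations: pd.DataFrame
    admixture: dict = field(default_factory=dict)
    bottlenecks: dict = field(default_factory=dict)
    #: pop -> (n_individuals x n_sources) ancestry rows; overrides the
    #: population-level mixture at genotype draw so individuals can be
    #: heterogeneous (e.g. half pure natives, half recent migrants)
    individual_admixture: dict = field(default_factory=dict)

    def __post_init__(self):
        for node, (_parent, c) in self.branches.items():
            if not (0.0 <= c < 1.0):
                raise ValueError(f"drift c={c} for {node} outside [0, 1)")
        for tgt, (sources, props) in self.admixture.items():
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"admixture proportions for {tgt} do not sum to 1")
            if len(sources) != len(props):
                raise ValueError(f"admixture recipe for {tgt} is ragged")
        for pop, rows in self.individual_admixture.items():
            rows = np.asarray(rows, dtype=float)
            if pop not in self.admixture:
                raise ValueError(f"{pop} has individual ancestry but no admixture recipe")
            if rows.shape != (int(self.populations.loc[pop, "n"]), len(self.admixture[pop][0])):
                raise ValueError(f"individual ancestry for {pop} has the wrong shape")
            if not np.allclose(rows.sum(axis=1), 1.0):
                raise ValueError(f"individual ancestry rows for {pop} do not sum to 1")
        if (self.populations["n"] < 2).any():
            raise ValueError("every population needs sample size >= 2")
        self._toposort()  # raises on cycles

    def _toposort(self) -> list:
        """Topological order of the frequency-construction DAG."""
        deps: dict = {}
        for node, (parent, _c) in self.branches.items():
            deps[node] = set()
            if node in self.admixture:
                deps[node].update(self.admixture[node][0])
            elif parent is not None:
                deps[node].add(parent)
        order, done = [], set()
        state: dict = {}

        def visit(u):
            if state.get(u) == 1:
                raise ValueError(f"population graph has a cycle through {u!r}")
            if u in done:
                return
            state[u] = 1
            for v in deps.get(u, ()):
                visit(v)
            state[u] = 0
            done.add(u)
            order.append(u)

        for node in self.branches:
            visit(node)
        return order

    def population_map(self) -> PopulationMap:
        return PopulationMap(
            population_of=pd.Series(
                {
                    f"{pop}_{i:02d}": pop
                    for pop, n in self.populations["n"].items()
                    for i in range(int(n))
                }
            ),
            group_of=self.populations["group"],
            native=self.populations["native"],
        )

    def site_table(self) -> SiteTable:
        return SiteTable(self.populations[["latitude", "longitude", "temp_c"]])


@dataclass
class SelectionPlan:
    """Counts and effect sizes for planted selected loci."""

    n_clinal: int = 0
    clinal_slope: float = 2.0
    n_divergent: int = 0
    divergent_inflation: float = 5.0
    n_balanced: int = 0
    balanced_concentration: float = 80.0  # Beta(a, a) around 0.5

    def total(self) -> int:
        return self.n_clinal + self.n_divergent + self.n_balanced


@dataclass
class TagLayout:
    """RAD-tag grouping and scaffold coordinates for simulated loci."""

    scaffold_lengths: dict
    mean_snps_per_tag: float = 0.61
    tag_length: int = 100
    max_snps_per_tag: int = 5

    def __post_init__(self):
        if self.mean_snps_per_tag <= 0:
            raise ValueError("mean SNPs per tag must be positive")


def default_tag_layout(n_scaffolds: int = 24) -> TagLayout:
    """Scaffold panel emulating the 24 longest assembly scaffolds
    (9.6–19.1 Mb)."""
    lengths = np.linspace(19_100_000, 9_600_000, n_scaffolds).astype(int)
    return TagLayout({f"CI{i:08d}": int(l) for i, l in enumerate(lengths)})


# ---------------------------------------------------------------------------
# The default study design
# ---------------------------------------------------------------------------

#: Nenjiang ancestry composition target (Heilongjiang, Yangtze, Pearl)
NENJIANG_MIX = (0.488, 0.436, 0.075)

_SITES = {
    # pop: (group, native, lat, lon, n)
    "Nenjiang": ("Heilongjiang", True, 49.17, 125.22, 20),
    "Hanjiang": ("Yangtze", True, 30.55, 113.45, 22),
    "Jiujiang": ("Yangtze", True, 29.71, 116.00, 22),
    "Shishou": ("Yangtze", True, 29.72, 112.40, 22),
    "Zhaoqing": ("Pearl", True, 23.05, 112.47, 22),
    "Vietnam": ("Pearl", True, 21.03, 105.85, 23),
    "Malaysia": ("Introduced", False, 3.14, 101.69, 22),
    "India": ("Introduced", False, 22.57, 88.36, 22),
    "Nepal": ("Introduced", False, 27.72, 85.32, 22),
}


def default_design(seed: int = 0, founder_size: int = 100, founder_duration: int = 50) -> SimulationDesign:
    """The nine-location grass-carp-like design (197 individuals).

    Drift parameters are chosen so that pairwise F_ST lands in the ranges
    reported for the system: ~0.005–0.05 among native locations,
    ~0.1–0.25 between native and introduced locations (the introduced
    founder bottleneck dominates).  Annual mean temperature is generated
    as an affine function of latitude plus small noise, reproducing the
    near-perfect temperature–latitude collinearity of the sampling sites.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pop, (group, native, lat, lon, n) in _SITES.items():
        temp = 30.0 - 0.52 * lat + rng.normal(0.0, 0.3)
        rows.append(
            {
                "population": pop,
                "group": group,
                "native": native,
                "latitude": lat,
                "longitude": lon,
                "temp_c": round(float(temp), 2),
                "n": n,
            }
        )
    populations = pd.DataFrame(rows).set_index("population")

    branches = {
        "root": (None, 0.0),
        "H_anc": ("root", 0.030),
        "Y_anc": ("root", 0.012),
        "P_anc": ("root", 0.030),
        "Nenjiang": (None, 0.004),  # admixed, see below
        "Hanjiang": ("Y_anc", 0.006),
        "Jiujiang": ("Y_anc", 0.004),
        "Shishou": ("Y_anc", 0.004),
        "Zhaoqing": ("P_anc", 0.006),
        "Vietnam": ("P_anc", 0.010),
        "Malaysia": (None, 0.004),
        "India": (None, 0.004),
        "Nepal": (None, 0.004),
    }
    mix = [w / sum(NENJIANG_MIX) for w in NENJIANG_MIX]  # renormalize 0.999
    admixture = {
        "Nenjiang": (["H_anc", "Y_anc", "P_anc"], mix),
        "Malaysia": (["Y_anc", "P_anc"], [0.5, 0.5]),
        "India": (["Y_anc", "P_anc"], [0.4, 0.6]),
        "Nepal": (["Y_anc", "P_anc"], [0.4, 0.6]),
    }
    bottlenecks = {
        "Malaysia": (founder_size, founder_duration),
        "India": (founder_size, founder_duration),
        "Nepal": (founder_size, founder_duration),
    }
    # Nenjiang is individual-heterogeneous: half the sample is purely
    # native Heilongjiang, the other half carries almost entirely
    # Yangtze/Pearl ancestry, so the location-mean composition lands at
    # the admixture recipe while exactly ten individuals are flaggable as
    # recent migrants (> 50% foreign composition)
    nenjiang_rows = [[1.0, 0.0, 0.0]] * 10 + [[0.0, 0.872, 0.128]] * 10
    individual_admixture = {"Nenjiang": nenjiang_rows}
    return SimulationDesign(
        branches, populations, admixture, bottlenecks, individual_admixture
    )


# ---------------------------------------------------------------------------
# Frequency construction and genotype draws
# ---------------------------------------------------------------------------


def bottleneck_drift(founder_size: float, duration: float) -> float:
    """Extra drift increment of a ``duration``-generation bottleneck at
    effective size ``founder_size``: ``1 - (1 - 1/(2 Nm))**db``."""
    return 1.0 - (1.0 - 1.0 / (2.0 * founder_size)) ** duration


def _bn_draw(rng, p: np.ndarray, c: float) -> np.ndarray:
    """Balding–Nichols Beta draw: mean p, variance c*p*(1-p)."""
    if c <= 0.0:
        return p.copy()
    scale = (1.0 - c) / c
    out = rng.beta(np.maximum(p * scale, 1e-9), np.maximum((1.0 - p) * scale, 1e-9))
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def _population_frequencies(design, n_loci, rng, drift_scale=None):
    """Per-node allele frequencies along the design graph.

    drift_scale: optional multiplier applied to every branch drift c
    (used for planting divergent loci).
    """
    p0 = rng.uniform(0.05, 0.95, size=n_loci)
    freqs = {None: p0}
    scale = 1.0 if drift_scale is None else float(drift_scale)
    for node in design._toposort():
        parent, c = design.branches[node]
        c_eff = min(c * scale, 0.98)
        if node in design.admixture:
            sources, props = design.admixture[node]
            base = sum(w * freqs[s] for s, w in zip(sources, props))
            base = np.clip(base, 1e-9, 1 - 1e-9)
        else:
            base = freqs[parent]
        freqs[node] = _bn_draw(rng, base, c_eff)
    for pop, (nm, db) in design.bottlenecks.items():
        c_f = min(bottleneck_drift(nm, db) * scale, 0.98)
        freqs[pop] = _bn_draw(rng, freqs[pop], c_f)
    pops = list(design.populations.index)
    return p0, np.column_stack([freqs[p] for p in pops]), freqs


def _draw_genotypes(rng, pop_freqs, sizes):
    """Binomial(2, p_pop) dosage draws; rows grouped by population."""
    blocks = [
        rng.binomial(2, pop_freqs[:, k][None, :], size=(int(n), pop_freqs.shape[0]))
        for k, n in enumerate(sizes)
    ]
    return np.vstack(blocks).astype(np.int8)


def _draw_cohort(rng, design, node_freqs):
    """Genotype draws for the whole design, honoring per-individual
    ancestry where specified: an individual with ancestry a over sources
    S draws each allele alt with probability sum_k a_k p_{S_k}."""
    blocks = []
    for pop, n in design.populations["n"].items():
        n = int(n)
        if pop in design.individual_admixture:
            a = np.asarray(design.individual_admixture[pop], dtype=float)
            src = np.stack([node_freqs[s] for s in design.admixture[pop][0]])
            p_ind = np.clip(a @ src, 0.0, 1.0)  # (n, L)
            blocks.append(rng.binomial(2, p_ind))
        else:
            p = node_freqs[pop]
            blocks.append(rng.binomial(2, np.broadcast_to(p, (n, p.shape[0]))))
    return np.vstack(blocks).astype(np.int8)


def simulate_metapopulation(
    design: SimulationDesign,
    n_loci: int,
    seed: int,
    missing_rate: float = 0.0,
):
    """Neutral genotypes for the full design.

    Returns ``(GenotypeMatrix, truth)`` where truth is a per-locus frame
    with the ancestral frequency and class label ``neutral``.  Locus
    metadata initially carries placeholder coordinates; use
    :func:`assign_tags_and_coords` for a RAD-tag layout.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    p0, _pop_freqs, node_freqs = _population_frequencies(design, n_loci, rng)
    dosage = _draw_cohort(rng, design, node_freqs)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = MISSING
    ids = [f"L{j:06d}" for j in range(n_loci)]
    loci = make_locus_table(ids, tag_ids=[f"T{j:06d}" for j in range(n_loci)],
                            scaffolds=["CI00000000"] * n_loci,
                            positions=list(range(1, n_loci + 1)))
    g = GenotypeMatrix(design.population_map().population_of.index.tolist(), loci, dosage)
    truth = pd.DataFrame(
        {"class": "neutral", "p0": p0, "param": np.nan}, index=loci.index
    )
    return g, truth


def plant_selected_loci(
    g: GenotypeMatrix,
    plan: SelectionPlan,
    design: SimulationDesign,
    seed: int,
    truth: pd.DataFrame | None = None,
):
    """Overwrite a disjoint random subset of loci with selected classes.

    Clinal loci shift each population's frequency on the logit scale by
    ``slope * standardized(latitude)``; divergent loci re-run the drift
    graph with inflated branch variance; balanced loci draw frequencies
    from a tight Beta around 0.5 in every population.  Returns the new
    matrix and the updated truth table.
    """
    if plan.total() > g.n_loci:
        raise ValueError("selection plan larger than the number of loci")
    if plan.n_clinal and plan.clinal_slope == 0.0:
        warnings.warn("clinal slope 0 is indistinguishable from neutral", stacklevel=2)
    rng = np.random.default_rng(seed)
    sizes = design.populations["n"].to_numpy()
    lat = design.populations["latitude"].to_numpy(dtype=float)
    lat_z = (lat - lat.mean()) / lat.std()

    chosen = rng.choice(g.n_loci, size=plan.total(), replace=False)
    idx_clin = chosen[: plan.n_clinal]
    idx_div = chosen[plan.n_clinal : plan.n_clinal + plan.n_divergent]
    idx_bal = chosen[plan.n_clinal + plan.n_divergent :]

    dosage = g.dosage.copy()
    truth = (
        truth.copy()
        if truth is not None
        else pd.DataFrame({"class": "neutral", "p0": np.nan, "param": np.nan},
                          index=g.loci.index)
    )

    if plan.n_clinal:
        p0 = rng.uniform(0.2, 0.8, size=plan.n_clinal)
        logit = np.log(p0 / (1 - p0))[:, None] + plan.clinal_slope * lat_z[None, :]
        pf = 1.0 / (1.0 + np.exp(-logit))
        dosage[:, idx_clin] = _draw_genotypes(rng, pf, sizes)
        truth.iloc[idx_clin, truth.columns.get_loc("class")] = "clinal"
        truth.iloc[idx_clin, truth.columns.get_loc("param")] = plan.clinal_slope

    if plan.n_divergent:
        _p0, pf, _nf = _population_frequencies(
            design, plan.n_divergent, rng, drift_scale=plan.divergent_inflation
        )
        dosage[:, idx_div] = _draw_genotypes(rng, pf, sizes)
        truth.iloc[idx_div, truth.columns.get_loc("class")] = "divergent"
        truth.iloc[idx_div, truth.columns.get_loc("param")] = plan.divergent_inflation

    if plan.n_balanced:
        a = plan.balanced_concentration
        pf = rng.beta(a, a, size=(plan.n_balanced, len(sizes)))
        dosage[:, idx_bal] = _draw_genotypes(rng, pf, sizes)
        truth.iloc[idx_bal, truth.columns.get_loc("class")] = "balanced"
        truth.iloc[idx_bal, truth.columns.get_loc("param")] = a

    return GenotypeMatrix(g.individuals, g.loci, dosage), truth


def plant_genomic_island(
    g: GenotypeMatrix,
    design: SimulationDesign,
    scaffold: str,
    start: int,
    end: int,
    seed: int,
    inflation: float = 10.0,
):
    """Re-draw all loci inside [start, end) bp of a scaffold with inflated
    branch drift, creating a contiguous elevated-differentiation region
    (a genomic island) for window-scan recovery studies.

    Returns the new matrix and the list of affected locus ids.
    """
    rng = np.random.default_rng(seed)
    pos0 = g.loci["position"].to_numpy() - 1
    mask = (g.loci["scaffold"] == scaffold).to_numpy() & (pos0 >= start) & (pos0 < end)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no loci inside the requested island span")
    _p0, pf, _nf = _population_frequencies(design, idx.size, rng, drift_scale=inflation)
    dosage = g.dosage.copy()
    dosage[:, idx] = _draw_genotypes(rng, pf, design.populations["n"].to_numpy())
    return GenotypeMatrix(g.individuals, g.loci, dosage), list(g.loci.index[idx])


# ---------------------------------------------------------------------------
# RAD-tag layout
# ---------------------------------------------------------------------------


def sample_snps_per_tag(rng, n_tags: int, layout: TagLayout) -> np.ndarray:
    """SNP count per tag: Poisson(mean) truncated at ``max_snps_per_tag``."""
    counts = rng.poisson(layout.mean_snps_per_tag, size=n_tags)
    return np.minimum(counts, layout.max_snps_per_tag)


def assign_tags_and_coords(
    locus_ids, layout: TagLayout, seed: int
) -> pd.DataFrame:
    """Group loci into RAD tags and place them on scaffolds.

    Tags are placed uniformly over the scaffold panel; SNP counts per tag
    follow a truncated Poisson with the layout's target mean; within-tag
    offsets are strictly increasing and < ``tag_length``.  Returns a fresh
    locus metadata table for the given ids.
    """
    rng = np.random.default_rng(seed)
    locus_ids = list(locus_ids)
    n = len(locus_ids)
    if sum(layout.scaffold_lengths.values()) < n * layout.tag_length:
        raise ValueError("scaffold panel too small for the requested loci")

    # draw tag occupancies until we cover all loci
    counts = []
    covered = 0
    while covered < n:
        batch = sample_snps_per_tag(rng, max(64, int(1.2 * (n - covered))), layout)
        for c in batch:
            counts.append(int(c))
            covered += int(c)
            if covered >= n:
                break
    # trim overshoot on the last occupied tag
    overshoot = covered - n
    if overshoot:
        counts[-1] -= overshoot

    scaffolds = list(layout.scaffold_lengths)
    lengths = np.array([layout.scaffold_lengths[s] for s in scaffolds], dtype=float)
    probs = lengths / lengths.sum()
    n_tags = len(counts)
    tag_scaf = rng.choice(len(scaffolds), size=n_tags, p=probs)

    # uniform tag starts per scaffold, sorted and spaced >= tag_length so
    # tags never overlap (keeps within-scaffold coordinates strictly
    # increasing when walking tags in start order)
    tag_col, scaf_col, pos_col = [], [], []
    rank = 0
    occupied = [t for t in range(n_tags) if counts[t] > 0]
    for si, scaf in enumerate(scaffolds):
        mine = [t for t in occupied if tag_scaf[t] == si]
        if not mine:
            continue
        span = layout.scaffold_lengths[scaf] - layout.tag_length - 1
        starts = np.sort(rng.integers(1, span, size=len(mine)))
        for i in range(1, len(starts)):
            if starts[i] < starts[i - 1] + layout.tag_length:
                starts[i] = starts[i - 1] + layout.tag_length
        for t, start in zip(mine, starts):
            k = counts[t]
            offs = np.sort(rng.choice(layout.tag_length, size=k, replace=False))
            for o in offs:
                tag_col.append(f"T{rank:07d}")
                scaf_col.append(scaf)
                pos_col.append(int(start) + int(o))
            rank += 1
    return make_locus_table(locus_ids, tag_col, scaf_col, pos_col)
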