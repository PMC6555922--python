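"""Diversity, differentiation, distance, IBD, tree and PCA statistics.

Differentiation uses the Weir–Cockerham variance-components estimator
theta throughout, with multi-locus values computed as the ratio of summed
components.  Pairwise significance follows the permutation convention for
genotypic data (individuals permuted between the pair).  Genetic distance
for isolation-by-distance is linearized F_ST, F_ST / (1 - F_ST), against
great-circle geographic distance; trees are neighbor-joining on Nei's
standard genetic distance with bootstrap-over-loci supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap, SiteTable

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Symmetric population x population distance with a kind tag."""

    values: pd.DataFrame
    kind: str  # fst | linearized_fst | nei_standard | geographic_km

    def __post_init__(self):
        v = pd.DataFrame(self.values)
        if not np.allclose(v.to_numpy(), v.to_numpy().T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        self.values = v

    @property
    def populations(self) -> list:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major."""
        a = self.values.to_numpy()
        iu = np.triu_indices(a.shape[0], k=1)
        return a[iu]


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # individuals x components
    eigenvalues: np.ndarray
    normalization: str = "eigenstrat"


# ---------------------------------------------------------------------------
# Per-population counts
# ---------------------------------------------------------------------------


def _pop_counts(g: GenotypeMatrix, rows_by_pop: dict):
    """Stacked per-population (n_called, alt_freq, het_prop), each of shape
    (n_pops, n_loci); entries with no calls are NaN frequencies."""
    n, p, h = [], [], []
    for pop, idx in rows_by_pop.items():
        d = g.dosage[idx]
        called = d != MISSING
        ni = called.sum(axis=0).astype(float)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(ni > 0, alt / (2.0 * ni), np.nan)
            hi = np.where(ni > 0, (d == 1).sum(axis=0) / ni, np.nan)
        n.append(ni)
        p.append(pi)
        h.append(hi)
    return np.array(n), np.array(p), np.array(h)


# ---------------------------------------------------------------------------
# Diversity table
# ---------------------------------------------------------------------------


def per_pop_diversity(g: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """H_O, unbiased H_E and per-variant-site nucleotide diversity Pi.

    Per locus and population: H_O is the heterozygote fraction among
    genotyped individuals; H_E = 2 p (1-p) * 2n/(2n-1) (unbiased); Pi is
    the average proportion of differing pairs among the 2n sampled
    alleles, which for a biallelic site equals the unbiased H_E.  The
    population means run over loci variant in the pooled sample with >= 2
    genotyped individuals in that population.
    """
    rows = popmap.row_indices(g)
    maf = g.minor_allele_freq()
    variant = np.nan_to_num(maf, nan=0.0) > 0.0
    n, p, h = _pop_counts(g, rows)
    out = []
    for i, pop in enumerate(rows):
        ok = variant & (n[i] >= 2)
        if not ok.any():
            raise ValueError(f"population {pop} has no usable variant loci")
        ni, pi, hi = n[i][ok], p[i][ok], h[i][ok]
        he = 2.0 * pi * (1.0 - pi) * (2.0 * ni) / (2.0 * ni - 1.0)
        out.append(
            {
                "population": pop,
                "n_individuals": len(rows[pop]),
                "H_O": float(hi.mean()),
                "H_E": float(he.mean()),
                "Pi": float(he.mean()),  # identical for biallelic sites
                "n_loci": int(ok.sum()),
            }
        )
    return pd.DataFrame(out).set_index("population")


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components(n, p, h):
    """Per-locus Weir–Cockerham variance components (a, b, c).

    Inputs are stacked per-population arrays of shape (r, ...): sample
    sizes (diploids with calls), alt-allele frequencies and heterozygote
    proportions.  Loci where any population has < 1 call or where the
    pooled sample is monomorphic come out NaN.
    """
    r = n.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        rn = r * nbar
        nc = (rn - (n**2).sum(axis=0) / rn) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / rn
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / rn
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (nbar <= 1.0) | (nc <= 0.0) | (pbar <= 0.0) | (pbar >= 1.0)
    for arr in (a, b, c):
        arr[..., bad] = np.nan
    return a, b, c


def wc_fst(g: GenotypeMatrix, popmap: PopulationMap, pops=None):
    """Per-locus and multi-locus Weir–Cockerham theta.

    Returns ``(theta_per_locus, theta_multilocus)``; the multi-locus value
    is the ratio of summed components over loci polymorphic in the pooled
    sample.
    """
    rows = popmap.row_indices(g)
    if pops is not None:
        rows = {p: rows[p] for p in pops}
    if len(rows) < 2:
        raise ValueError("theta needs at least two populations")
    n, p, h = _pop_counts(g, rows)
    a, b, c = _wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    multi = float(a[ok].sum() / denom) if denom != 0 else float("nan")
    return per_locus, multi


def wc_fst_grouped(g: GenotypeMatrix, rows_a: np.ndarray, rows_b: np.ndarray):
    """Theta between two pooled groups given row indices."""
    n, p, h = [], [], []
    for idx in (rows_a, rows_b):
        d = g.dosage[idx]
        called = d != MISSING
        ni = called.sum(axis=0).astype(float)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n.append(ni)
            p.append(np.where(ni > 0, alt / (2 * ni), np.nan))
            h.append(np.where(ni > 0, (d == 1).sum(axis=0) / ni, np.nan))
    a, b, c = _wc_components(np.array(n), np.array(p), np.array(h))
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    multi = float(a[ok].sum() / denom) if denom != 0 else float("nan")
    return per_locus, multi


def pairwise_fst(g: GenotypeMatrix, popmap: PopulationMap) -> DistanceMatrix:
    """Multi-locus theta for every population pair."""
    rows = popmap.row_indices(g)
    pops = list(rows)
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            _pl, th = wc_fst_grouped(g, rows[a], rows[b])
            m.loc[a, b] = m.loc[b, a] = th
    return DistanceMatrix(m, "fst")


def _perm_theta_block(dos_pair, n_a, perms):
    """Multi-locus theta for each row-permutation of a two-population
    genotype block.  ``perms``: (n_perm, n_ind) permuted row indices; the
    first n_a rows of each permutation form population A."""
    called = (dos_pair != MISSING).astype(np.float64)
    alt = np.where(dos_pair != MISSING, dos_pair, 0).astype(np.float64)
    het = (dos_pair == 1).astype(np.float64)
    thetas = np.empty(perms.shape[0])
    for k in range(perms.shape[0]):
        idx = perms[k]
        ra, rb = idx[:n_a], idx[n_a:]
        n = np.array([called[ra].sum(axis=0), called[rb].sum(axis=0)])
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.array(
                [alt[ra].sum(axis=0) / (2 * n[0]), alt[rb].sum(axis=0) / (2 * n[1])]
            )
            h = np.array([het[ra].sum(axis=0) / n[0], het[rb].sum(axis=0) / n[1]])
        a, b, c = _wc_components(n, p, h)
        ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
        denom = (a[ok] + b[ok] + c[ok]).sum()
        thetas[k] = a[ok].sum() / denom if denom != 0 else np.nan
    return thetas


def pairwise_fst_test(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Observed pairwise theta with permutation p-values.

    The null permutes individuals between the pair; p = (1 + #{theta_perm
    >= theta_obs}) / (n_perm + 1).  Returns (DistanceMatrix, p-value
    frame, Bonferroni significance frame at ``alpha / n_pairs``).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = popmap.row_indices(g)
    pops = list(rows)
    n_pairs = len(pops) * (len(pops) - 1) // 2
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    pval = pd.DataFrame(1.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            ra, rb = rows[a], rows[b]
            block = g.dosage[np.concatenate([ra, rb])]
            n_ind = block.shape[0]
            _pl, obs = wc_fst_grouped(g, ra, rb)
            perms = np.array([rng.permutation(n_ind) for _ in range(n_perm)])
            null = _perm_theta_block(block, len(ra), perms)
            p = (1.0 + np.sum(null >= obs - 1e-15)) / (n_perm + 1.0)
            fst.loc[a, b] = fst.loc[b, a] = obs
            pval.loc[a, b] = pval.loc[b, a] = p
    signif = pval < alpha / n_pairs
    np.fill_diagonal(signif.values, False)
    return DistanceMatrix(fst, "fst"), pval, signif


# ---------------------------------------------------------------------------
# Gene flow, linearization, geography
# ---------------------------------------------------------------------------


def nm_from_fst(fst: float) -> float:
    """Effective number of migrants from F_ST ~ 1/(4 Nm + 1)."""
    if fst <= 0.0:
        return float("inf")
    if fst >= 1.0:
        return 0.0
    return (1.0 / fst - 1.0) / 4.0


def linearized_fst(dm: DistanceMatrix) -> DistanceMatrix:
    """Elementwise F_ST / (1 - F_ST); genetic distance for IBD."""
    a = dm.values.to_numpy()
    if (a >= 1.0).any():
        raise ValueError("F_ST of 1 cannot be linearized")
    out = a / (1.0 - a)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(
        pd.DataFrame(out, index=dm.values.index, columns=dm.values.columns),
        "linearized_fst",
    )


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two points in kilometres."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance(sites: SiteTable, populations=None, planar: bool = False) -> DistanceMatrix:
    """Pairwise linear distance between sampling localities in km.

    Great-circle by default; ``planar`` switches to an equirectangular
    approximation (1 degree latitude = 111.195 km).
    """
    pops = list(populations) if populations is not None else sites.populations
    lat = sites.covariate("latitude", pops)
    lon = sites.covariate("longitude", pops)
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            if planar:
                ky = 111.195
                kx = ky * np.cos(np.radians((lat[i] + lat[j]) / 2))
                d = float(np.hypot(ky * (lat[i] - lat[j]), kx * (lon[i] - lon[j])))
            else:
                d = haversine_km(lat[i], lon[i], lat[j], lon[j])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(pd.DataFrame(m, index=pops, columns=pops), "geographic_km")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def mantel_test(
    dist_a: DistanceMatrix, dist_b: DistanceMatrix, n_perm: int = 9999, seed: int = 0
) -> MantelResult:
    """Mantel matrix correlation with simultaneous row/column permutation.

    One-sided p for positive association; r is the Pearson correlation of
    off-diagonal entries.  R^2 = r^2 follows the reporting convention.
    """
    if dist_a.populations != dist_b.populations:
        raise ValueError("distance matrices must share population ordering")
    n = len(dist_a.populations)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 populations")
    A = dist_a.values.to_numpy()
    B = dist_b.values.to_numpy()
    iu = np.triu_indices(n, k=1)

    def _r(x, y):
        xs, ys = x - x.mean(), y - y.mean()
        den = np.sqrt((xs**2).sum() * (ys**2).sum())
        if den == 0.0:
            raise ValueError("constant distance matrix: Mantel r undefined")
        return float((xs * ys).sum() / den)

    r_obs = _r(A[iu], B[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Bp = B[np.ix_(perm, perm)]
        if _r(A[iu], Bp[iu]) >= r_obs - 1e-15:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=r_obs, r_squared=r_obs**2, p_value=p, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Nei distance and NJ tree
# ---------------------------------------------------------------------------


def _nei_from_freqs(p, valid):
    """Nei's standard D for stacked per-population frequencies (r, L)."""
    r = p.shape[0]
    m = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            ok = valid[i] & valid[j]
            pi, pj = p[i][ok], p[j][ok]
            jx = (pi**2 + (1 - pi) ** 2).mean()
            jy = (pj**2 + (1 - pj) ** 2).mean()
            jxy = (pi * pj + (1 - pi) * (1 - pj)).mean()
            if jxy <= 0:
                raise ValueError("zero inter-population gene identity: D infinite")
            m[i, j] = m[j, i] = -np.log(jxy / np.sqrt(jx * jy))
    return m


def nei_distance(g: GenotypeMatrix, popmap: PopulationMap) -> DistanceMatrix:
    """Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx Jy)), with the
    gene-identity terms averaged over loci."""
    rows = popmap.row_indices(g)
    pops = list(rows)
    n, p, _h = _pop_counts(g, rows)
    valid = n > 0
    m = _nei_from_freqs(p, valid)
    return DistanceMatrix(pd.DataFrame(m, index=pops, columns=pops), "nei_standard")


def nj_tree(dm: DistanceMatrix):
    """Neighbor-joining tree (standard Q-matrix agglomeration) as a
    scikit-bio TreeNode."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    if len(dm.populations) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    sk = SkbioDM(dm.values.to_numpy(), ids=[str(p) for p in dm.populations])
    return skbio_nj(sk)


def _bipartitions(tree, taxa: frozenset):
    """Non-trivial bipartitions of an unrooted tree, each normalized to the
    lexicographically smaller side."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            parts.add(min(side, other, key=lambda s: sorted(s)))
    return parts


def nj_tree_with_support(
    g: GenotypeMatrix, popmap: PopulationMap, n_bootstrap: int = 1000, seed: int = 0
):
    """NJ tree on Nei distance with bootstrap-over-loci bipartition support.

    Returns ``(tree, support)`` where support maps each internal bipartition
    (frozenset of taxa on its smaller side) to the fraction of bootstrap
    trees containing it; supports are also written onto the tree nodes.
    """
    rows = popmap.row_indices(g)
    pops = [str(p) for p in rows]
    taxa = frozenset(pops)
    n, p, _h = _pop_counts(g, rows)
    valid = n > 0
    base = _nei_from_freqs(p, valid)
    tree = nj_tree(DistanceMatrix(pd.DataFrame(base, index=pops, columns=pops), "nei_standard"))

    rng = np.random.default_rng(seed)
    counts: dict = {}
    for _ in range(n_bootstrap):
        take = rng.integers(0, g.n_loci, size=g.n_loci)
        bm = _nei_from_freqs(p[:, take], valid[:, take])
        bt = nj_tree(DistanceMatrix(pd.DataFrame(bm, index=pops, columns=pops), "nei_standard"))
        for part in _bipartitions(bt, taxa):
            counts[part] = counts.get(part, 0) + 1
    support = {part: c / n_bootstrap for part, c in counts.items()}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            key = min(side, taxa - side, key=lambda s: sorted(s))
            node.name = f"{support.get(key, 0.0):.2f}"
    return tree, support


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_genotypes(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the genotype matrix with allele-frequency normalization.

    Columns are mean-centered and scaled by sqrt(p(1-p)) with p estimated
    from pooled counts; missing entries are mean-imputed before the
    decomposition.  Zero-variance columns are dropped with a warning.
    """
    if g.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    p = mean / 2.0
    scale = np.sqrt(np.maximum(p * (1 - p), 0.0))
    keep = scale > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance loci", stacklevel=2)
    x = (d[:, keep] - mean[keep]) / scale[keep]
    x = np.where(np.isnan(x), 0.0, x)  # mean imputation after centering
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    eig = (s**2) / max(g.n_individuals - 1, 1)
    return PcaResult(
        coordinates=pd.DataFrame(
            coords, index=g.individuals, columns=[f"PC{i+1}" for i in range(k)]
        ),
        eigenvalues=eig[:k],
    )
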