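import numpy as np
import pandas as pd
import pytest

from ctenopop import diversity as dv
from ctenopop import synthetic as syn
from ctenopop.core import MISSING

from conftest import small_matrix


# ---------------------------------------------------------------------------
# Independent Weir–Cockerham oracle (straight textbook transcription)
# ---------------------------------------------------------------------------


def wc_theta_oracle(counts):
    """counts: list per population of (n_AA, n_Aa, n_aa).  Returns
    per-locus (a, b, c) via the variance-components formulas, coded
    independently of the package implementation."""
    r = len(counts)
    n = np.array([sum(c) for c in counts], dtype=float)
    p = np.array([(2 * c[0] + c[1]) / (2 * sum(c)) for c in counts])
    h = np.array([c[1] / sum(c) for c in counts])
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def matrix_from_counts(counts_per_locus):
    """Build a matrix + popmap from per-locus, per-pop genotype counts."""
    n_pops = len(counts_per_locus[0])
    sizes = [sum(counts_per_locus[0][i]) for i in range(n_pops)]
    cols = []
    for counts in counts_per_locus:
        col = []
        for i, (aa, ab, bb) in enumerate(counts):
            col += [0] * aa + [1] * ab + [2] * bb
        cols.append(col)
    dosage = np.array(cols, dtype=np.int8).T
    pops = sum([[f"P{i}"] * s for i, s in enumerate(sizes)], [])
    return small_matrix(dosage, pops=pops)


def test_wc_theta_matches_oracle_exactly():
    """2 pops x 10 individuals toy table agrees with the independently
    coded variance-components oracle to 1e-12."""
    counts = [[(3, 4, 3), (6, 2, 2)], [(1, 5, 4), (2, 6, 2)], [(5, 5, 0), (0, 4, 6)]]
    g, pm = matrix_from_counts(counts)
    per_locus, multi = dv.wc_fst(g, pm)
    a_sum = b_sum = c_sum = 0.0
    for j, c in enumerate(counts):
        a, b, cc = wc_theta_oracle(c)
        assert per_locus[j] == pytest.approx(a / (a + b + cc), abs=1e-12)
        a_sum += a
        b_sum += b
        c_sum += cc
    assert multi == pytest.approx(a_sum / (a_sum + b_sum + c_sum), abs=1e-12)


def test_wc_theta_limits():
    # fixed difference -> theta ~ 1; identical frequencies -> ~ 0
    fixed = [[(30, 0, 0), (0, 0, 30)]]
    g, pm = matrix_from_counts(fixed)
    per_locus, multi = dv.wc_fst(g, pm)
    assert multi > 0.97
    same = [[(10, 10, 10), (10, 10, 10)]]
    g, pm = matrix_from_counts(same)
    _pl, multi = dv.wc_fst(g, pm)
    assert abs(multi) < 0.05


def test_wc_theta_single_population_errors(study_cohort, study_popmap):
    g, _ = study_cohort
    with pytest.raises(ValueError, match="two populations"):
        dv.wc_fst(g, study_popmap, pops=["Nenjiang"])


# ---------------------------------------------------------------------------
# Diversity table
# ---------------------------------------------------------------------------


def test_diversity_all_heterozygotes():
    g, pm = small_matrix(np.ones((6, 1), dtype=np.int8), pops=["P"] * 6)
    # add a variant locus so pooled-variant filtering keeps the column
    tab = dv.per_pop_diversity(g, pm)
    assert tab.loc["P", "H_O"] == 1.0


def test_pi_two_individuals_dosages_0_and_2():
    """n = 2, genotypes {0, 2}: 4 sampled alleles, 2 A and 2 a; the
    proportion of differing pairs is (2*2)/C(4,2) = 2/3."""
    g, pm = small_matrix(np.array([[0], [2]], dtype=np.int8), pops=["P", "P"])
    tab = dv.per_pop_diversity(g, pm)
    assert tab.loc["P", "Pi"] == pytest.approx(2 / 3, abs=1e-12)


def test_he_estimator_unbiased_monte_carlo():
    """Unbiased H_E at known p: mean over many replicate loci matches
    2p(1-p) within Monte-Carlo error."""
    rng = np.random.default_rng(12)
    p_true = 0.3
    dosage = rng.binomial(2, p_true, size=(10, 10_000)).astype(np.int8)
    g, pm = small_matrix(dosage, pops=["P"] * 10)
    rows = {"P": np.arange(10)}
    n = (dosage != MISSING).sum(axis=0)
    phat = dosage.sum(axis=0) / (2 * n)
    he = 2 * phat * (1 - phat) * (2 * n) / (2 * n - 1)
    assert he.mean() == pytest.approx(2 * p_true * (1 - p_true), abs=0.005)


# ---------------------------------------------------------------------------
# Pairwise permutation test
# ---------------------------------------------------------------------------


def test_duplicated_population_theta_nonpositive_p_large():
    rng = np.random.default_rng(1)
    block = rng.binomial(2, rng.uniform(0.2, 0.8, 40), size=(12, 40)).astype(np.int8)
    dosage = np.vstack([block, block])
    g, pm = small_matrix(dosage, pops=["A"] * 12 + ["B"] * 12)
    dm, pval, signif = dv.pairwise_fst_test(g, pm, n_perm=199, seed=2)
    assert dm.values.loc["A", "B"] <= 0.0
    assert pval.loc["A", "B"] > 0.5
    assert not signif.loc["A", "B"]


def test_diverged_pair_hits_permutation_floor():
    d = syn.SimulationDesign(
        branches={"root": (None, 0.0), "P1": ("root", 0.2), "P2": ("root", 0.2)},
        populations=pd.DataFrame(
            {
                "group": ["G", "G"],
                "native": [True, True],
                "latitude": [10.0, 20.0],
                "longitude": [100.0, 100.0],
                "temp_c": [25.0, 20.0],
                "n": [15, 15],
            },
            index=pd.Index(["P1", "P2"], name="population"),
        ),
    )
    g, _ = syn.simulate_metapopulation(d, 400, seed=3)
    dm, pval, _ = dv.pairwise_fst_test(g, d.population_map(), n_perm=199, seed=4)
    assert pval.loc["P1", "P2"] == pytest.approx(1 / 200)


def test_permutation_p_invariant_to_allele_relabeling(study_cohort, study_popmap):
    g, _ = study_cohort
    pm = study_popmap.subset(["Hanjiang", "Zhaoqing"])
    inds = [i for i in g.individuals if i in pm.population_of.index]
    sub = g.take_individuals(inds).take_loci(np.arange(100))
    flipped = sub.dosage.copy()
    called = flipped != MISSING
    flipped[called] = 2 - flipped[called]
    from ctenopop.core import GenotypeMatrix

    g2 = GenotypeMatrix(sub.individuals, sub.loci, flipped)
    _d1, p1, _ = dv.pairwise_fst_test(sub, pm, n_perm=99, seed=7)
    _d2, p2, _ = dv.pairwise_fst_test(g2, pm, n_perm=99, seed=7)
    pd.testing.assert_frame_equal(p1, p2)


# ---------------------------------------------------------------------------
# Gene flow / linearization / geography / Mantel
# ---------------------------------------------------------------------------


def test_nm_closed_form_and_round_trip():
    assert dv.nm_from_fst(0.2) == pytest.approx(1.0)
    assert dv.nm_from_fst(1 / (4 * 12.505 + 1)) == pytest.approx(12.505)
    fsts = np.linspace(0.01, 0.5, 20)
    nms = [dv.nm_from_fst(f) for f in fsts]
    assert all(np.diff(nms) < 0)  # monotone decreasing in F_ST


def test_linearized_fst_arithmetic_and_monotone():
    m = pd.DataFrame([[0.0, 0.052], [0.052, 0.0]], index=["A", "B"], columns=["A", "B"])
    lin = dv.linearized_fst(dv.DistanceMatrix(m, "fst"))
    assert lin.values.loc["A", "B"] == pytest.approx(0.052 / (1 - 0.052))
    with pytest.raises(ValueError):
        dv.linearized_fst(
            dv.DistanceMatrix(pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"], columns=["A", "B"]), "fst")
        )


def test_geographic_distance_haversine_oracle():
    from ctenopop.core import SiteTable

    st = SiteTable(
        pd.DataFrame(
            {"latitude": [10.0, 10.0, -10.0], "longitude": [20.0, 20.0, -160.0]},
            index=["A", "B", "C"],
        )
    )
    dm = dv.geographic_distance(st)
    assert dm.values.loc["A", "B"] == 0.0  # coincident sites
    # C is antipodal to A/B: half the Earth's circumference
    assert dm.values.loc["A", "C"] == pytest.approx(np.pi * dv.EARTH_RADIUS_KM, rel=1e-6)


def test_mantel_identity_and_constant_error():
    rng = np.random.default_rng(8)
    m = rng.random((5, 5))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    dm = dv.DistanceMatrix(pd.DataFrame(m, index=list("abcde"), columns=list("abcde")), "fst")
    res = dv.mantel_test(dm, dm, n_perm=99, seed=1)
    assert res.r == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)
    const = dv.DistanceMatrix(
        pd.DataFrame(np.zeros((5, 5)), index=list("abcde"), columns=list("abcde")), "fst"
    )
    with pytest.raises(ValueError, match="constant"):
        dv.mantel_test(dm, const, n_perm=9, seed=0)


def test_mantel_detects_isolation_by_distance(study_design, study_cohort, study_popmap):
    """Stepping-stone-like design: linearized F_ST correlates with
    great-circle distance across the five unadmixed native locations."""
    g, _ = study_cohort
    native = [p for p in study_popmap.populations if study_popmap.native[p] and p != "Nenjiang"]
    pm = study_popmap.subset(native)
    sub = g.take_individuals([i for i in g.individuals if i in pm.population_of.index])
    fst = dv.pairwise_fst(sub, pm)
    lin = dv.linearized_fst(fst)
    geo = dv.geographic_distance(study_design.site_table(), native)
    res = dv.mantel_test(geo, lin, n_perm=999, seed=5)
    assert res.r > 0.5
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# Nei distance and NJ tree
# ---------------------------------------------------------------------------


def test_nei_distance_zero_for_identical_frequencies():
    rng = np.random.default_rng(4)
    block = rng.binomial(2, 0.5, size=(20, 200)).astype(np.int8)
    dosage = np.vstack([block, block])
    g, pm = small_matrix(dosage, pops=["A"] * 20 + ["B"] * 20)
    dm = dv.nei_distance(g, pm)
    assert dm.values.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)


def test_nj_recovers_additive_four_taxon_tree():
    """NJ applied to an exactly additive distance matrix recovers the
    generating topology ((a,b),(c,d)) with the right branch lengths."""
    # branch lengths: a=2, b=3, internal=4, c=5, d=6
    taxa = ["a", "b", "c", "d"]
    m = pd.DataFrame(0.0, index=taxa, columns=taxa)
    m.loc["a", "b"] = m.loc["b", "a"] = 2 + 3
    m.loc["a", "c"] = m.loc["c", "a"] = 2 + 4 + 5
    m.loc["a", "d"] = m.loc["d", "a"] = 2 + 4 + 6
    m.loc["b", "c"] = m.loc["c", "b"] = 3 + 4 + 5
    m.loc["b", "d"] = m.loc["d", "b"] = 3 + 4 + 6
    m.loc["c", "d"] = m.loc["d", "c"] = 5 + 6
    tree = dv.nj_tree(dv.DistanceMatrix(m, "nei_standard"))
    dists = {
        frozenset([x, y]): tree.find(x).distance(tree.find(y))
        for i, x in enumerate(taxa)
        for y in taxa[i + 1 :]
    }
    for pair, want in [
        (("a", "b"), 5), (("a", "c"), 11), (("a", "d"), 12),
        (("b", "c"), 12), (("b", "d"), 13), (("c", "d"), 11),
    ]:
        assert dists[frozenset(pair)] == pytest.approx(want, abs=1e-9)


def test_nj_tree_groups_river_systems(study_cohort, study_popmap):
    """Bootstrap NJ separates the Yangtze+Heilongjiang side from the
    Pearl side (the introduced locations, founded with Pearl ancestry,
    attach on the Pearl side)."""
    g, _ = study_cohort
    tree, support = dv.nj_tree_with_support(g, study_popmap, n_bootstrap=100, seed=9)
    taxa = frozenset(str(p) for p in study_popmap.populations)
    north = frozenset(["Nenjiang", "Hanjiang", "Jiujiang", "Shishou"])
    key = min(north, taxa - north, key=lambda s: sorted(s))
    assert support.get(key, 0.0) > 0.8


def test_nj_three_taxa_closed_form():
    taxa = ["a", "b", "c"]
    m = pd.DataFrame(
        [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]], index=taxa, columns=taxa
    )
    tree = dv.nj_tree(dv.DistanceMatrix(m, "nei_standard"))
    # three-point formulas: d(a) = (3+4-5)/2 = 1, d(b) = 2, d(c) = 3
    assert tree.find("a").distance(tree.find("b")) == pytest.approx(3.0, abs=1e-9)
    assert tree.find("a").distance(tree.find("c")) == pytest.approx(4.0, abs=1e-9)
    assert tree.find("b").distance(tree.find("c")) == pytest.approx(5.0, abs=1e-9)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_separates_diverged_clusters():
    rng = np.random.default_rng(11)
    a = rng.binomial(2, 0.1, size=(15, 300))
    b = rng.binomial(2, 0.9, size=(15, 300))
    g = small_matrix(np.vstack([a, b]).astype(np.int8))
    res = dv.pca_genotypes(g)
    pc1 = res.coordinates["PC1"].to_numpy()
    assert (pc1[:15].mean() * pc1[15:].mean()) < 0  # opposite signs
    margin = abs(pc1[:15].mean() - pc1[15:].mean())
    spread = pc1[:15].std() + pc1[15:].std()
    assert margin > 3 * spread


def test_pca_duplicated_individual_identical_coordinates():
    rng = np.random.default_rng(13)
    base = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
    dosage = np.vstack([base, base[:1]])
    g = small_matrix(dosage)
    res = dv.pca_genotypes(g)
    np.testing.assert_allclose(
        res.coordinates.iloc[0].to_numpy(), res.coordinates.iloc[10].to_numpy(), atol=1e-8
    )


def test_pca_eigenvalues_sorted_nonnegative(study_cohort):
    g, _ = study_cohort
    res = dv.pca_genotypes(g.take_loci(np.arange(300)))
    ev = res.eigenvalues
    assert (ev >= -1e-12).all()
    assert (np.diff(ev) <= 1e-9).all()
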