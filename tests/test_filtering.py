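from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from ctenopop import filtering as flt
from ctenopop.core import MISSING, RunConfig

from conftest import small_matrix


# ---------------------------------------------------------------------------
# Call rate
# ---------------------------------------------------------------------------


def test_call_rate_strict_boundary():
    """8/10 typed (> 0.7) kept; exactly 7/10 (= 0.7, not >) removed."""
    dosage = np.zeros((10, 2), dtype=np.int8)
    dosage[:2, 0] = MISSING  # locus 0: 8/10 typed
    dosage[:3, 1] = MISSING  # locus 1: 7/10 typed
    g, pm = small_matrix(dosage, pops=["P"] * 10)
    kept = flt.filter_call_rate(g, pm, min_prop=0.7)
    assert list(kept.loci.index) == ["L000"]


def test_call_rate_per_population_brute_force():
    rng = np.random.default_rng(0)
    dosage = rng.integers(0, 3, size=(30, 80)).astype(np.int8)
    dosage[rng.random(dosage.shape) < 0.25] = MISSING
    pops = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
    g, pm = small_matrix(dosage, pops=pops)
    mask = flt.call_rate_mask(g, pm, 0.7)
    for j in range(80):
        expect = all(
            np.mean(dosage[np.array(pops) == p, j] != MISSING) > 0.7
            for p in "ABC"
        )
        assert mask[j] == expect


# ---------------------------------------------------------------------------
# Paralog tags and thinning
# ---------------------------------------------------------------------------


def test_paralog_whole_tag_removed_on_high_het():
    # tag t1: one SNP with H_O = 0.6 -> both t1 SNPs go; tag t2 clean
    dosage = np.array(
        [[1, 0, 0], [1, 0, 1], [1, 2, 2], [0, 0, 0], [1, 2, 1],
         [1, 0, 0], [0, 2, 1], [0, 0, 0], [1, 2, 2], [0, 0, 1]],
        dtype=np.int8,
    )
    assert (dosage[:, 0] == 1).mean() == 0.6
    g = small_matrix(dosage, tag_ids=["t1", "t1", "t2"])
    kept = flt.filter_paralog_tags(g)
    assert list(kept.loci["tag_id"]) == ["t2"]


def test_paralog_multiallelic_or_rule_and_literal_and():
    dosage = np.zeros((10, 2), dtype=np.int8)
    dosage[0, :] = 1
    g = small_matrix(dosage, tag_ids=["t1", "t2"])
    g.loci.loc["L000", "n_alleles"] = 3  # multi-allelic, H_O = 0.1
    assert list(flt.filter_paralog_tags(g).loci.index) == ["L001"]
    # literal AND keeps it (H_O <= 0.5)
    assert len(flt.filter_paralog_tags(g, literal_and=True).loci) == 2


def test_paralog_count_matches_hand_enumeration():
    """10 tags, 3 planted violations -> exactly 7 tags survive."""
    rng = np.random.default_rng(2)
    n, L = 20, 20  # 10 tags x 2 SNPs
    dosage = rng.binomial(2, 0.15, size=(n, L)).astype(np.int8)
    assert (flt.observed_het(small_matrix(dosage)) <= 0.5).all()
    tags = [f"t{j // 2}" for j in range(L)]
    bad_tags = {"t1", "t4", "t8"}
    for j, t in enumerate(tags):
        if t in bad_tags and j % 2 == 0:
            dosage[:, j] = 1  # H_O = 1
    g = small_matrix(dosage, tag_ids=tags)
    kept = flt.filter_paralog_tags(g)
    assert set(kept.loci["tag_id"]) == {f"t{k}" for k in range(10)} - bad_tags


def test_thinning_keeps_lowest_coordinate_and_is_idempotent():
    dosage = np.zeros((4, 3), dtype=np.int8)
    g = small_matrix(dosage, tag_ids=["t", "t", "t"], positions=[57, 12, 88])
    once = flt.thin_first_snp_per_tag(g)
    assert list(once.loci["position"]) == [12]
    twice = flt.thin_first_snp_per_tag(once)
    assert list(twice.loci.index) == list(once.loci.index)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def levene_pvalue_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional heterozygote-count
    distribution; independent of the implementation under test."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    weights = {}
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        from math import factorial

        weights[h] = (
            Fraction(factorial(n), factorial(naa) * factorial(h) * factorial(nbb))
            * Fraction(2) ** h
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize(
    "counts",
    [(3, 4, 3), (0, 10, 0), (5, 0, 5), (2, 7, 1), (8, 1, 11), (0, 1, 19)],
)
def test_hwe_exact_pvalue_matches_enumeration_oracle(counts):
    got = flt.hwe_exact_pvalue(*counts)
    want = levene_pvalue_oracle(*counts)
    assert got == pytest.approx(want, abs=1e-12)


def test_hwe_all_heterozygous_removed_at_alpha_001():
    """n = 20 all heterozygous is an extreme HWE deviation."""
    assert flt.hwe_exact_pvalue(0, 20, 0) < 0.01
    dosage = np.ones((20, 1), dtype=np.int8)
    g, pm = small_matrix(dosage, pops=["P"] * 20)
    assert flt.hwe_exact_filter(g, pm, alpha=0.01).n_loci == 0


def test_hwe_proportioned_sample_kept():
    dosage = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)[:, None]
    g, pm = small_matrix(dosage, pops=["P"] * 100)
    assert flt.hwe_exact_filter(g, pm, alpha=0.01).n_loci == 1


def test_hwe_monomorphic_defined_as_one():
    assert flt.hwe_exact_pvalue(10, 0, 0) == 1.0


def test_hwe_exactly_one_rule():
    """A locus deviating in two populations is kept under the
    'exactly one' reading but removed under the inclusive default."""
    dosage = np.ones((40, 1), dtype=np.int8)  # all het in both pops
    g, pm = small_matrix(dosage, pops=["A"] * 20 + ["B"] * 20)
    assert flt.hwe_exact_filter(g, pm, rule="any").n_loci == 0
    assert flt.hwe_exact_filter(g, pm, rule="exactly_one").n_loci == 1


# ---------------------------------------------------------------------------
# MAF / missingness / LD
# ---------------------------------------------------------------------------


def test_maf_strict_boundary_and_monomorphic():
    dosage = np.zeros((10, 3), dtype=np.int8)
    dosage[0, 0] = 1  # 1/20 alleles = 0.05 exactly -> removed
    dosage[0, 1] = 2  # 2/20 = 0.10 -> kept
    g = small_matrix(dosage)
    kept = flt.filter_maf(g, 0.05)
    assert list(kept.loci.index) == ["L001"]  # monomorphic L002 removed too


def test_maf_brute_force_recount():
    rng = np.random.default_rng(5)
    dosage = rng.binomial(2, rng.uniform(0.01, 0.5, 60), size=(25, 60)).astype(np.int8)
    dosage[rng.random(dosage.shape) < 0.1] = MISSING
    g = small_matrix(dosage)
    mask = flt.maf_mask(g, 0.05)
    for j in range(60):
        col = dosage[:, j]
        called = col[col != MISSING]
        p = called.sum() / (2 * len(called))
        assert mask[j] == (min(p, 1 - p) > 0.05)


def test_ld_prune_removes_duplicate_and_respects_postcondition():
    rng = np.random.default_rng(6)
    base = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
    dosage = np.column_stack([base, base[:, 0]])  # duplicate of first column
    g = small_matrix(dosage, scaffolds=["s"] * 11)
    kept = flt.ld_prune(g, r2_max=0.5)
    assert "L010" not in kept.loci.index
    # postcondition replay: no kept pair within the window has r2 >= cutoff
    d = kept.dosage
    for i in range(kept.n_loci):
        for j in range(i + 1, kept.n_loci):
            assert flt.genotype_r2(d[:, i], d[:, j]) < 0.5


def test_ld_prune_independent_loci_mostly_kept():
    rng = np.random.default_rng(7)
    dosage = rng.binomial(2, 0.5, size=(200, 100)).astype(np.int8)
    g = small_matrix(dosage, scaffolds=["s"] * 100)
    kept = flt.ld_prune(g, r2_max=0.05)
    # chance r2 >= 0.05 at n=200 is ~0.2%, so very few removals
    assert kept.n_loci >= 90


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def hwe_clean_column(n=20, rotate=0):
    """Deterministic HWE-proportioned column: 5 AA, 10 Aa, 5 aa (H_O = 0.5,
    exactly the Hardy–Weinberg expectation at p = 0.5)."""
    col = np.array([0] * 5 + [1] * 10 + [2] * 5, dtype=np.int8)
    return np.roll(col, rotate)


def build_violation_fixture():
    """Hand-constructed matrix with one planted violation per rule."""
    n = 20
    clean = np.column_stack([hwe_clean_column(n, r) for r in range(6)])
    dosage = clean.copy()
    dosage[:15, 0] = MISSING  # call-rate violation (5/20 = 0.25 typed)
    dosage[:, 1] = 1  # H_O = 1 -> paralog tag (tag shared with locus 2)
    dosage[:, 3] = 1  # HWE violation on its own tag... also paralog H_O=1
    tags = ["t0", "t1", "t1", "t2", "t3", "t4"]
    g, pm = small_matrix(dosage, pops=["P"] * n, tag_ids=tags)
    return g, pm


def test_cascade_counts_match_hand_enumeration():
    g, pm = build_violation_fixture()
    out, report = flt.run_filter_cascade(g, pm)
    stages = {s["stage"]: s for s in report.stages}
    assert stages["call_rate"]["loci_removed"] == 1  # L0
    # L1 is H_O=1 -> tag t1 (L1+L2) removed; L3 (H_O=1, tag t2) removed
    assert stages["paralog_tags"]["loci_removed"] == 3
    assert stages["first_snp_per_tag"]["loci_removed"] == 0
    assert stages["hwe_exact"]["loci_removed"] == 0  # violators already gone
    assert list(out.loci.index) == ["L004", "L005"]


def test_cascade_identity_on_clean_matrix():
    dosage = np.column_stack([hwe_clean_column(20, r) for r in range(8)])
    g, pm = small_matrix(dosage, pops=["P"] * 20, tag_ids=[f"t{j}" for j in range(8)])
    out, report = flt.run_filter_cascade(g, pm)
    assert out.n_loci == g.n_loci
    np.testing.assert_array_equal(out.dosage, g.dosage)
    for s in report.stages:
        assert s["loci_out"] == s["loci_in"] - s["loci_removed"]


def test_cascade_equals_stagewise_composition(study_design):
    from ctenopop import synthetic as syn

    g, _ = syn.simulate_metapopulation(study_design, 400, seed=21, missing_rate=0.05)
    pm = study_design.population_map()
    cfg = RunConfig()
    cascade, _rep = flt.run_filter_cascade(g, pm, cfg)
    manual = flt.hwe_exact_filter(
        flt.thin_first_snp_per_tag(
            flt.filter_paralog_tags(flt.filter_call_rate(g, pm, cfg.call_rate_min))
        ),
        pm,
        cfg.hwe_alpha,
    )
    assert list(cascade.loci.index) == list(manual.loci.index)


def test_cascade_error_when_stage_empties(study_design):
    dosage = np.full((20, 2), MISSING, dtype=np.int8)
    dosage[0, :] = 1
    g, pm = small_matrix(dosage, pops=["P"] * 20)
    with pytest.raises(ValueError, match="call_rate"):
        flt.run_filter_cascade(g, pm)


def test_filters_never_modify_surviving_genotypes(study_cohort, study_popmap):
    g, _ = study_cohort
    kept = flt.filter_maf(g, 0.05)
    np.testing.assert_array_equal(
        kept.dosage, g.dosage[:, g.loci.index.get_indexer(kept.loci.index)]
    )
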