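import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from ctenopop import origins as og
from ctenopop.diversity import wc_fst_grouped


@pytest.fixture(scope="module")
def specs():
    return og.default_scenarios()


@pytest.fixture(scope="module")
def priors():
    return og.PriorSet()


@pytest.fixture(scope="module")
def small_reference(specs, priors):
    return og.build_reference_table(
        specs, priors, n_sims=900, n_loci=250, n_diploids=15, seed=77
    )


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


def test_prior_draws_satisfy_ordering_constraints(priors):
    rng = np.random.default_rng(0)
    for _ in range(300):
        d = priors.sample(rng)
        assert d["t3"] > d["t2"] > d["t1"] > d["db"]
        assert min(d["N_A"], d["N_B"], d["N_I"]) > d["N_m"]
        assert 0 < d["r"] < 1


def test_prior_acceptance_rate_matches_analytic():
    """P(N > Nm) for two iid discrete uniforms on [10, 10000] is
    (1 - 1/n) / 2; the Monte-Carlo acceptance of that single constraint
    matches."""
    rng = np.random.default_rng(1)
    lo, hi = 10, 10_000
    n = hi - lo + 1
    draws = rng.integers(lo, hi + 1, size=(40_000, 2))
    acc = (draws[:, 0] > draws[:, 1]).mean()
    assert acc == pytest.approx((1 - 1 / n) / 2, abs=0.01)


def test_prior_fixed_seed_determinism(priors):
    assert og.sample_prior(priors, 123) == og.sample_prior(priors, 123)


def test_unsatisfiable_priors_error():
    bad = og.PriorSet(time_range=(1, 2), max_rejections=2000)
    # t3 > t2 > t1 > db cannot hold with only {1, 2} available
    with pytest.raises(RuntimeError, match="unsatisfiable"):
        og.sample_prior(bad, 0)


# ---------------------------------------------------------------------------
# Scenario simulation
# ---------------------------------------------------------------------------


def test_single_population_halves_have_no_structure(specs, priors):
    """Sampling one panmictic population and splitting it in two gives
    theta ~ 0."""
    params = dict(N_A=2000, N_B=2000, N_I=2000, N_m=100, t1=50, t2=80, db=20, t3=4000, r=0.5)
    g = og.simulate_scenario(specs[0], params, 600, 20, seed=5)
    # halves of population A
    rows_a = np.arange(0, 10)
    rows_b = np.arange(10, 20)
    _pl, theta = wc_fst_grouped(g, rows_a, rows_b)
    assert abs(theta) < 0.02


def test_admixture_rate_extremes_degenerate_to_pure_splits(specs, priors):
    """Scenario 1 with r = 1 is scenario 2 (every admixing lineage takes
    the Yangtze-side source — bitwise-identical simulation under a shared
    seed); with r = 0 it is scenario 3 in distribution (KS on the
    discriminating statistics)."""
    params = dict(N_A=2000, N_B=2000, N_I=2000, N_m=200, t1=60, t2=90, db=20, t3=3000, r=1.0)
    g1 = og.simulate_scenario(specs[0], params, 300, 12, seed=42)
    g2 = og.simulate_scenario(specs[1], params, 300, 12, seed=42)
    np.testing.assert_array_equal(g1.dosage, g2.dosage)

    params["r"] = 0.0
    pm = og.scenario_popmap(12)
    s1, s3 = [], []
    for k in range(40):
        ga = og.simulate_scenario(specs[0], params, 200, 12, seed=1000 + k)
        gb = og.simulate_scenario(specs[2], params, 200, 12, seed=5000 + k)
        s1.append(og.summary_stats(ga, pm))
        s3.append(og.summary_stats(gb, pm))
    s1, s3 = pd.DataFrame(s1), pd.DataFrame(s3)
    checked = ["theta_A_I", "theta_B_I"]
    for col in checked:
        p = ks_2samp(s1[col], s3[col]).pvalue
        assert p > 0.01 / len(checked), f"{col} distributions differ"


def test_sample_larger_than_2n_errors(specs):
    params = dict(N_A=5, N_B=2000, N_I=2000, N_m=2, t1=50, t2=80, db=20, t3=4000, r=0.5)
    with pytest.raises(ValueError, match="sample larger"):
        og.simulate_scenario(specs[0], params, 10, 20, seed=1)


def test_coalescent_agrees_with_msprime_oracle(specs):
    """Two-population split: mean multi-locus theta from this package's
    coalescent matches msprime on identical parameters within 3
    Monte-Carlo standard errors, for three parameter sets."""
    import msprime

    cases = [
        dict(N=1000, t=500),
        dict(N=2000, t=2000),
        dict(N=500, t=1500),
    ]
    n_dip, n_loci, n_rep = 10, 400, 6
    for case in cases:
        params = dict(
            N_A=case["N"], N_B=case["N"], N_I=case["N"], N_m=case["N"] // 2,
            t1=2, t2=3, db=1, t3=case["t"], r=1.0,
        )
        # our simulator: use populations A and B only (I merges instantly)
        thetas = []
        for rep in range(n_rep):
            g = og.simulate_scenario(specs[1], params, n_loci, n_dip, seed=100 + rep)
            _pl, th = wc_fst_grouped(g, np.arange(0, n_dip), np.arange(n_dip, 2 * n_dip))
            thetas.append(th)
        ours = np.array(thetas)

        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=case["N"])
        dem.add_population(name="B", initial_size=case["N"])
        dem.add_population(name="anc", initial_size=case["N"])
        dem.add_population_split(time=case["t"], derived=["A", "B"], ancestral="anc")
        ms_thetas = []
        for rep in range(n_rep):
            a_sum = np.zeros(3)
            n_acc, p_acc, h_acc = [], [], []
            dos_cols = []
            for ts in msprime.sim_ancestry(
                samples={"A": n_dip, "B": n_dip},
                demography=dem,
                num_replicates=n_loci,
                random_seed=200 + rep,
                ploidy=2,
            ):
                mts = msprime.sim_mutations(
                    ts, rate=0.25 / case["N"], random_seed=300 + rep, discrete_genome=False
                )
                if mts.num_sites == 0:
                    continue
                gm = mts.genotype_matrix()  # sites x haplotypes
                dos = gm[:, 0::2] + gm[:, 1::2]
                dos_cols.append(np.minimum(dos, 2))
            dos = np.vstack(dos_cols).T  # individuals x sites
            _pl, th = wc_fst_grouped(
                _as_matrix(dos), np.arange(0, n_dip), np.arange(n_dip, 2 * n_dip)
            )
            ms_thetas.append(th)
        ms = np.array(ms_thetas)
        se = np.sqrt(ours.var(ddof=1) / n_rep + ms.var(ddof=1) / n_rep)
        assert abs(ours.mean() - ms.mean()) < 3 * max(se, 1e-3), (
            f"case {case}: ours {ours.mean():.4f} vs msprime {ms.mean():.4f}"
        )


def _as_matrix(dosage):
    from ctenopop.core import GenotypeMatrix, make_locus_table

    n, L = dosage.shape
    return GenotypeMatrix(
        [f"i{k}" for k in range(n)],
        make_locus_table([f"L{j}" for j in range(L)]),
        dosage.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def test_summary_stats_identical_populations_near_zero_distance():
    rng = np.random.default_rng(4)
    block = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(10, 300)).astype(np.int8)
    dosage = np.vstack([block, block, block])
    g = _as_matrix(dosage)
    g.individuals = [f"{p}_{i:03d}" for p in "ABI" for i in range(10)]
    pm = og.scenario_popmap(10)
    s = og.summary_stats(g, pm)
    for name in ["theta_A_B", "theta_A_I", "theta_B_I"]:
        # Weir–Cockerham theta is slightly negative for identical samples
        # (expectation about -1/(2n - 1)); it must not be positive
        assert -0.1 < s[name] < 0.01
    for name in ["nei_A_B", "nei_A_I", "nei_B_I"]:
        assert abs(s[name]) < 0.01


def test_summary_vector_length_and_determinism(specs, priors):
    params = og.sample_prior(priors, 3)
    g = og.simulate_scenario(specs[0], params, 150, 10, seed=9)
    pm = og.scenario_popmap(10)
    panel = og.StatPanel()
    s1 = og.summary_stats(g, pm, panel)
    s2 = og.summary_stats(g, pm, panel)
    assert len(s1) == len(panel.names(["A", "B", "I"])) == 21
    pd.testing.assert_series_equal(s1, s2)
    assert not s1.isna().any()


# ---------------------------------------------------------------------------
# Reference table and model choice
# ---------------------------------------------------------------------------


def test_reference_table_stratified_counts_and_shape(small_reference, specs):
    counts = small_reference["scenario"].value_counts()
    assert (counts == 300).all()
    # columns: scenario + 9 parameters + 21 statistics
    assert small_reference.shape[1] == 1 + 9 + 21


def test_reference_table_reproducible(specs, priors):
    a = og.build_reference_table(specs, priors, n_sims=30, n_loci=60, n_diploids=6, seed=5)
    b = og.build_reference_table(specs, priors, n_sims=30, n_loci=60, n_diploids=6, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_model_choice_probabilities_sum_to_one(small_reference, specs, priors):
    params = og.sample_prior(priors, 21)
    g = og.simulate_scenario(specs[2], params, 250, 15, seed=31)
    obs = og.summary_stats(g, og.scenario_popmap(15))
    res = og.model_choice(small_reference, obs, top_frac=0.05)
    assert res.posterior.sum() == pytest.approx(1.0, abs=1e-6)
    assert ((res.ci["lo"] >= 0) & (res.ci["hi"] <= 1)).all()


def test_model_choice_identifies_distinct_scenario(small_reference, specs):
    """A pod from a well-separated admixture history gets posterior > 0.9
    for the admixture scenario."""
    params = dict(N_A=5000, N_B=5000, N_I=5000, N_m=1000, t1=30, t2=60, db=10, t3=5000, r=0.5)
    g = og.simulate_scenario(specs[0], params, 250, 15, seed=41)
    obs = og.summary_stats(g, og.scenario_popmap(15))
    res = og.model_choice(small_reference, obs, top_frac=0.05)
    assert res.selected == "scenario1_admixture"
    assert res.posterior["scenario1_admixture"] > 0.9


def test_identical_scenarios_split_posterior(priors):
    """Two copies of the same scenario are indistinguishable: posterior
    splits about evenly."""
    twins = [og.ScenarioSpec("s_a", "split_A"), og.ScenarioSpec("s_b", "split_A")]
    ref = og.build_reference_table(twins, priors, n_sims=600, n_loci=150, n_diploids=10, seed=8)
    ps = []
    for k in range(6):
        params = og.sample_prior(priors, 55 + k)
        g = og.simulate_scenario(twins[0], params, 150, 10, seed=66 + k)
        obs = og.summary_stats(g, og.scenario_popmap(10))
        ps.append(og.model_choice(ref, obs, top_frac=0.1).posterior["s_a"])
    assert abs(np.mean(ps) - 0.5) < 0.2


def test_confusion_errors_symmetric_for_identical_scenarios(priors):
    twins = [og.ScenarioSpec(f"s{i}", "split_A") for i in range(3)]
    ref = og.build_reference_table(twins, priors, n_sims=450, n_loci=100, n_diploids=8, seed=9)
    errs = og.confusion_errors(
        twins, priors, ref, n_pods=15, n_loci=100, n_diploids=8, seed=10, top_frac=0.1
    )
    # with identical scenarios assignment is chance: type I ~ 2/3
    assert errs["type_I"].mean() == pytest.approx(2 / 3, abs=0.2)
    assert ((errs["type_I"] >= 0) & (errs["type_I"] <= 1)).all()


def test_parameter_posterior_from_full_prior_matches_prior(small_reference, specs, priors):
    """top_frac = 1 keeps everything: the 'posterior' is the prior."""
    params = og.sample_prior(priors, 77)
    g = og.simulate_scenario(specs[0], params, 250, 15, seed=88)
    obs = og.summary_stats(g, og.scenario_popmap(15))
    est = og.estimate_parameters(
        small_reference, obs, "scenario1_admixture", top_frac=1.0, adjust=False
    )
    # r prior is uniform(0.01, 0.99): median ~ 0.5, wide interval
    assert est.loc["r", "median"] == pytest.approx(0.5, abs=0.1)
    assert est.loc["r", "q975"] - est.loc["r", "q025"] > 0.8


def test_model_check_pca_observed_inside_cloud(small_reference, specs, priors):
    params = og.sample_prior(priors, 99)
    g = og.simulate_scenario(specs[0], params, 250, 15, seed=111)
    obs = og.summary_stats(g, og.scenario_popmap(15))
    coords, obs_xy, _ = og.model_check_pca(small_reference, obs)
    for dim in range(2):
        lo, hi = coords[:, dim].min(), coords[:, dim].max()
        assert lo <= obs_xy[dim] <= hi
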