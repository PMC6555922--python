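"""ABC model choice for the origin of the introduced populations.

Three competing demographic scenarios for an introduced population I
sampled together with a Yangtze-cluster population A and a Pearl-cluster
population B (all times in generations, backwards from sampling):

* scenario 1 (``admixture``): I founded at t1 as an admixture of A
  (rate r) and B (rate 1 - r);
* scenario 2 (``split_A``): I founded at t1 from A alone;
* scenario 3 (``split_B``): I founded at t1 from B alone;

with a founder bottleneck (size Nm from the founding at t1 until t1 - db)
and the deep split of A and B at t3.  Uniform priors with the ordering
constraints t3 > t2 > t1 > db and N > Nm.

Inference is rejection ABC on a simulated reference table followed by a
multinomial logistic regression of scenario identity on summary-statistic
differences among the retained simulations, read out at difference zero;
parameter posteriors use the classic local-linear regression adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PopulationMap, make_locus_table
from .coalescent import carriers_to_dosage, simulate_carriers
from .diversity import _nei_from_freqs, _pop_counts, _wc_components

PARAM_NAMES = ["N_A", "N_B", "N_I", "N_m", "t1", "t2", "db", "t3", "r"]


@dataclass
class ScenarioSpec:
    """One competing demographic scenario."""

    name: str
    kind: str  # admixture | split_A | split_B

    def __post_init__(self):
        if self.kind not in ("admixture", "split_A", "split_B"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")

    def events(self, params: dict):
        """Flat event list for the coalescent kernel.

        Populations: 0 = A (Yangtze cluster), 1 = B (Pearl cluster),
        2 = I (introduced).
        """
        t1, db, t3 = params["t1"], params["db"], params["t3"]
        ev = [(t1 - db, 0, 2, 0, params["N_m"])]  # founder bottleneck
        if self.kind == "admixture":
            ev.append((t1, 1, 2, 0, params["r"]))
            ev.append((t1, 1, 2, 1, 1.0))
        elif self.kind == "split_A":
            ev.append((t1, 1, 2, 0, 1.0))
        else:
            ev.append((t1, 1, 2, 1, 1.0))
        ev.append((t3, 1, 1, 0, 1.0))  # deep split of A and B
        return ev


def default_scenarios():
    return [
        ScenarioSpec("scenario1_admixture", "admixture"),
        ScenarioSpec("scenario2_yangtze", "split_A"),
        ScenarioSpec("scenario3_pearl", "split_B"),
    ]


@dataclass
class PriorSet:
    """Uniform priors with ordering constraints, rejection-sampled."""

    size_range: tuple = (10, 10_000)  # N and Nm
    time_range: tuple = (1, 150)  # t1, t2, db
    deep_range: tuple = (10, 10_000)  # t3
    r_range: tuple = (0.01, 0.99)
    max_rejections: int = 1_000_000

    def sample(self, rng) -> dict:
        """One accepted draw: integers for sizes and times, continuous r,
        rejected until t3 > t2 > t1 > db and every N > Nm."""
        lo_s, hi_s = self.size_range
        lo_t, hi_t = self.time_range
        lo_d, hi_d = self.deep_range
        for _ in range(self.max_rejections):
            draw = {
                "N_A": int(rng.integers(lo_s, hi_s + 1)),
                "N_B": int(rng.integers(lo_s, hi_s + 1)),
                "N_I": int(rng.integers(lo_s, hi_s + 1)),
                "N_m": int(rng.integers(lo_s, hi_s + 1)),
                "t1": int(rng.integers(lo_t, hi_t + 1)),
                "t2": int(rng.integers(lo_t, hi_t + 1)),
                "db": int(rng.integers(lo_t, hi_t + 1)),
                "t3": int(rng.integers(lo_d, hi_d + 1)),
                "r": float(rng.uniform(*self.r_range)),
            }
            if (
                draw["t3"] > draw["t2"] > draw["t1"] > draw["db"]
                and min(draw["N_A"], draw["N_B"], draw["N_I"]) > draw["N_m"]
            ):
                return draw
        raise RuntimeError("prior constraints appear unsatisfiable")


def sample_prior(priors: PriorSet, seed) -> dict:
    return priors.sample(np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Scenario simulation
# ---------------------------------------------------------------------------


def simulate_scenario(
    spec: ScenarioSpec,
    params: dict,
    n_loci: int,
    n_diploids: int,
    seed: int,
    pop_names=("A", "B", "I"),
) -> GenotypeMatrix:
    """Simulate one dataset: equal diploid samples from A, B and I."""
    samp = [2 * n_diploids] * 3
    sizes = [params["N_A"], params["N_B"], params["N_I"]]
    carriers = simulate_carriers(n_loci, samp, sizes, spec.events(params), seed)
    dosage = carriers_to_dosage(carriers)
    individuals = [f"{p}_{i:03d}" for p in pop_names for i in range(n_diploids)]
    return GenotypeMatrix(
        individuals, make_locus_table([f"S{j:05d}" for j in range(n_loci)]), dosage
    )


def scenario_popmap(n_diploids: int, pop_names=("A", "B", "I")) -> PopulationMap:
    return PopulationMap(
        population_of=pd.Series(
            {f"{p}_{i:03d}": p for p in pop_names for i in range(n_diploids)}
        ),
        group_of=pd.Series({p: p for p in pop_names}),
        native=pd.Series({"A": True, "B": True, "I": False}),
    )


# ---------------------------------------------------------------------------
# Summary statistics (shared estimators with ctenopop.diversity)
# ---------------------------------------------------------------------------


@dataclass
class StatPanel:
    """Which statistic families go into the summary vector."""

    diversity_mean: bool = True
    diversity_var: bool = True
    pairwise_theta: bool = True
    pairwise_nei: bool = True
    maf_deciles: int = 9

    def names(self, pops) -> list:
        pops = list(pops)
        out = []
        if self.diversity_mean:
            out += [f"He_mean_{p}" for p in pops]
        if self.diversity_var:
            out += [f"He_var_{p}" for p in pops]
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
        if self.pairwise_theta:
            out += [f"theta_{a}_{b}" for a, b in pairs]
        if self.pairwise_nei:
            out += [f"nei_{a}_{b}" for a, b in pairs]
        out += [f"maf_q{i+1}" for i in range(self.maf_deciles)]
        return out


def summary_stats(
    g: GenotypeMatrix, popmap: PopulationMap, panel: StatPanel | None = None
) -> pd.Series:
    """Deterministic summary vector: per-population genic diversity
    (mean and variance over loci), pairwise multi-locus theta, pairwise
    Nei standard distance, pooled MAF deciles.  Monomorphic or degenerate
    entries get defined defaults (0), never NaN."""
    panel = panel or StatPanel()
    rows = popmap.row_indices(g)
    pops = list(rows)
    n, p, h = _pop_counts(g, rows)
    valid = n > 0
    vals: list = []
    if panel.diversity_mean or panel.diversity_var:
        he = 2.0 * p * (1.0 - p) * np.where(n > 0, 2 * n / np.maximum(2 * n - 1, 1), 0.0)
        he = np.where(valid, he, np.nan)
        if panel.diversity_mean:
            vals += list(np.nan_to_num(np.nanmean(he, axis=1), nan=0.0))
        if panel.diversity_var:
            vals += list(np.nan_to_num(np.nanvar(he, axis=1), nan=0.0))
    pair_idx = [(i, j) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    if panel.pairwise_theta:
        for i, j in pair_idx:
            a, b, c = _wc_components(n[[i, j]], p[[i, j]], h[[i, j]])
            ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
            denom = (a[ok] + b[ok] + c[ok]).sum()
            vals.append(float(a[ok].sum() / denom) if denom != 0 else 0.0)
    if panel.pairwise_nei:
        nei = _nei_from_freqs(np.clip(p, 1e-9, 1 - 1e-9), valid)
        vals += [float(nei[i, j]) for i, j in pair_idx]
    if panel.maf_deciles:
        maf = g.minor_allele_freq()
        maf = maf[np.isfinite(maf)]
        qs = np.linspace(0.1, 0.9, panel.maf_deciles)
        vals += list(np.quantile(maf, qs)) if maf.size else [0.0] * panel.maf_deciles
    return pd.Series(vals, index=panel.names(pops), dtype=float)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


def build_reference_table(
    specs,
    priors: PriorSet,
    n_sims: int,
    n_loci: int,
    n_diploids: int,
    seed: int,
    panel: StatPanel | None = None,
) -> pd.DataFrame:
    """Stratified reference table: n_sims rows of (scenario, parameters,
    summary statistics), scenarios simulated in equal numbers."""
    if len(specs) < 2:
        raise ValueError("need at least 2 scenarios")
    panel = panel or StatPanel()
    rng = np.random.default_rng(seed)
    popmap = scenario_popmap(n_diploids)
    per = n_sims // len(specs)
    rows = []
    for s_i, spec in enumerate(specs):
        for k in range(per):
            params = priors.sample(rng)
            sim_seed = int(rng.integers(2**31 - 1))
            g = simulate_scenario(spec, params, n_loci, n_diploids, sim_seed)
            stats = summary_stats(g, popmap, panel)
            row = {"scenario": spec.name, **params, **stats.to_dict()}
            rows.append(row)
    return pd.DataFrame(rows)


def _stat_columns(reference: pd.DataFrame) -> list:
    return [c for c in reference.columns if c not in ["scenario"] + PARAM_NAMES]


def _leading_components(z: np.ndarray, max_dim: int) -> np.ndarray:
    """Project standardized stat differences onto their leading singular
    axes (keeps regression designs full-rank at small retained counts).

    The SVD is deliberately uncentered: the readout/evaluation point of
    every downstream regression is stat-difference zero, which must map
    to the origin of the reduced space.
    """
    u, s, _vt = np.linalg.svd(z, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        return np.zeros((z.shape[0], 1))
    k = int(min(max_dim, (s > 1e-8 * s[0]).sum()))
    return u[:, :k] * s[:k]


def _standardized_distances(reference, observed, stat_cols):
    ref = reference[stat_cols].to_numpy(dtype=float)
    obs = observed[stat_cols].to_numpy(dtype=float) if isinstance(observed, pd.Series) else np.asarray(observed, dtype=float)
    sd = ref.std(axis=0)
    sd[sd == 0] = 1.0
    z = (ref - obs) / sd
    return np.sqrt((z**2).sum(axis=1)), z


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelChoiceResult:
    posterior: pd.Series  # per-scenario probability
    ci: pd.DataFrame  # columns lo, hi
    selected: str
    n_retained: int
    degenerate: list = field(default_factory=list)


def model_choice(
    reference: pd.DataFrame,
    observed: pd.Series,
    top_frac: float = 0.01,
) -> ModelChoiceResult:
    """Posterior scenario probabilities by rejection + logistic regression.

    Euclidean distance on standardized statistics selects the closest
    ``top_frac`` simulations; a multinomial logistic regression of
    scenario identity on (statistic - observed) among those is read out
    at difference zero.  The CI comes from the regression's parameter
    covariance via the delta method.
    """
    scen_names = list(dict.fromkeys(reference["scenario"]))
    n_keep = max(int(round(top_frac * len(reference))), len(scen_names) + 2)
    if len(reference) < 100 * len(scen_names) * top_frac:
        pass  # tiny tables still work; CI will just be wide
    stat_cols = _stat_columns(reference)
    dist, z = _standardized_distances(reference, observed, stat_cols)
    keep = np.argsort(dist)[:n_keep]
    zk = z[keep]
    yk = reference["scenario"].to_numpy()[keep]

    counts = pd.Series(yk).value_counts()
    present = [s for s in scen_names if s in counts.index]
    degenerate = [s for s in scen_names if s not in counts.index]

    probs = pd.Series(0.0, index=scen_names)
    ci = pd.DataFrame({"lo": 0.0, "hi": 0.0}, index=scen_names)

    if len(present) == 1:
        probs[present[0]] = 1.0
        ci.loc[present[0]] = [1.0, 1.0]
        for s in degenerate:
            ci.loc[s] = [0.0, 0.0]
        return ModelChoiceResult(probs, ci, present[0], n_keep, degenerate)

    y_codes = np.array([present.index(s) for s in yk])
    # regress on leading principal components of the stat differences so
    # the design stays well conditioned at small retained counts
    X = _leading_components(zk, max_dim=min(8, max(2, n_keep // 10)))
    import statsmodels.api as sm

    Xd = sm.add_constant(X, has_constant="add")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(y_codes, Xd).fit(disp=0, maxiter=200, method="lbfgs")
        params = np.asarray(fit.params)  # (k_vars, J-1)
        eta = np.concatenate([[0.0], params[0, :]])  # intercepts at diff 0
        e = np.exp(eta - eta.max())
        pi = e / e.sum()
        cov = np.asarray(fit.cov_params())
        k_vars = Xd.shape[1]
        j1 = len(present) - 1
        # gradient of pi_s wrt the intercept of equation j
        var = np.zeros(len(present))
        for s in range(len(present)):
            grad = np.zeros(k_vars * j1)
            for j in range(j1):
                dpi = pi[s] * ((1.0 if s == j + 1 else 0.0) - pi[j + 1])
                grad[j * k_vars + 0] = dpi  # intercept is the first variable
            var[s] = float(grad @ cov @ grad)
        half = 1.96 * np.sqrt(np.maximum(var, 0.0))
        for s_i, s in enumerate(present):
            probs[s] = pi[s_i]
            ci.loc[s] = [max(pi[s_i] - half[s_i], 0.0), min(pi[s_i] + half[s_i], 1.0)]
    except Exception:
        # quasi-separation (one scenario dominating the retained set) or a
        # singular design: penalized multinomial regression still gives the
        # read-out probability at difference zero; CI degenerates
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=10.0, max_iter=500)
        clf.fit(X, y_codes)
        pi = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        class_order = list(clf.classes_)
        for s_i, s in enumerate(present):
            val = pi[class_order.index(s_i)] if s_i in class_order else 0.0
            probs[s] = val
            ci.loc[s] = [val, val]
        degenerate = degenerate + ["_penalized_fallback"]
    probs = probs / probs.sum()
    return ModelChoiceResult(probs, ci, probs.idxmax(), n_keep, degenerate)


def confusion_errors(
    specs,
    priors: PriorSet,
    reference: pd.DataFrame,
    n_pods: int,
    n_loci: int,
    n_diploids: int,
    seed: int,
    top_frac: float = 0.01,
    panel: StatPanel | None = None,
) -> pd.DataFrame:
    """Type I / type II error per scenario from pseudo-observed datasets.

    ``n_pods`` pods are simulated per scenario with prior-drawn
    parameters and classified against the reference table.  Type I for S
    is the fraction of S-generated pods not assigned to S; type II the
    fraction of non-S pods assigned to S.
    """
    panel = panel or StatPanel()
    rng = np.random.default_rng(seed)
    popmap = scenario_popmap(n_diploids)
    names = [s.name for s in specs]
    assigned = {s: [] for s in names}
    for spec in specs:
        for _ in range(n_pods):
            params = priors.sample(rng)
            g = simulate_scenario(
                spec, params, n_loci, n_diploids, int(rng.integers(2**31 - 1))
            )
            obs = summary_stats(g, popmap, panel)
            res = model_choice(reference, obs, top_frac)
            assigned[spec.name].append(res.selected)
    out = []
    for s in names:
        own = np.array(assigned[s])
        others = np.concatenate([np.array(assigned[o]) for o in names if o != s])
        out.append(
            {
                "scenario": s,
                "type_I": float((own != s).mean()),
                "type_II": float((others == s).mean()),
                "n_pods": n_pods,
            }
        )
    return pd.DataFrame(out).set_index("scenario")


# ---------------------------------------------------------------------------
# Parameter estimation and model checking
# ---------------------------------------------------------------------------

_LOG_PARAMS = {"N_A", "N_B", "N_I", "N_m", "t1", "t2", "db", "t3"}
_LOGIT_PARAMS = {"r"}


def _to_working(name, x):
    if name in _LOGIT_PARAMS:
        x = np.clip(x, 1e-6, 1 - 1e-6)
        return np.log(x / (1 - x))
    return np.log(np.maximum(x, 1e-9))


def _from_working(name, y):
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + np.exp(-y))
    return np.exp(y)


def estimate_parameters(
    reference: pd.DataFrame,
    observed: pd.Series,
    scenario: str,
    top_frac: float = 0.01,
    params=None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Posterior medians and 95% credible intervals for one scenario.

    The retained draws (closest ``top_frac`` of the scenario's rows) are
    adjusted by local-linear regression of each parameter on the
    standardized statistic differences; bounded parameters are regressed
    on the logit scale, sizes and times on the log scale.  A singular
    design falls back to the unadjusted rejection posterior.
    """
    sub = reference[reference["scenario"] == scenario].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no reference rows for scenario {scenario!r}")
    stat_cols = _stat_columns(reference)
    dist, z = _standardized_distances(sub, observed, stat_cols)
    n_keep = max(int(round(top_frac * len(sub))), 10)
    keep = np.argsort(dist)[:n_keep]
    zk = z[keep]
    names = params or [p for p in PARAM_NAMES if p in sub.columns and sub[p].notna().all()]
    zred = _leading_components(zk, max_dim=max(1, min(4, n_keep // 12)))
    out = []
    for name in names:
        raw = sub[name].to_numpy(dtype=float)[keep]
        w = _to_working(name, raw)
        if adjust:
            X = np.column_stack([np.ones(len(keep)), zred])
            try:
                beta, *_ = np.linalg.lstsq(X, w, rcond=None)
                adj = w - zred @ beta[1:]
            except np.linalg.LinAlgError:
                adj = w
        else:
            adj = w
        vals = _from_working(name, adj)
        # adjustment can extrapolate past the prior support; truncate to the
        # range the scenario's draws actually cover
        vals = np.clip(vals, sub[name].min(), sub[name].max())
        out.append(
            {
                "parameter": name,
                "median": float(np.median(vals)),
                "q025": float(np.quantile(vals, 0.025)),
                "q975": float(np.quantile(vals, 0.975)),
                "n_retained": n_keep,
            }
        )
    return pd.DataFrame(out).set_index("parameter")


def model_check_pca(
    reference: pd.DataFrame,
    observed: pd.Series,
    posterior_stats: pd.DataFrame | None = None,
    n_components: int = 2,
):
    """PCA of the reference summary statistics with the observed point
    (and optionally a posterior-predictive cloud) projected in.

    Returns (reference coordinates, observed coordinates, cloud
    coordinates or None)."""
    from sklearn.decomposition import PCA

    stat_cols = _stat_columns(reference)
    ref = reference[stat_cols].to_numpy(dtype=float)
    mu, sd = ref.mean(axis=0), ref.std(axis=0)
    sd[sd == 0] = 1.0
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform((ref - mu) / sd)
    obs = pca.transform(((observed[stat_cols].to_numpy(dtype=float) - mu) / sd)[None, :])[0]
    cloud = None
    if posterior_stats is not None:
        cloud = pca.transform((posterior_stats[stat_cols].to_numpy(dtype=float) - mu) / sd)
    return coords, obs, cloud
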