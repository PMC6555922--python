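"""Selection scans: environmental association, F_ST outliers, F-model.

Three complementary procedures, mirroring a standard RAD-seq toolkit:

* :func:`env_bayes_factor` — covariance-controlled environmental
  association.  Population allele frequencies are standardized against
  their ancestral frequency; the genome-wide (neutral) population
  covariance matrix Omega is estimated by MCMC and the per-locus Bayes
  factor compares a linear covariate effect against the Omega-null, with
  the effect size integrated numerically over its prior.  BF > 3 in every
  one of several runs (each under an independent Omega draw) counts as
  substantial evidence.
* :func:`fdist_hier_outliers` — an F_ST outlier test under a hierarchical
  island null (groups of demes), calibrated to the observed global F_ST
  and F_CT, flagging loci in the extreme conditional tails of theta given
  heterozygosity (high tail: positive selection; low tail: balancing).
* :func:`fmodel_outliers` — a Bayesian F-model decomposition
  logit(F_ij) = alpha_i + beta_j with reversible-jump MCMC over inclusion
  of the locus effects; outliers at q-value <= 5%, with the sign of
  alpha separating positive from balancing selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .core import MISSING, GenotypeMatrix, PopulationMap
from .diversity import _pop_counts, _wc_components, wc_fst_grouped


# ---------------------------------------------------------------------------
# Population covariance of standardized allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class PopCovMatrix:
    omega: pd.DataFrame  # population x population posterior mean
    draws: list  # thinned posterior draws (ndarrays)
    n_iter: int
    populations: list = field(default_factory=list)

    def __post_init__(self):
        self.populations = list(self.omega.index)


def _standardized_freqs(g: GenotypeMatrix, popmap: PopulationMap):
    """Observed standardized frequencies x_hat (loci x pops), the
    mean per-pop diploid call counts, and the pooled ancestral-frequency
    estimate per locus.  Loci pooled-monomorphic are dropped."""
    rows = popmap.row_indices(g)
    pops = list(rows)
    n, p, _h = _pop_counts(g, rows)
    eps = g.alt_freq()
    ok = np.isfinite(eps) & (eps > 0) & (eps < 1) & np.isfinite(p).all(axis=0)
    x = (p[:, ok] - eps[ok]) / np.sqrt(eps[ok] * (1 - eps[ok]))
    n_mean = n[:, ok].mean(axis=1)
    return x.T, n_mean, pops, ok  # (L, P)


def estimate_pop_cov(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    n_iter: int = 100_000,
    seed: int = 0,
    burn_frac: float = 0.2,
    thin: int = 50,
) -> PopCovMatrix:
    """Posterior mean of the population covariance Omega.

    Model: per locus, the latent standardized frequency vector is
    N(0, Omega); the observed standardized sample frequency adds
    independent sampling noise of variance 1/(2 n_j).  A Gibbs sampler
    alternates the latent vectors (conjugate Gaussian) with Omega
    (inverse-Wishart, identity prior scale).  The posterior mean over
    retained iterations is returned together with thinned draws for
    consistency runs.
    """
    from scipy.stats import invwishart

    if len(popmap.populations) < 3:
        raise ValueError("covariance estimation needs >= 3 populations")
    if g.n_loci < 200:
        raise ValueError("covariance estimation needs >= 200 loci")
    rng = np.random.default_rng(seed)
    xhat, n_mean, pops, _ok = _standardized_freqs(g, popmap)
    L, P = xhat.shape
    d_inv = np.diag(2.0 * n_mean)  # inverse sampling variance
    omega = np.eye(P) * float(np.var(xhat))
    nu0 = P + 2
    psi0 = np.eye(P)
    burn = int(burn_frac * n_iter)
    acc = np.zeros((P, P))
    n_acc = 0
    draws = []
    for it in range(n_iter):
        # latent vectors | Omega  (same conditional covariance for all loci)
        try:
            s_inv = np.linalg.inv(omega) + d_inv
            s_cov = np.linalg.inv(s_inv)
        except np.linalg.LinAlgError:
            omega = omega + 1e-6 * np.eye(P)
            continue
        mean = xhat @ d_inv @ s_cov
        chol = np.linalg.cholesky(s_cov + 1e-12 * np.eye(P))
        x = mean + rng.standard_normal((L, P)) @ chol.T
        # Omega | latent vectors
        scale = psi0 + x.T @ x
        omega = invwishart.rvs(df=nu0 + L, scale=scale, random_state=rng)
        if it >= burn:
            acc += omega
            n_acc += 1
            if (it - burn) % thin == 0:
                draws.append(omega.copy())
    mean_omega = acc / max(n_acc, 1)
    # guard: numerical PSD jitter
    w = np.linalg.eigvalsh(mean_omega)
    if w.min() <= 0:
        warnings.warn("non-PSD running mean; jitter applied", stacklevel=2)
        mean_omega += (1e-9 - w.min()) * np.eye(P)
    return PopCovMatrix(
        omega=pd.DataFrame(mean_omega, index=pops, columns=pops),
        draws=draws,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Environmental-association Bayes factors
# ---------------------------------------------------------------------------


def _bf_one_run(xhat, n_mean, omega, covariate_z, beta_grid):
    """Vectorized BF per locus for one Omega draw.

    Whitening the null covariance (Omega + sampling noise) reduces the
    likelihood ratio at effect size beta to exp(beta * a_l - 0.5 beta^2
    * b), with a_l the whitened projection of locus l on the covariate.
    """
    from scipy.linalg import cho_factor, cho_solve, solve_triangular

    P = omega.shape[0]
    sigma = omega + np.diag(1.0 / (2.0 * n_mean))
    cl = np.linalg.cholesky(sigma)
    z = solve_triangular(cl, xhat.T, lower=True)  # (P, L)
    y = solve_triangular(cl, covariate_z, lower=True)  # (P,)
    a = y @ z  # (L,)
    b = float(y @ y)
    # mean over the uniform beta grid of the likelihood ratio
    lr = np.exp(np.clip(beta_grid[:, None] * a[None, :] - 0.5 * beta_grid[:, None] ** 2 * b, -700, 700))
    return lr.mean(axis=0)


def env_bayes_factor(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    pop_cov: PopCovMatrix,
    covariate: np.ndarray,
    n_runs: int = 5,
    seed: int = 0,
    beta_max: float = 1.0,
    n_grid: int = 41,
) -> pd.DataFrame:
    """Per-locus Bayes factor for a linear covariate effect.

    ``covariate`` is one value per population in the population map's
    order; it is standardized internally (a constant covariate is an
    error).  Each of ``n_runs`` runs uses an independent Omega draw;
    the reported BF is the run median and ``significant`` requires
    BF > 3 in every run.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.std() == 0:
        raise ValueError("constant covariate")
    cov_z = (cov - cov.mean()) / cov.std()
    xhat, n_mean, pops, ok = _standardized_freqs(g, popmap)
    if len(cov_z) != len(pops):
        raise ValueError("covariate length does not match populations")
    beta_grid = np.linspace(-beta_max, beta_max, n_grid)
    rng = np.random.default_rng(seed)
    if pop_cov.draws:
        pick = rng.choice(len(pop_cov.draws), size=n_runs, replace=len(pop_cov.draws) < n_runs)
        omegas = [pop_cov.draws[i] for i in pick]
    else:
        omegas = [pop_cov.omega.to_numpy()] * n_runs
    bfs = np.array([_bf_one_run(xhat, n_mean, om, cov_z, beta_grid) for om in omegas])
    out = pd.DataFrame(
        {
            "BF": np.median(bfs, axis=0),
            "BF_min": bfs.min(axis=0),
            "significant": (bfs > 3.0).all(axis=0),
        },
        index=g.loci.index[ok],
    )
    return out.reindex(g.loci.index).fillna({"BF": 1.0, "BF_min": 1.0, "significant": False})


def latitudinal_candidates(bf_temp: pd.DataFrame, bf_lat: pd.DataFrame) -> list:
    """Loci significant (BF > 3 in all runs) for both temperature and
    latitude — the latitudinal-gradient candidate set."""
    s1 = set(bf_temp.index[bf_temp["significant"].astype(bool)])
    s2 = set(bf_lat.index[bf_lat["significant"].astype(bool)])
    return sorted(s1 & s2)


# ---------------------------------------------------------------------------
# Hierarchical-island F_ST outlier test
# ---------------------------------------------------------------------------


def _hier_null_loci(rng, n_sims, c_ct, c_sc, group_of_pop, n_diploids):
    """Simulate null (pooled He, theta) pairs under a two-level
    Balding–Nichols hierarchy (groups of demes), sampling the observed
    deme layout."""
    groups = list(dict.fromkeys(group_of_pop.values()))
    p0 = rng.uniform(0.01, 0.99, size=n_sims)

    def bn(base, c):
        if c <= 0:
            return np.tile(base, (1, 1)) if base.ndim == 1 else base.copy()
        scale = (1 - c) / c
        return rng.beta(np.maximum(base * scale, 1e-9), np.maximum((1 - base) * scale, 1e-9))

    pg = {}
    for gr in groups:
        pg[gr] = bn(p0, c_ct) if c_ct > 0 else p0.copy()
    n_list, p_list, h_list = [], [], []
    for pop, gr in group_of_pop.items():
        pp = bn(pg[gr], c_sc) if c_sc > 0 else pg[gr].copy()
        nd = int(n_diploids[pop])
        dosage = rng.binomial(2, np.tile(pp, (nd, 1)))
        n_list.append(np.full(n_sims, float(nd)))
        p_list.append(dosage.mean(axis=0) / 2.0)
        h_list.append((dosage == 1).mean(axis=0))
    n = np.array(n_list)
    p = np.array(p_list)
    h = np.array(h_list)
    a, b, c = _wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    pooled = (n * p).sum(axis=0) / n.sum(axis=0)
    he = 2 * pooled * (1 - pooled)
    ok = np.isfinite(theta)
    return he[ok], theta[ok], n, p, h


def _observed_fst_fct(g, popmap, trim: float = 0.05):
    """Observed global F_ST and F_CT with the per-locus theta tails
    trimmed (candidate outliers must not inflate the neutral target the
    null is calibrated to)."""
    rows = popmap.row_indices(g)
    pops = list(rows)
    n, p, h = _pop_counts(g, rows)
    a, b, c = _wc_components(n, p, h)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
    if trim > 0 and ok.sum() > 50:
        lo, hi = np.nanquantile(per_locus[ok], [trim, 1 - trim])
        ok = ok & (per_locus >= lo) & (per_locus <= hi)
    fst = float(a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum())
    # F_CT from pooled groups (two-level approximation)
    groups = popmap.group_of[pops]
    uniq = list(dict.fromkeys(groups))
    gidx = [np.concatenate([rows[p_] for p_ in pops if groups[p_] == gr]) for gr in uniq]
    ng, pg, hg = [], [], []
    for idx in gidx:
        d = g.dosage[idx]
        called = d != MISSING
        ni = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ng.append(ni)
            pg.append(np.where(ni > 0, np.where(called, d, 0).sum(axis=0) / (2 * ni), np.nan))
            hg.append(np.where(ni > 0, (d == 1).sum(axis=0) / ni, np.nan))
    ag, bg, cg = _wc_components(np.array(ng), np.array(pg), np.array(hg))
    okg = ok & np.isfinite(ag) & np.isfinite(bg) & np.isfinite(cg)
    fct = float(ag[okg].sum() / (ag[okg] + bg[okg] + cg[okg]).sum())
    return fst, max(fct, 0.0)


def fdist_hier_outliers(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    n_sims: int = 50_000,
    n_groups: int = 10,
    demes_per_group: int = 100,
    seed: int = 0,
    quantile_threshold: float = 0.995,
    fdr: float = 0.01,
    n_he_bins: int = 10,
    calib_loci: int = 20_000,
    max_calib_iter: int = 12,
) -> pd.DataFrame:
    """Hierarchical-island F_ST outlier test.

    The null's two drift levels (among groups c_CT, among demes within
    groups c_SC) are calibrated so the simulated expected F_ST and F_CT
    match the observed values; ``n_sims`` null loci then give the joint
    (He, theta) distribution, and each observed locus is placed at its
    conditional theta quantile within its He bin.  High-tail outliers
    (putative positive selection) require quantile > ``quantile_threshold``
    and Benjamini–Hochberg FDR <= ``fdr``; the low tail is symmetric and
    flags balancing candidates.  ``n_groups``/``demes_per_group`` describe
    the null island model; only the observed deme layout is sampled from
    it (drift levels are exchangeable across unsampled demes).
    """
    rows = popmap.row_indices(g)
    pops = list(rows)
    group_of_pop = {p_: popmap.group_of[p_] for p_ in pops}
    if len(set(group_of_pop.values())) < 2:
        raise ValueError("hierarchical test needs >= 2 groups")
    n_diploids = {p_: len(rows[p_]) for p_ in pops}
    fst_obs, fct_obs = _observed_fst_fct(g, popmap)
    rng = np.random.default_rng(seed)

    # calibrate (c_ct, c_sc), starting from the analytic hierarchy relation
    c_ct = np.clip(fct_obs, 1e-6, 0.9)
    c_sc = np.clip((fst_obs - fct_obs) / max(1 - fct_obs, 1e-9), 1e-6, 0.9)
    for it in range(max_calib_iter):
        he, theta, n, p, h = _hier_null_loci(
            rng, calib_loci, c_ct, c_sc, group_of_pop, n_diploids
        )
        a, b, c = _wc_components(n, p, h)
        ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
        # mirror the trimmed observed target: same tail trim on the
        # simulated per-locus theta, else the calibration is biased low
        with np.errstate(invalid="ignore", divide="ignore"):
            th_sim = a / (a + b + c)
        lo_q, hi_q = np.nanquantile(th_sim[ok], [0.05, 0.95])
        ok = ok & (th_sim >= lo_q) & (th_sim <= hi_q)
        fst_sim = float(a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum())
        # group-level theta on the same simulated loci
        groups = list(dict.fromkeys(group_of_pop.values()))
        gmask = [np.array([group_of_pop[p_] == gr for p_ in pops]) for gr in groups]
        ng = np.array([n[m].sum(axis=0) for m in gmask])
        pgr = np.array(
            [(n[m] * p[m]).sum(axis=0) / np.maximum(n[m].sum(axis=0), 1e-9) for m in gmask]
        )
        hgr = np.array(
            [(n[m] * h[m]).sum(axis=0) / np.maximum(n[m].sum(axis=0), 1e-9) for m in gmask]
        )
        ag, bg, cg = _wc_components(ng, pgr, hgr)
        okg = ok & np.isfinite(ag) & np.isfinite(bg) & np.isfinite(cg)
        fct_sim = float(ag[okg].sum() / (ag[okg] + bg[okg] + cg[okg]).sum())
        err_fst = fst_obs - fst_sim
        err_fct = fct_obs - fct_sim
        tol_fst = max(0.004, 0.08 * fst_obs)
        tol_fct = max(0.004, 0.08 * max(fct_obs, 1e-3))
        if abs(err_fst) < tol_fst and abs(err_fct) < tol_fct:
            break
        # bias-corrected updates: the estimators carry a (slowly varying)
        # offset from their analytic targets; re-solve the hierarchy
        # relations F_CT = c_ct, F_ST = c_ct + (1 - c_ct) c_sc using the
        # current simulated bias
        bias_ct = fct_sim - c_ct
        bias_st = fst_sim - (c_ct + (1 - c_ct) * c_sc)
        c_ct = float(np.clip(fct_obs - bias_ct, 1e-6, 0.95))
        c_sc = float(np.clip((fst_obs - bias_st - c_ct) / max(1 - c_ct, 1e-6), 1e-6, 0.95))
    else:
        # near-misses within twice the tolerance are Monte-Carlo wobble of
        # the calibration fixed point; a genuine bracketing failure raises
        if abs(err_fst) < 2 * tol_fst and abs(err_fct) < 2 * tol_fct:
            warnings.warn(
                f"island-model calibration stopped at F_ST={fst_sim:.4f} "
                f"F_CT={fct_sim:.4f} (targets {fst_obs:.4f}/{fct_obs:.4f})",
                stacklevel=2,
            )
        else:
            raise RuntimeError(
                f"island-model calibration failed: observed F_ST={fst_obs:.4f} "
                f"F_CT={fct_obs:.4f}, last simulated {fst_sim:.4f}/{fct_sim:.4f}"
            )

    he_null, th_null, *_ = _hier_null_loci(
        rng, n_sims, c_ct, c_sc, group_of_pop, n_diploids
    )

    # observed per-locus theta and pooled He
    n, p, h = _pop_counts(g, rows)
    a, b, c = _wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        th_obs = a / (a + b + c)
    pooled = g.alt_freq()
    he_obs = 2 * pooled * (1 - pooled)

    # He-conditional empirical quantiles
    edges = np.quantile(he_null, np.linspace(0, 1, n_he_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bins_null = np.searchsorted(edges, he_null, side="right") - 1
    bins_obs = np.searchsorted(edges, he_obs, side="right") - 1
    p_high = np.full(g.n_loci, np.nan)
    p_low = np.full(g.n_loci, np.nan)

    def _tail_p(null_sorted, obs_vals, tail_frac=0.01):
        """Empirical p with a generalized-Pareto smoothed extreme tail.

        Observations beyond the null's (1 - tail_frac) quantile get
        p = tail_frac * GPD survival of the exceedance (method-of-moments
        fit), removing the 1/(n+1) floor that would otherwise choke FDR
        control at large locus counts.  Below the threshold the plain
        empirical p-value is used.
        """
        n = null_sorted.size
        ge = n - np.searchsorted(null_sorted, obs_vals - 1e-15, side="left")
        p = (1.0 + ge) / (n + 1.0)
        thr_idx = int(np.floor((1 - tail_frac) * n))
        thr = null_sorted[min(thr_idx, n - 1)]
        exc = null_sorted[null_sorted > thr] - thr
        beyond = obs_vals > thr
        if exc.size >= 30 and beyond.any():
            m, v = exc.mean(), exc.var()
            if v > 0:
                xi = float(np.clip(0.5 * (1 - m * m / v), -0.4, 0.9))
                beta = max(0.5 * m * (m * m / v + 1), 1e-12)
                x = obs_vals[beyond] - thr
                if abs(xi) < 1e-6:
                    sf = np.exp(-x / beta)
                else:
                    sf = np.power(np.maximum(1 + xi * x / beta, 0.0), -1.0 / xi)
                p[beyond] = np.minimum(p[beyond], tail_frac * np.maximum(sf, 1e-300))
        return p

    for b_i in range(n_he_bins):
        # pool the bin with its neighbors: kernel-style conditioning that
        # triples the null resolution (the conditional theta law varies
        # smoothly in He, and the p-value floor must stay well below the
        # FDR threshold)
        pool = (bins_null >= b_i - 1) & (bins_null <= b_i + 1)
        null_t = np.sort(th_null[pool])
        if null_t.size == 0:
            continue
        sel = np.flatnonzero((bins_obs == b_i) & np.isfinite(th_obs))
        if sel.size == 0:
            continue
        p_high[sel] = _tail_p(null_t, th_obs[sel])
        p_low[sel] = _tail_p(np.sort(-null_t), -th_obs[sel])

    def _bh(pvals, level):
        okm = np.isfinite(pvals)
        flags = np.zeros(len(pvals), dtype=bool)
        if okm.sum():
            from statsmodels.stats.multitest import multipletests

            rej, *_ = multipletests(pvals[okm], alpha=level, method="fdr_bh")
            flags[np.flatnonzero(okm)] = rej
        return flags

    high = (p_high < 1 - quantile_threshold) & _bh(p_high, fdr)
    low = (p_low < 1 - quantile_threshold) & _bh(p_low, fdr)
    return pd.DataFrame(
        {
            "He": he_obs,
            "theta": th_obs,
            "p_high": p_high,
            "p_low": p_low,
            "positive": high,
            "balancing": low,
            "c_ct": c_ct,
            "c_sc": c_sc,
        },
        index=g.loci.index,
    )


# ---------------------------------------------------------------------------
# F-model outlier test (reversible-jump MCMC)
# ---------------------------------------------------------------------------


def _fmodel_loglik(alpha, beta, p, alt, tot):
    """Beta-binomial log-likelihood per locus (summed over populations).

    alpha: (L,), beta: (J,), p: (L,) ancestral frequencies,
    alt/tot: (L, J) allele counts.  The binomial coefficient is constant
    across the sampled quantities and omitted.
    """
    f = expit(alpha[:, None] + beta[None, :])
    f = np.clip(f, 1e-6, 1 - 1e-6)
    th = 1.0 / f - 1.0
    a1 = p[:, None] * th
    a2 = (1 - p)[:, None] * th
    ll = betaln(alt + a1, tot - alt + a2) - betaln(a1, a2)
    return ll.sum(axis=1)


@dataclass
class FModelResult:
    table: pd.DataFrame  # per locus: post_incl, q, alpha, positive, balancing
    beta: np.ndarray
    ess_beta: float
    flagged_nonmixing: bool = False


def fmodel_outliers(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    prior_odds: float = 10.0,
    n_iter: int = 4000,
    burn: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
    sd_alpha_prior: float = 2.0,
) -> FModelResult:
    """Locus-specific selection effects via the F-model.

    logit(F_ij) = alpha_i + beta_j; allele counts are beta-binomial given
    the ancestral frequency.  A reversible-jump move toggles each locus
    effect alpha_i (prior inclusion odds 1:``prior_odds`` against), with
    the prior N(0, ``sd_alpha_prior``) doubling as the birth proposal so
    the acceptance ratio reduces to the likelihood ratio times the prior
    odds.  The q-value of a locus is the running mean of the posterior
    error (1 - inclusion probability) in ranked order; outliers at
    q <= ``q_threshold``, classed positive (alpha > 0) or balancing
    (alpha < 0).
    """
    rng = np.random.default_rng(seed)
    rows = popmap.row_indices(g)
    pops = list(rows)
    J = len(pops)
    if J < 2:
        raise ValueError("F-model needs >= 2 populations")
    alt = np.empty((g.n_loci, J))
    tot = np.empty((g.n_loci, J))
    for j, p_ in enumerate(pops):
        d = g.dosage[rows[p_]]
        called = d != MISSING
        alt[:, j] = np.where(called, d, 0).sum(axis=0)
        tot[:, j] = 2.0 * called.sum(axis=0)
    pooled = alt.sum(axis=1) / np.maximum(tot.sum(axis=1), 1.0)
    keep = (pooled > 0) & (pooled < 1)
    altk, totk = alt[keep], tot[keep]
    L = int(keep.sum())

    p = np.clip(pooled[keep], 0.01, 0.99)
    alpha = np.zeros(L)
    incl = np.zeros(L, dtype=bool)
    # start beta at the logit of the observed global differentiation
    _pl, fst0 = wc_fst_grouped(
        g, np.concatenate([rows[p_] for p_ in pops[: J // 2 + 1]]),
        np.concatenate([rows[p_] for p_ in pops[J // 2 + 1 :]]),
    ) if J > 2 else (None, 0.05)
    fst0 = min(max(fst0 if np.isfinite(fst0) else 0.05, 1e-3), 0.5)
    beta = np.full(J, float(logit(fst0)))
    ll = _fmodel_loglik(alpha * incl, beta, p, altk, totk)

    incl_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    alpha_cnt = np.zeros(L)
    beta_trace = []
    n_kept = 0
    for it in range(n_iter):
        # ancestral frequencies: logit random walk (vectorized MH)
        prop = np.clip(expit(logit(p) + rng.normal(0, 0.2, L)), 0.01, 0.99)
        ll_prop = _fmodel_loglik(alpha * incl, beta, prop, altk, totk)
        accept = np.log(rng.random(L)) < ll_prop - ll
        p = np.where(accept, prop, p)
        ll = np.where(accept, ll_prop, ll)

        # alpha random walk for included loci
        if incl.any():
            prop_a = np.where(incl, alpha + rng.normal(0, 0.3, L), alpha)
            ll_prop = _fmodel_loglik(prop_a * incl, beta, p, altk, totk)
            logr = (
                ll_prop - ll - (prop_a**2 - alpha**2) / (2 * sd_alpha_prior**2)
            )
            accept = incl & (np.log(rng.random(L)) < logr)
            alpha = np.where(accept, prop_a, alpha)
            ll = np.where(accept, ll_prop, ll)

        # reversible jump: toggle inclusion, prior as birth proposal
        a_birth = rng.normal(0, sd_alpha_prior, L)
        prop_a = np.where(incl, 0.0, a_birth)
        prop_incl = ~incl
        ll_prop = _fmodel_loglik(prop_a * prop_incl, beta, p, altk, totk)
        log_odds = np.where(incl, np.log(prior_odds), -np.log(prior_odds))
        accept = np.log(rng.random(L)) < ll_prop - ll + log_odds
        alpha = np.where(accept, prop_a, alpha)
        incl = np.where(accept, prop_incl, incl)
        ll = np.where(accept, ll_prop, ll)

        # shared beta: MH step on one random population per iteration
        j = int(rng.integers(J))
        bp = beta.copy()
        bp[j] += rng.normal(0, 0.15)
        ll_prop = _fmodel_loglik(alpha * incl, bp, p, altk, totk)
        logr = ll_prop.sum() - ll.sum() - ((bp[j] + 1) ** 2 - (beta[j] + 1) ** 2) / 2.0
        if np.log(rng.random()) < logr:
            beta = bp
            ll = ll_prop

        if it >= burn:
            incl_sum += incl
            alpha_sum += np.where(incl, alpha, 0.0)
            alpha_cnt += incl
            beta_trace.append(beta.copy())
            n_kept += 1

    post_incl = incl_sum / max(n_kept, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mean = np.where(alpha_cnt > 0, alpha_sum / np.maximum(alpha_cnt, 1), 0.0)
    pep = 1.0 - post_incl
    order = np.argsort(pep, kind="mergesort")
    qv = np.empty(L)
    qv[order] = np.cumsum(pep[order]) / np.arange(1, L + 1)

    bt = np.array(beta_trace)
    ess = _ess(bt.mean(axis=1)) if len(bt) > 2 else 0.0
    flagged = ess < 50
    if flagged:
        warnings.warn(
            f"F-model chain mixing poor (ESS {ess:.0f} < 50); results flagged",
            stacklevel=2,
        )

    table = pd.DataFrame(
        {
            "post_incl": post_incl,
            "q": qv,
            "alpha": alpha_mean,
            "positive": (qv <= q_threshold) & (alpha_mean > 0),
            "balancing": (qv <= q_threshold) & (alpha_mean < 0),
        },
        index=g.loci.index[keep],
    )
    table = table.reindex(g.loci.index)
    table[["positive", "balancing"]] = table[["positive", "balancing"]].fillna(False)
    return FModelResult(table, bt.mean(axis=0) if len(bt) else beta, float(ess), flagged)


def _ess(x: np.ndarray) -> float:
    """Effective sample size by initial positive-sequence autocorrelation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (xc @ xc)
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


# ---------------------------------------------------------------------------
# Set combination and stability protocol
# ---------------------------------------------------------------------------


def combine_outlier_sets(sets: dict, universe=None) -> dict:
    """Exact set algebra over named outlier locus sets.

    Returns union size/members, pairwise intersection counts and per-set
    sizes.  Unknown loci (outside ``universe`` when given) are an error.
    """
    clean = {k: set(v) for k, v in sets.items()}
    if universe is not None:
        uni = set(universe)
        for name, s in clean.items():
            bad = s - uni
            if bad:
                raise ValueError(f"set {name!r} references unknown loci: {sorted(bad)[:5]}")
    names = list(clean)
    union = set().union(*clean.values()) if clean else set()
    inter = {
        (a, b): len(clean[a] & clean[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return {
        "sizes": {k: len(v) for k, v in clean.items()},
        "union_size": len(union),
        "union": sorted(union),
        "pairwise_intersections": inter,
    }


def leave_one_out(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    test,
    keep_population: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability protocol: rerun ``test`` dropping one population at a time.

    ``test(g_subset, popmap_subset, seed)`` must return a set of outlier
    locus ids.  ``keep_population`` (e.g. the admixed location) is never
    dropped.  Returns per-replicate set sizes and the proportion of loci
    shared with the full-data run.
    """
    full = set(test(g, popmap, seed))
    rows = []
    for pop in popmap.populations:
        if pop == keep_population:
            continue
        kept_pops = [p_ for p_ in popmap.populations if p_ != pop]
        pm2 = popmap.subset(kept_pops)
        inds = [i for i in g.individuals if i in pm2.population_of.index]
        sub = test(g.take_individuals(inds), pm2, seed)
        sub = set(sub)
        rows.append(
            {
                "dropped": pop,
                "n_outliers": len(sub),
                "n_common_with_full": len(sub & full),
                "stability": len(sub & full) / len(full) if full else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("dropped")
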