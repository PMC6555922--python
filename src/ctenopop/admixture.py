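"""Maximum-likelihood admixture: EM over the binomial mixture likelihood.

The model is the classic unsupervised ancestry decomposition: individual
``i`` draws each of its two alleles at locus ``l`` from ancestral cluster
``k`` with probability ``q_ik`` and then an alternate allele with
probability ``f_kl``, so the dosage likelihood is

    L = sum_{i,l}  g_il * ln(sum_k q_ik f_kl)
              + (2 - g_il) * ln(sum_k q_ik (1 - f_kl)).

EM updates (FRAPPE-style) monotonically increase L; multiple restarts keep
the best run.  Model order K is chosen by masking a random fold of
genotype entries and scoring them by squared deviation between the
observed dosage and its fitted expectation 2 * sum_k q_ik f_kl — the K
with the lowest cross-validation error is the suggested number of
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap

_EPS = 1e-9


@dataclass
class AncestryResult:
    Q: pd.DataFrame  # individuals x K
    F: np.ndarray  # K x loci
    log_likelihood: float
    trace: np.ndarray
    K: int
    seed: int
    cv_error: float | None = None
    n_iter: int = 0
    converged: bool = False


def _loglik(g01, g2m, qf, qf1):
    return float(np.sum(g01 * np.log(qf + _EPS) + g2m * np.log(qf1 + _EPS)))


def _em_once(dosage, K, rng, tol, max_iter):
    n, L = dosage.shape
    obs = dosage != MISSING
    g = np.where(obs, dosage, 0).astype(np.float64)
    g2 = np.where(obs, 2.0 - g, 0.0)

    q = rng.dirichlet(np.ones(K), size=n)
    f = rng.uniform(0.1, 0.9, size=(K, L))
    trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        qf = q @ f  # (n, L) expected alt prob
        qf1 = q @ (1.0 - f)
        ll = _loglik(g, g2, qf, qf1)
        trace.append(ll)
        if ll - prev < tol and it > 0:
            converged = True
            break
        prev = ll
        # responsibilities folded into the updates
        ga = g / (qf + _EPS)  # (n, L)
        gb = g2 / (qf1 + _EPS)
        a = q * (ga @ f.T)  # (n, K): expected alt-allele draws from k
        b = q * (gb @ (1.0 - f).T)
        denom = 2.0 * obs.sum(axis=1, keepdims=True).astype(float)
        q = (a + b) / np.maximum(denom, _EPS)
        q = np.clip(q, _EPS, None)
        q /= q.sum(axis=1, keepdims=True)
        num = q.T @ ga * f  # (K, L) — note f factors restore the joint term
        den = num + q.T @ gb * (1.0 - f)
        f = np.clip(num / np.maximum(den, _EPS), _EPS, 1.0 - _EPS)
    return q, f, trace, converged


def fit_admixture(
    g: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
) -> AncestryResult:
    """Fit ancestry fractions Q and cluster frequencies F at a given K.

    K = 1 has the closed form Q = 1, F = pooled frequencies.  For K > 1,
    EM runs from ``n_restarts`` random starts and the best likelihood
    wins.  Missing entries are dropped from all sums.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n_individuals:
        raise ValueError("K larger than the number of individuals")
    dosage = g.dosage
    if K == 1:
        p = g.alt_freq()
        obs = dosage != MISSING
        gg = np.where(obs, dosage, 0).astype(float)
        g2 = np.where(obs, 2 - gg, 0.0)
        f = np.clip(np.nan_to_num(p, nan=0.5), _EPS, 1 - _EPS)[None, :]
        ll = _loglik(gg, g2, np.broadcast_to(f, dosage.shape), np.broadcast_to(1 - f, dosage.shape))
        return AncestryResult(
            Q=pd.DataFrame(np.ones((g.n_individuals, 1)), index=g.individuals, columns=["K1"]),
            F=f, log_likelihood=ll, trace=np.array([ll]), K=1, seed=seed,
            n_iter=1, converged=True,
        )
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng((seed, K, r))
        q, f, trace, conv = _em_once(dosage, K, rng, tol, max_iter)
        if best is None or trace[-1] > best[2][-1]:
            best = (q, f, trace, conv)
    q, f, trace, conv = best
    return AncestryResult(
        Q=pd.DataFrame(q, index=g.individuals, columns=[f"K{k+1}" for k in range(K)]),
        F=f,
        log_likelihood=trace[-1],
        trace=np.array(trace),
        K=K,
        seed=seed,
        n_iter=len(trace),
        converged=conv,
    )


# ---------------------------------------------------------------------------
# Cross-validation over K
# ---------------------------------------------------------------------------


def cv_error_over_k(
    g: GenotypeMatrix,
    k_range=range(1, 13),
    folds: int = 5,
    seed: int = 0,
    holdout_frac: float = 0.1,
    **fit_kwargs,
):
    """Masked-entry cross-validation error per K.

    For each fold, a random ``holdout_frac`` of the non-missing entries is
    masked, the model refit, and the masked dosages scored by
    (g - 2 * sum_k q_ik f_kl)^2.  Returns (per-K error Series, best K).
    """
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(g.dosage != MISSING)
    rng.shuffle(obs_idx)
    errors = {}
    for K in k_range:
        fold_err = []
        for fold in range(folds):
            take = obs_idx[fold::folds]
            take = take[: max(1, int(len(obs_idx) * holdout_frac))]
            masked = g.dosage.copy()
            masked[take[:, 0], take[:, 1]] = MISSING
            if (np.all(masked == MISSING, axis=0)).any():
                raise ValueError("cross-validation fold emptied a locus column")
            gm = GenotypeMatrix(g.individuals, g.loci, masked)
            res = fit_admixture(gm, K, seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
            expected = 2.0 * (res.Q.to_numpy() @ res.F)
            truth = g.dosage[take[:, 0], take[:, 1]].astype(float)
            pred = expected[take[:, 0], take[:, 1]]
            fold_err.append(float(np.mean((truth - pred) ** 2)))
        errors[K] = float(np.mean(fold_err))
    per_k = pd.Series(errors).sort_index()
    return per_k, int(per_k.idxmin())


# ---------------------------------------------------------------------------
# Composition and alien-individual flagging
# ---------------------------------------------------------------------------


def label_clusters(Q: pd.DataFrame, popmap: PopulationMap) -> dict:
    """cluster column -> river-system group, by majority vote of the
    sampling groups of the individuals hard-assigned (argmax ancestry)
    to that cluster.  A tie is a hard error asking for manual labels."""
    groups = popmap.group_of[popmap.population_of.reindex(Q.index)].to_numpy()
    assign = Q.to_numpy().argmax(axis=1)
    labels = {}
    for k, col in enumerate(Q.columns):
        mine = groups[assign == k]
        if mine.size == 0:
            # no individual majority-assigned: fall back to weighted vote
            tally = pd.Series(Q[col].to_numpy()).groupby(groups).sum()
        else:
            tally = pd.Series(mine).value_counts()
        tally = tally.sort_values(ascending=False)
        if len(tally) > 1 and np.isclose(tally.iloc[0], tally.iloc[1]):
            raise ValueError(
                f"ambiguous cluster labeling for {col}: tie between "
                f"{tally.index[0]} and {tally.index[1]}; provide labels manually"
            )
        labels[col] = tally.index[0]
    return labels


def population_composition(Q: pd.DataFrame, popmap: PopulationMap) -> pd.DataFrame:
    """Per-population mean ancestry: column means of Q within populations."""
    pops = popmap.population_of.reindex(Q.index)
    return Q.groupby(pops.to_numpy()).mean().reindex(popmap.populations)


def flag_alien_individuals(
    Q: pd.DataFrame,
    popmap: PopulationMap,
    cluster_groups: dict | None = None,
    threshold: float = 0.5,
) -> list:
    """Individuals whose summed non-native ancestry is strictly > threshold.

    'Native' for an individual means clusters labeled with its own
    sampling group (labels from :func:`label_clusters` unless given).
    """
    labels = cluster_groups or label_clusters(Q, popmap)
    out = []
    for ind, row in Q.iterrows():
        own_group = popmap.group_of[popmap.population_of[ind]]
        foreign = sum(row[c] for c in Q.columns if labels[c] != own_group)
        if foreign > threshold:
            out.append(ind)
    return out


def match_clusters(Q: pd.DataFrame, truth: np.ndarray) -> np.ndarray:
    """Permute Q's columns to best match a truth matrix (maximal
    correlation assignment); returns the reordered Q array.  Used by
    label-switching-aware assertions."""
    from scipy.optimize import linear_sum_assignment

    qa = Q.to_numpy()
    K = qa.shape[1]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(truth.shape[1]):
            cost[i, j] = -np.corrcoef(qa[:, i], truth[:, j])[0, 1]
    cost = np.nan_to_num(cost, nan=0.0)
    _r, c = linear_sum_assignment(cost.T)
    return qa[:, c]
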