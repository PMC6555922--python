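"""Per-locus structured-coalescent simulator for the ABC scenarios.

Each locus gets an independent genealogy of the sampled lineages:
within-population coalescence at rate C(k,2) / (2N) per generation
(continuous-time approximation), lineage movement at demographic events
(admixture: each lineage picks a source with the admixture rate; splits:
all lineages move), and population-size changes (founder bottlenecks).
One segregating site per locus is placed on a branch chosen proportional
to branch length; the leaves under that branch carry the derived allele.

The kernel is numba-compiled and driven by flat event arrays so a single
implementation serves every scenario:

* ``ev_time`` — event times in generations, ascending;
* ``ev_kind`` — 0: resize (``ev_a`` = population, ``ev_val`` = new 2N-half
  i.e. diploid size), 1: move (``ev_a`` = source, ``ev_b`` = destination,
  ``ev_val`` = per-lineage probability of moving).

Events with the same time are applied in array order, which expresses an
admixture as two moves: source I -> A with probability r, then I -> B with
probability 1.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _simulate_carriers(
    n_loci,
    samp,  # int64[n_pop] haploid sample sizes
    sizes0,  # float64[n_pop] diploid effective sizes at time 0
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_val,
    seed,
):
    np.random.seed(seed)
    n_pop = samp.shape[0]
    n_tot = 0
    for p in range(n_pop):
        n_tot += samp[p]
    n_nodes = 2 * n_tot - 1
    out = np.zeros((n_tot, n_loci), dtype=np.uint8)

    parent = np.empty(n_nodes, dtype=np.int64)
    ntime = np.empty(n_nodes, dtype=np.float64)
    child1 = np.empty(n_nodes, dtype=np.int64)
    child2 = np.empty(n_nodes, dtype=np.int64)
    act = np.empty(n_tot, dtype=np.int64)  # active node ids
    act_pop = np.empty(n_tot, dtype=np.int64)
    stack = np.empty(n_nodes, dtype=np.int64)
    rates = np.empty(n_pop, dtype=np.float64)
    counts = np.empty(n_pop, dtype=np.int64)
    sizes = np.empty(n_pop, dtype=np.float64)

    for locus in range(n_loci):
        for i in range(n_nodes):
            parent[i] = -1
            child1[i] = -1
            child2[i] = -1
        k = 0
        for p in range(n_pop):
            counts[p] = samp[p]
            sizes[p] = sizes0[p]
            for _ in range(samp[p]):
                act[k] = k
                act_pop[k] = p
                ntime[k] = 0.0
                k += 1
        n_active = n_tot
        next_node = n_tot
        t = 0.0
        ev_i = 0
        n_ev = ev_time.shape[0]

        while n_active > 1:
            total = 0.0
            for p in range(n_pop):
                kp = counts[p]
                rates[p] = 0.5 * kp * (kp - 1) / (2.0 * sizes[p])
                total += rates[p]
            if total <= 0.0:
                if ev_i < n_ev:
                    t = ev_time[ev_i]
                else:
                    # should not happen with well-formed events; force merge
                    break
            else:
                dt = np.random.exponential(1.0 / total)
                if ev_i < n_ev and t + dt >= ev_time[ev_i]:
                    t = ev_time[ev_i]
                else:
                    t = t + dt
                    # choose population for the coalescence
                    u = np.random.random() * total
                    p = 0
                    acc = rates[0]
                    while acc < u and p < n_pop - 1:
                        p += 1
                        acc += rates[p]
                    # pick two distinct active lineages in p
                    i1 = np.random.randint(counts[p])
                    i2 = np.random.randint(counts[p] - 1)
                    if i2 >= i1:
                        i2 += 1
                    # map the within-pop ranks to positions in act
                    pos1 = -1
                    pos2 = -1
                    seen = 0
                    for a_i in range(n_active):
                        if act_pop[a_i] == p:
                            if seen == i1:
                                pos1 = a_i
                            if seen == i2:
                                pos2 = a_i
                            seen += 1
                    n1 = act[pos1]
                    n2 = act[pos2]
                    m = next_node
                    next_node += 1
                    parent[n1] = m
                    parent[n2] = m
                    child1[m] = n1
                    child2[m] = n2
                    ntime[m] = t
                    act[pos1] = m
                    # remove pos2 by swapping in the tail
                    act[pos2] = act[n_active - 1]
                    act_pop[pos2] = act_pop[n_active - 1]
                    n_active -= 1
                    counts[p] -= 1
                    continue
            # apply every event scheduled at this time
            while ev_i < n_ev and ev_time[ev_i] <= t + 1e-12:
                if ev_kind[ev_i] == 0:
                    sizes[ev_a[ev_i]] = ev_val[ev_i]
                else:
                    src = ev_a[ev_i]
                    dst = ev_b[ev_i]
                    prob = ev_val[ev_i]
                    for a_i in range(n_active):
                        if act_pop[a_i] == src and np.random.random() < prob:
                            act_pop[a_i] = dst
                            counts[src] -= 1
                            counts[dst] += 1
                ev_i += 1

        # place the mutation: branch chosen proportional to length
        root = act[0]
        total_len = 0.0
        for v in range(next_node):
            if parent[v] >= 0:
                total_len += ntime[parent[v]] - ntime[v]
        u = np.random.random() * total_len
        chosen = -1
        acc = 0.0
        for v in range(next_node):
            if parent[v] >= 0:
                acc += ntime[parent[v]] - ntime[v]
                if acc >= u:
                    chosen = v
                    break
        if chosen < 0:
            chosen = root - 1 if root > 0 else 0
        # mark leaves under the chosen node
        sp = 0
        stack[sp] = chosen
        sp += 1
        while sp > 0:
            sp -= 1
            v = stack[sp]
            if v < n_tot:
                out[v, locus] = 1
            else:
                stack[sp] = child1[v]
                sp += 1
                stack[sp] = child2[v]
                sp += 1
    return out


def simulate_carriers(n_loci, sample_sizes, sizes, events, seed):
    """Run the kernel; returns an (n_haploid, n_loci) uint8 carrier matrix.

    ``events``: iterable of tuples ``(time, kind, a, b, value)`` (see module
    docstring), applied in the order given for equal times.
    """
    events = sorted(events, key=lambda e: e[0])
    ev_time = np.array([e[0] for e in events], dtype=np.float64)
    ev_kind = np.array([e[1] for e in events], dtype=np.int64)
    ev_a = np.array([e[2] for e in events], dtype=np.int64)
    ev_b = np.array([e[3] for e in events], dtype=np.int64)
    ev_val = np.array([e[4] for e in events], dtype=np.float64)
    samp = np.asarray(sample_sizes, dtype=np.int64)
    sizes0 = np.asarray(sizes, dtype=np.float64)
    if (samp > 2 * sizes0).any():
        raise ValueError("sample larger than 2N in a contemporary population")
    return _simulate_carriers(
        int(n_loci), samp, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_val, int(seed)
    )


def carriers_to_dosage(carriers: np.ndarray) -> np.ndarray:
    """Pair consecutive haploid lineages into diploid dosages."""
    if carriers.shape[0] % 2:
        raise ValueError("odd number of haploid lineages")
    c = carriers.astype(np.int8)
    return c[0::2, :] + c[1::2, :]
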