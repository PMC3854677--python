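"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (pure Python,
math.lgamma, exhaustive loops) and shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import itertools
from math import lgamma, exp

import numpy as np


def dirichlet_factor_mc(counts, rng, n_draws=1_000_000):
    """Monte-Carlo estimate of E_{Dirichlet(1,..,1)}[prod_k q_k^{n_k}]."""
    k = len(counts)
    q = rng.dirichlet(np.ones(k), size=n_draws)
    return float(np.prod(q ** np.asarray(counts), axis=1).mean())


def pair_factor_exact(counts):
    """(K-1)! * prod n_k! / (n + K - 1)! via lgamma, independent code path."""
    k = len(counts)
    n = sum(counts)
    return exp(lgamma(k) + sum(lgamma(c + 1) for c in counts) - lgamma(n + k))


def h_of_assignment(g, edges, k):
    """Negative log partition weight of a labeled assignment.

    ``edges`` is a list of (u, v, t) index triples; ``g`` maps drug index to
    group label.
    """
    cnt: dict[tuple[int, int], list[int]] = {}
    for u, v, t in edges:
        key = (min(g[u], g[v]), max(g[u], g[v]))
        cnt.setdefault(key, [0] * k)[t] += 1
    h = 0.0
    for vec in cnt.values():
        n = sum(vec)
        h -= lgamma(k) + sum(lgamma(x + 1) for x in vec) - lgamma(n + k)
    return h


def exact_posteriors(n_drugs, edges, k, query_pairs):
    """Exhaustive Bayesian average over all labeled assignments of
    ``n_drugs`` drugs into ``n_drugs`` groups.

    Returns {(i, j): length-k probability vector} for index pairs.  This is
    the exact value of the quantity the Metropolis sampler estimates.
    """
    num = {p: np.zeros(k) for p in query_pairs}
    den = 0.0
    h_min = None
    states = list(itertools.product(range(n_drugs), repeat=n_drugs))
    hs = [h_of_assignment(g, edges, k) for g in states]
    h_min = min(hs)
    for g, h in zip(states, hs):
        w = exp(-(h - h_min))
        den += w
        cnt: dict[tuple[int, int], list[int]] = {}
        for u, v, t in edges:
            key = (min(g[u], g[v]), max(g[u], g[v]))
            cnt.setdefault(key, [0] * k)[t] += 1
        for i, j in query_pairs:
            key = (min(g[i], g[j]), max(g[i], g[j]))
            vec = cnt.get(key, [0] * k)
            n = sum(vec)
            num[(i, j)] += w * np.array([(vec[t] + 1) / (n + k) for t in range(k)])
    return {p: num[p] / den for p in query_pairs}


def set_partition_distribution(n_drugs, edges, k):
    """exp(-H)/Z aggregated over the set partitions reachable by the
    labeled-assignment chain (each set partition weighted by the number of
    labeled states representing it)."""

    def canon(g):
        seen: dict[int, int] = {}
        out = []
        for x in g:
            if x not in seen:
                seen[x] = len(seen)
            out.append(seen[x])
        return tuple(out)

    weights: dict[tuple, float] = {}
    hs = []
    states = list(itertools.product(range(n_drugs), repeat=n_drugs))
    hs = [h_of_assignment(g, edges, k) for g in states]
    h_min = min(hs)
    for g, h in zip(states, hs):
        key = canon(g)
        weights[key] = weights.get(key, 0.0) + exp(-(h - h_min))
    z = sum(weights.values())
    return {key: w / z for key, w in weights.items()}


def brute_force_neighbor(net, pair):
    """Exhaustive double loop over ordered candidate pairs (k, l) with known
    type, ranked by S_ik * S_jl; mirrors the documented tie-breaking.
    Returns the predicted type index, or None if no positive product exists.
    """
    i, j = pair
    drugs = net.drugs

    def sim(a, b):
        if a == b:
            return 1.0
        common = equal = 0
        for z in drugs:
            if z in (a, b):
                continue
            ta, tb = net.get(a, z), net.get(b, z)
            if ta is None or tb is None:
                continue
            common += 1
            equal += ta == tb
        return None if common == 0 else equal / common

    best = None
    for kd in drugs:
        for ld in drugs:
            if kd == ld or {kd, ld} == {i, j}:
                continue
            t = net.get(kd, ld)
            if t is None:
                continue
            sik = sim(i, kd)
            sjl = sim(j, ld)
            if sik is None or sjl is None:
                continue
            p = sik * sjl
            if p <= 0:
                continue
            key = (-p, -min(sik, sjl), net.drug_index(kd), net.drug_index(ld))
            if best is None or key < best[0]:
                best = (key, t)
    return None if best is None else best[1]


def brute_force_auroc(pos, neg):
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))
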