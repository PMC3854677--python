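"""Bayesian model averaging over stochastic block models for link-type inference.

The model: drugs are partitioned into groups, and the probability that a pair
interacts with each type k depends only on the two groups involved, through a
group-pair probability vector q_{alpha beta} on the K-simplex.  With a uniform
prior over those vectors they integrate out in closed form, leaving a weight
exp(-H(P)) for every partition P, where

    H(P) = -sum_{alpha<=beta} ln[ (K-1)! prod_k n^k_{ab}! / (n_ab + K - 1)! ]

and n^k_{ab} counts observed interactions of type k between groups alpha and
beta.  The posterior probability that an unobserved pair (i, j) has type k is
the average, over partitions weighted by exp(-H), of the Laplace-smoothed
rate (n^k + 1)/(n + K) between the groups of i and j.  The partition sum is
estimated by Metropolis sampling: move a random drug to a random other group
and accept with probability min(1, exp(H - H')).

The sampler state space is assignments of the N drugs into N labeled groups,
so every partition is reachable and the proposal is symmetric.  All partition
averages in this package (and the exhaustive small-network oracles used to
test them) are taken over that same labeled space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln

from .network import InteractionNetwork, Pair, _canon

__all__ = [
    "SamplerConfig",
    "ObservationView",
    "Partition",
    "SampleSet",
    "ThermalizationWarning",
    "log_pair_factor",
    "compute_H",
    "metropolis_step",
    "run_sampler",
    "link_type_posterior",
    "score_all_pairs",
    "coclassification_matrix",
    "build_view",
]

Mode = Literal["heldout", "fully_observed"]


class ThermalizationWarning(UserWarning):
    """A chain hit the burn-in cap before the equilibration test passed."""


# ---------------------------------------------------------------------------
# Closed-form marginal likelihood of one group pair
# ---------------------------------------------------------------------------

def log_pair_factor(
    type_counts: Sequence[int] | np.ndarray, include_prior_constant: bool = True
) -> float:
    """Log marginal likelihood of one group pair's observed interactions.

    Integrating the K-type interaction probabilities of a group pair over the
    uniform prior on the simplex gives

        (K-1)! * prod_k n_k! / (n + K - 1)!   with  n = sum_k n_k,

    i.e. the mean of ``prod_k q_k^{n_k}`` under Dirichlet(1,...,1).  The
    ``include_prior_constant`` switch drops the (K-1)! prior-density factor;
    it does not cancel between partitions with different group counts, so the
    default keeps it.
    """
    counts = np.asarray(type_counts)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("type_counts must be a length-K vector with K >= 2")
    if np.any(counts < 0):
        raise ValueError("negative interaction counts")
    k = len(counts)
    n = counts.sum()
    out = float(np.sum(gammaln(counts + 1)) - gammaln(n + k))
    if include_prior_constant:
        out += float(gammaln(k))
    return out


# ---------------------------------------------------------------------------
# Observation views
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationView:
    """Which pairs count as observed, as index arrays over ``drugs``.

    ``heldout`` views contain exactly the network's observations (unobserved
    pairs contribute to no counts); ``fully_observed`` views of a binary
    network contain every pair, with absent pairs as type 0.
    """

    drugs: tuple[str, ...]
    n_types: int
    u: np.ndarray  # (M,) first-endpoint indices
    v: np.ndarray  # (M,) second-endpoint indices
    t: np.ndarray  # (M,) type indices

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_observed(self) -> int:
        return len(self.u)

    def observed_types(self) -> dict[tuple[int, int], int]:
        return {
            (int(a), int(b)): int(tt)
            for a, b, tt in zip(self.u, self.v, self.t)
        }


def build_view(
    net: InteractionNetwork,
    mode: Mode = "heldout",
    exclude_pairs: Iterable[Pair] = (),
) -> ObservationView:
    """Build the sampler's observation view of a network.

    ``exclude_pairs`` masks pairs out of the view in either mode (used by the
    discovery simulation, where a target drug's untested pairs are unknown
    rather than absent).
    """
    k = len(net.alphabet)
    excluded = {_canon(*p) for p in exclude_pairs}
    u, v, t = [], [], []
    if mode == "heldout":
        for a, b in net.pairs():
            if (a, b) in excluded:
                continue
            u.append(net.drug_index(a))
            v.append(net.drug_index(b))
            t.append(net.get(a, b))
    elif mode == "fully_observed":
        if k != 2:
            raise ValueError("fully_observed mode requires a binary alphabet")
        for a, b in net.all_pairs():
            if (a, b) in excluded:
                continue
            u.append(net.drug_index(a))
            v.append(net.drug_index(b))
            t.append(net.get(a, b, default=0))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ObservationView(
        drugs=net.drugs,
        n_types=k,
        u=np.asarray(u, dtype=np.int64),
        v=np.asarray(v, dtype=np.int64),
        t=np.asarray(t, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """A group assignment plus its per-group-pair type-count tables.

    ``counts[a, b, k]`` is the number of observed interactions of type k
    between groups a and b (symmetric; the diagonal holds within-group pair
    counts once, not doubled).
    """

    drugs: tuple[str, ...]
    n_types: int
    assignment: np.ndarray  # (N,) group index per drug, in [0, N-1]
    counts: np.ndarray  # (G, G, K)

    @classmethod
    def from_assignment(
        cls,
        view: ObservationView,
        assignment: Sequence[int] | np.ndarray | Mapping[str, int],
    ) -> "Partition":
        if isinstance(assignment, Mapping):
            assignment = [assignment[d] for d in view.drugs]
        g = np.asarray(assignment, dtype=np.int64)
        if g.shape != (view.n_drugs,):
            raise ValueError("assignment length must equal the number of drugs")
        n = view.n_drugs
        counts = _count_table(g, view.u, view.v, view.t, n, view.n_types)
        return cls(view.drugs, view.n_types, g, counts)

    @property
    def n_groups(self) -> int:
        return len(np.unique(self.assignment))

    def group_of(self, drug: str) -> int:
        return int(self.assignment[self.drugs.index(drug)])


def _count_table(
    g: np.ndarray, u: np.ndarray, v: np.ndarray, t: np.ndarray, n_groups: int, k: int
) -> np.ndarray:
    """Symmetric (G, G, K) type-count table for an assignment."""
    counts = np.zeros((n_groups, n_groups, k), dtype=np.int64)
    np.add.at(counts, (g[u], g[v], t), 1)
    counts = counts + counts.swapaxes(0, 1)
    idx = np.arange(n_groups)
    counts[idx, idx, :] //= 2
    return counts


def compute_H(partition: Partition, include_prior_constant: bool = True) -> float:
    """Negative log partition weight, recomputed from scratch.

    Sums -log_pair_factor over all unordered group pairs including the
    diagonal.  Lower H means higher explanatory power.
    """
    g = partition.counts.shape[0]
    k = partition.n_types
    iu, ju = np.triu_indices(g)
    rows = partition.counts[iu, ju, :]  # (P, K)
    n = rows.sum(axis=1)
    lpf = gammaln(rows + 1).sum(axis=1) - gammaln(n + k)
    if include_prior_constant:
        # the constant only matters on pairs with observations; but adding it
        # for every potential group pair is a partition-independent shift
        # (same number of group pairs for all partitions at fixed G), so keep
        # the convention of counting it once per group pair.
        lpf = lpf + gammaln(k)
    return float(-lpf.sum())


# ---------------------------------------------------------------------------
# Metropolis kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_moves(
    g, counts, h, nbr_flat, nbr_off, typ_flat, tbl1, tblk,
    i_arr, b_arr, u_arr, c_scratch, used_scratch, touched_scratch,
):  # pragma: no cover - exercised via _ChainState
    """Batch of elementary Metropolis moves, updating state in place.

    For each proposed move of drug i from group a to group b, only the
    group-pair blocks involving a or b and a group containing a neighbor of
    i change; the H delta is accumulated from log-gamma lookup tables over
    exactly those blocks.  Random draws are supplied pre-generated so the
    chain is a deterministic function of (state, draws).
    """
    k = counts.shape[2]
    for m in range(len(i_arr)):
        i = i_arr[m]
        a = g[i]
        b = b_arr[m]
        if b >= a:
            b += 1
        # per-group type counts of i's neighbors
        n_t = 0
        for e in range(nbr_off[i], nbr_off[i + 1]):
            gr = g[nbr_flat[e]]
            if not used_scratch[gr]:
                used_scratch[gr] = True
                touched_scratch[n_t] = gr
                n_t += 1
            c_scratch[gr, typ_flat[e]] += 1
        # H delta over affected blocks
        d = 0.0
        for idx in range(n_t):
            gt = touched_scratch[idx]
            if gt == a or gt == b:
                continue
            s_old = 0.0
            s_new = 0.0
            tot_old = 0
            tot_new = 0
            for kk in range(k):
                v_old = counts[a, gt, kk]
                v_new = v_old - c_scratch[gt, kk]
                s_old += tbl1[v_old]
                s_new += tbl1[v_new]
                tot_old += v_old
                tot_new += v_new
            d += (s_new - tblk[tot_new]) - (s_old - tblk[tot_old])
            s_old = 0.0
            s_new = 0.0
            tot_old = 0
            tot_new = 0
            for kk in range(k):
                v_old = counts[b, gt, kk]
                v_new = v_old + c_scratch[gt, kk]
                s_old += tbl1[v_old]
                s_new += tbl1[v_new]
                tot_old += v_old
                tot_new += v_new
            d += (s_new - tblk[tot_new]) - (s_old - tblk[tot_old])
        # the three blocks rearranged among themselves:
        # (a,a) loses c[a], (b,b) gains c[b], (a,b) loses c[b] gains c[a]
        s_old = 0.0
        s_new = 0.0
        tot_old = 0
        tot_new = 0
        for kk in range(k):
            v_old = counts[a, a, kk]
            v_new = v_old - c_scratch[a, kk]
            s_old += tbl1[v_old]
            s_new += tbl1[v_new]
            tot_old += v_old
            tot_new += v_new
        d += (s_new - tblk[tot_new]) - (s_old - tblk[tot_old])
        s_old = 0.0
        s_new = 0.0
        tot_old = 0
        tot_new = 0
        for kk in range(k):
            v_old = counts[b, b, kk]
            v_new = v_old + c_scratch[b, kk]
            s_old += tbl1[v_old]
            s_new += tbl1[v_new]
            tot_old += v_old
            tot_new += v_new
        d += (s_new - tblk[tot_new]) - (s_old - tblk[tot_old])
        s_old = 0.0
        s_new = 0.0
        tot_old = 0
        tot_new = 0
        for kk in range(k):
            v_old = counts[a, b, kk]
            v_new = v_old - c_scratch[b, kk] + c_scratch[a, kk]
            s_old += tbl1[v_old]
            s_new += tbl1[v_new]
            tot_old += v_old
            tot_new += v_new
        d += (s_new - tblk[tot_new]) - (s_old - tblk[tot_old])
        dh = -d
        if dh <= 0.0 or u_arr[m] < np.exp(-dh):
            for idx in range(n_t):
                gt = touched_scratch[idx]
                if gt == a or gt == b:
                    continue
                for kk in range(k):
                    counts[a, gt, kk] -= c_scratch[gt, kk]
                    counts[gt, a, kk] = counts[a, gt, kk]
                    counts[b, gt, kk] += c_scratch[gt, kk]
                    counts[gt, b, kk] = counts[b, gt, kk]
            for kk in range(k):
                counts[a, a, kk] -= c_scratch[a, kk]
                counts[b, b, kk] += c_scratch[b, kk]
                ab = counts[a, b, kk] - c_scratch[b, kk] + c_scratch[a, kk]
                counts[a, b, kk] = ab
                counts[b, a, kk] = ab
            g[i] = b
            h += dh
        # reset scratch
        for idx in range(n_t):
            gt = touched_scratch[idx]
            used_scratch[gt] = False
            for kk in range(k):
                c_scratch[gt, kk] = 0
    return h


class _ChainState:
    """Live sampler state with incremental H bookkeeping.

    The move loop is a compiled kernel; randomness is pre-drawn per batch so
    a chain is a deterministic function of its seed.
    """

    def __init__(self, view: ObservationView, assignment: np.ndarray) -> None:
        self.view = view
        self.n = view.n_drugs
        self.k = view.n_types
        self.g = np.asarray(assignment, dtype=np.int64).copy()
        self.counts = _count_table(
            self.g, view.u, view.v, view.t, self.n, self.k
        )
        # flat neighbor lists (index + edge type), CSR-style offsets
        nbrs: list[list[int]] = [[] for _ in range(self.n)]
        typs: list[list[int]] = [[] for _ in range(self.n)]
        for a, b, t in zip(view.u, view.v, view.t):
            nbrs[a].append(b)
            typs[a].append(t)
            nbrs[b].append(a)
            typs[b].append(t)
        self._nbr_off = np.zeros(self.n + 1, dtype=np.int64)
        np.cumsum([len(x) for x in nbrs], out=self._nbr_off[1:])
        self._nbr_flat = np.asarray(
            [z for x in nbrs for z in x], dtype=np.int64
        )
        self._typ_flat = np.asarray(
            [z for x in typs for z in x], dtype=np.int64
        )
        # gammaln lookup tables; counts never exceed the number of edges
        m = view.n_observed + 2
        ar = np.arange(m, dtype=np.float64)
        self._tbl1 = gammaln(ar + 1)  # ln(n!)
        self._tblk = gammaln(ar + self.k) - gammaln(self.k)  # ln((n+K-1)!/(K-1)!)
        self._c_scratch = np.zeros((self.n, self.k), dtype=np.int64)
        self._used_scratch = np.zeros(self.n, dtype=np.bool_)
        self._touched_scratch = np.zeros(self.n, dtype=np.int64)
        self.h = self._h_from_scratch()

    def _lpf_rows(self, rows: np.ndarray) -> np.ndarray:
        return self._tbl1[rows].sum(axis=-1) - self._tblk[rows.sum(axis=-1)]

    def _h_from_scratch(self) -> float:
        iu, ju = np.triu_indices(self.n)
        return float(-self._lpf_rows(self.counts[iu, ju, :]).sum())

    def _moves(self, rng: np.random.Generator, n_moves: int) -> None:
        i_arr = rng.integers(0, self.n, size=n_moves)
        b_arr = rng.integers(0, self.n - 1, size=n_moves)
        u_arr = rng.random(n_moves)
        self.h = _run_moves(
            self.g, self.counts, self.h,
            self._nbr_flat, self._nbr_off, self._typ_flat,
            self._tbl1, self._tblk,
            i_arr, b_arr, u_arr,
            self._c_scratch, self._used_scratch, self._touched_scratch,
        )

    def step(self, rng: np.random.Generator) -> bool:
        """One elementary Metropolis move; returns True if accepted."""
        before = self.g.copy()
        self._moves(rng, 1)
        return not np.array_equal(before, self.g)

    def sweep(self, rng: np.random.Generator) -> None:
        """N elementary moves."""
        self._moves(rng, self.n)

    def sweeps(self, rng: np.random.Generator, n_sweeps: int) -> None:
        """A batch of sweeps in one kernel call (same draws as ``sweep``
        called repeatedly would consume, batched)."""
        self._moves(rng, self.n * n_sweeps)

    def partition(self) -> Partition:
        return Partition(
            self.view.drugs, self.k, self.g.copy(), self.counts.copy()
        )


def metropolis_step(
    partition: Partition, rng: np.random.Generator, view: ObservationView
) -> Partition:
    """One elementary move of the paper's rule, as a pure function.

    Proposes moving a uniformly chosen drug to a uniformly chosen other
    group; accepts always if H does not increase, else with probability
    exp(H - H').  Returns the (possibly unchanged) resulting partition.
    """
    state = _ChainState(view, partition.assignment)
    state.step(rng)
    return state.partition()


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis sampling protocol.

    Defaults follow the published protocol of 50 independent chains of 200
    thinned partitions each.  ``thinning`` is in sweeps (one sweep = N
    elementary moves); ``"auto"`` estimates the decorrelation time of H from
    a short calibration stretch after burn-in.
    """

    n_chains: int = 50
    samples_per_chain: int = 200
    seed: int = 0
    thinning: int | str = "auto"
    burnin_window: int = 20
    burnin_cap: int = 10_000
    calibration_sweeps: int = 50
    max_thinning: int = 25
    strict_thermalization: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.samples_per_chain < 1:
            raise ValueError("n_chains and samples_per_chain must be positive")
        if isinstance(self.thinning, str) and self.thinning != "auto":
            raise ValueError("thinning must be a positive int or 'auto'")
        if isinstance(self.thinning, int) and self.thinning < 1:
            raise ValueError("thinning must be a positive int or 'auto'")


@dataclass
class SampleSet:
    """Pooled partition samples from one or more chains.

    Holds the observation view they were drawn against, so posterior
    estimators can rebuild group-pair counts per sample and apply the
    leave-self-out correction for pairs that are themselves observed.
    """

    view: ObservationView
    assignments: np.ndarray  # (S, N) int32
    h_values: np.ndarray  # (S,)
    n_chains: int

    @property
    def n_samples(self) -> int:
        return self.assignments.shape[0]

    @property
    def drugs(self) -> tuple[str, ...]:
        return self.view.drugs

    def pair_index(self, pair: Pair) -> tuple[int, int]:
        a, b = pair
        return self.drugs.index(a), self.drugs.index(b)

    def save_trace(self, path) -> None:
        """Dump the per-sample H values and assignments as JSON (diagnostics)."""
        import json
        from pathlib import Path

        record = {
            "drugs": list(self.drugs),
            "n_chains": self.n_chains,
            "h": [float(h) for h in self.h_values],
            "assignments": self.assignments.tolist(),
        }
        Path(path).write_text(json.dumps(record))


def _thermalized(h_trace: list[float], window: int) -> bool:
    """Equilibration test: means of the two most recent windows of sweeps
    differ by no more than one pooled standard error."""
    if len(h_trace) < 2 * window:
        return False
    w1 = np.asarray(h_trace[-2 * window : -window])
    w2 = np.asarray(h_trace[-window:])
    se = np.sqrt((w1.var(ddof=0) + w2.var(ddof=0)) / window)
    return bool(abs(w1.mean() - w2.mean()) <= se)


def _estimate_thinning(h_cal: np.ndarray, cap: int) -> int:
    """First lag at which the autocorrelation of H drops below 1/e."""
    x = np.asarray(h_cal, dtype=np.float64)
    x = x - x.mean()
    var = float(np.dot(x, x))
    if var <= 0.0:
        return 1
    for lag in range(1, min(len(x) - 1, cap)):
        rho = float(np.dot(x[:-lag], x[lag:])) / var
        if rho < np.exp(-1):
            return lag
    return cap


def run_sampler(
    net: InteractionNetwork,
    config: SamplerConfig | None = None,
    mode: Mode = "heldout",
    exclude_pairs: Iterable[Pair] = (),
) -> SampleSet:
    """Run independent Metropolis chains and pool their partition samples.

    Each chain starts from an independent uniformly random assignment of the
    N drugs to N groups, discards a burn-in determined by the equilibration
    test, calibrates a thinning interval from the autocorrelation of H, then
    records ``samples_per_chain`` partitions one thinning interval apart.
    """
    config = config or SamplerConfig()
    view = build_view(net, mode=mode, exclude_pairs=exclude_pairs)
    n = view.n_drugs
    if n == 0:
        raise ValueError("network has no drugs")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_assign = np.empty(
        (config.n_chains * config.samples_per_chain, n), dtype=np.int32
    )
    all_h = np.empty(config.n_chains * config.samples_per_chain)
    pos = 0
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        state = _ChainState(view, rng.integers(0, n, size=n))
        h_trace: list[float] = []
        ok = False
        for _ in range(config.burnin_cap):
            state.sweep(rng)
            h_trace.append(state.h)
            if len(h_trace) % config.burnin_window == 0 and _thermalized(
                h_trace, config.burnin_window
            ):
                ok = True
                break
        if not ok:
            msg = (
                f"thermalization test not passed within {config.burnin_cap} "
                "sweeps; sampling anyway"
            )
            if config.strict_thermalization:
                raise RuntimeError(msg)
            warnings.warn(msg, ThermalizationWarning)
        if config.thinning == "auto":
            h_cal = np.empty(config.calibration_sweeps)
            for s in range(config.calibration_sweeps):
                state.sweep(rng)
                h_cal[s] = state.h
            thin = _estimate_thinning(h_cal, config.max_thinning)
        else:
            thin = int(config.thinning)
        for _ in range(config.samples_per_chain):
            for _ in range(thin):
                state.sweep(rng)
            all_assign[pos] = state.g
            all_h[pos] = state.h
            pos += 1
    return SampleSet(
        view=view,
        assignments=all_assign,
        h_values=all_h,
        n_chains=config.n_chains,
    )


# ---------------------------------------------------------------------------
# Posterior estimators
# ---------------------------------------------------------------------------

def _posterior_matrix(
    samples: SampleSet,
    pair_idx: np.ndarray,  # (P, 2) drug index pairs
    exclude_self: bool = True,
) -> np.ndarray:
    """Per-pair posterior type probabilities averaged over samples, (P, K).

    For every sample the Laplace-smoothed type rates between the two drugs'
    groups are accumulated; pairs that are themselves observed in the view
    have their own observation removed from the counts first (leave-self-out),
    so fully-observed scoring is not contaminated by the pair being scored.
    """
    view = samples.view
    n, k = view.n_drugs, view.n_types
    u, v, t = view.u, view.v, view.t
    obs = view.observed_types()
    p = pair_idx.shape[0]
    sub = np.zeros(p, dtype=bool)
    sub_t = np.zeros(p, dtype=np.int64)
    if exclude_self:
        for idx, (i, j) in enumerate(pair_idx):
            key = (min(i, j), max(i, j))
            alt = (max(i, j), min(i, j))
            tt = obs.get(key, obs.get(alt))
            if tt is not None:
                sub[idx] = True
                sub_t[idx] = tt
    acc = np.zeros((p, k))
    ii, jj = pair_idx[:, 0], pair_idx[:, 1]
    for s in range(samples.n_samples):
        g = samples.assignments[s].astype(np.int64)
        counts = _count_table(g, u, v, t, n, k)
        ntot = counts.sum(axis=-1)
        nk_pair = counts[g[ii], g[jj], :].astype(np.float64)
        n_pair = ntot[g[ii], g[jj]].astype(np.float64)
        if sub.any():
            nk_pair[np.arange(p)[sub], sub_t[sub]] -= 1.0
            n_pair[sub] -= 1.0
        est = (nk_pair + 1.0) / (n_pair + k)[:, None]
        acc += est
    acc /= samples.n_samples
    acc /= acc.sum(axis=1, keepdims=True)
    return acc


def link_type_posterior(
    samples: SampleSet, pair: Pair, exclude_self: bool = True
) -> np.ndarray:
    """Posterior probability of each interaction type for one drug pair.

    Plain average of the per-sample Laplace estimator (the chain already
    samples partitions proportionally to exp(-H)), normalized to sum to 1.
    """
    i, j = samples.pair_index(pair)
    if i == j:
        raise ValueError("self-pairs have no interaction type")
    return _posterior_matrix(
        samples, np.asarray([[i, j]], dtype=np.int64), exclude_self
    )[0]


def score_all_pairs(
    net: InteractionNetwork,
    config: SamplerConfig | None = None,
    mode: Mode = "heldout",
    samples: SampleSet | None = None,
) -> dict[Pair, np.ndarray]:
    """Posterior type probabilities for every drug pair from one sampler run.

    Pass a pre-computed ``samples`` to reuse a run; otherwise the sampler is
    run with ``config``.  In fully-observed mode each observed pair's own
    contribution is removed from the counts before it is scored.
    """
    if samples is None:
        samples = run_sampler(net, config, mode=mode)
    drugs = samples.drugs
    n = len(drugs)
    iu, ju = np.triu_indices(n, k=1)
    pair_idx = np.stack([iu, ju], axis=1)
    probs = _posterior_matrix(samples, pair_idx, exclude_self=True)
    return {
        (drugs[i], drugs[j]): probs[row]
        for row, (i, j) in enumerate(pair_idx)
    }


def coclassification_matrix(samples: SampleSet) -> np.ndarray:
    """Probability that each drug pair shares a group, (N, N), diagonal 1."""
    if samples.n_samples == 0:
        raise ValueError("empty sample set")
    n = samples.view.n_drugs
    acc = np.zeros((n, n))
    for s in range(samples.n_samples):
        g = samples.assignments[s]
        acc += g[:, None] == g[None, :]
    return acc / samples.n_samples
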