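"""Evaluation protocols: sub-sampling validation, snapshot ROC, discovery loop.

Predictors are evaluated exactly as an experimenter would use them: fit on
the interactions observed so far, query the rest.  The metrics are the exact
classification rate, the within-one-level rate for ordered type alphabets,
rank-based AUROC (Mann-Whitney with ties counted one half), and sensitivity/
specificity curves.  The discovery simulation replays the iterative
suggest-test-update loop for a new drug with a single known seed interaction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .benchmarks import (
    PrismConfig,
    _similarity_matrix,
    baseline_predict,
    neighbor_predict,
    prism_partition,
    prism_predict,
)
from .network import (
    InteractionNetwork,
    Pair,
    TypeAlphabet,
    _canon,
    diff_snapshots,
)
from .sbm import SamplerConfig, run_sampler, score_all_pairs

__all__ = [
    "Predictor",
    "BaselinePredictor",
    "NeighborPredictor",
    "PrismPredictor",
    "SBMPredictor",
    "PREDICTORS",
    "ValidationResult",
    "RocResult",
    "DiscoveryTrace",
    "classify_from_probs",
    "within_one_correct",
    "subsample_validate",
    "relative_improvement",
    "auroc",
    "sensitivity_specificity_curve",
    "evaluate_snapshots",
    "discovery_simulation",
]


# ---------------------------------------------------------------------------
# Predictor interface
# ---------------------------------------------------------------------------

class Predictor:
    """Fit-on-observed / predict-on-query interface shared by all methods."""

    name = "predictor"

    def predict_pairs(
        self,
        net: InteractionNetwork,
        pairs: Sequence[Pair],
        seed: int = 0,
    ) -> dict[Pair, np.ndarray]:
        raise NotImplementedError


class BaselinePredictor(Predictor):
    """Overall type rates of the training network, for every query."""

    name = "baseline"

    def predict_pairs(self, net, pairs, seed=0):
        probs = baseline_predict(net)
        return {_canon(*p): probs.copy() for p in pairs}


class NeighborPredictor(Predictor):
    """Most-similar-pair transfer prediction."""

    name = "neighbor"

    def predict_pairs(self, net, pairs, seed=0):
        sim = _similarity_matrix(net)
        return {
            _canon(*p): neighbor_predict(net, p, similarity=sim) for p in pairs
        }


class PrismPredictor(Predictor):
    """Prism II: one monochromatic partition, Laplace estimator on it."""

    name = "prism"

    def __init__(self, config: PrismConfig | None = None) -> None:
        self.config = config or PrismConfig()

    def predict_pairs(self, net, pairs, seed=0):
        part = prism_partition(net, self.config)
        return {_canon(*p): prism_predict(part, net, p) for p in pairs}


class SBMPredictor(Predictor):
    """Bayesian average over stochastic block models."""

    name = "sbm"

    def __init__(
        self,
        config: SamplerConfig | None = None,
        mode: str = "heldout",
    ) -> None:
        self.config = config or SamplerConfig()
        self.mode = mode

    def predict_pairs(self, net, pairs, seed=0):
        config = SamplerConfig(
            **{
                **self.config.__dict__,
                "seed": int(np.random.SeedSequence([self.config.seed, seed])
                            .generate_state(1)[0] % (2**31)),
            }
        )
        scores = score_all_pairs(net, config, mode=self.mode)
        return {_canon(*p): scores[_canon(*p)] for p in pairs}


PREDICTORS: dict[str, Callable[[], Predictor]] = {
    "baseline": BaselinePredictor,
    "neighbor": NeighborPredictor,
    "prism": PrismPredictor,
    "sbm": SBMPredictor,
}


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

def classify_from_probs(probs: np.ndarray) -> int:
    """Argmax type index; ties go to the lowest index."""
    return int(np.argmax(probs))


def within_one_correct(
    predicted: int, truth: int, alphabet: TypeAlphabet
) -> bool:
    """Whether a prediction is within one level of the truth on the ordered
    type scale (e.g. synergistic predicted as additive counts as correct,
    synergistic as suppressing does not)."""
    if not alphabet.ordered:
        raise ValueError("within-one metric requires an ordered alphabet")
    return abs(int(predicted) - int(truth)) <= 1


@dataclass
class ValidationResult:
    """Sub-sampling validation accuracies for one predictor at one f."""

    predictor: str
    observed_fraction: float
    exact: np.ndarray  # per-repetition exact accuracy
    within_one: np.ndarray | None  # per-repetition, None if unordered

    @property
    def exact_mean(self) -> float:
        return float(self.exact.mean())

    @property
    def exact_sem(self) -> float:
        return float(self.exact.std(ddof=1) / math.sqrt(len(self.exact)))

    @property
    def within_one_mean(self) -> float | None:
        return None if self.within_one is None else float(self.within_one.mean())

    @property
    def within_one_sem(self) -> float | None:
        if self.within_one is None:
            return None
        return float(self.within_one.std(ddof=1) / math.sqrt(len(self.within_one)))


def subsample_validate(
    net: InteractionNetwork,
    predictor: Predictor,
    f: float,
    n_reps: int = 10,
    seed: int = 0,
) -> ValidationResult:
    """Repeated random sub-sampling validation on an exhaustive network.

    Per repetition a uniformly random ceil(f*M) subset of the M observed
    pairs is kept as training data; the predictor is queried on the
    complement and scored by exact (and, for ordered alphabets, within-one)
    classification.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("observed fraction f must be in (0, 1)")
    all_obs = sorted(net.observations().items())
    m = len(all_obs)
    keep = math.ceil(f * m)
    if keep < 1:
        raise ValueError("f*M < 1: nothing to train on")
    rng = np.random.default_rng(seed)
    exact = np.empty(n_reps)
    w1 = np.empty(n_reps) if net.alphabet.ordered else None
    for rep in range(n_reps):
        idx = rng.permutation(m)
        train_pairs = [all_obs[i][0] for i in idx[:keep]]
        test = [all_obs[i] for i in idx[keep:]]
        train = net.keeping_pairs(train_pairs)
        rep_seed = int(rng.integers(2**31))
        preds = predictor.predict_pairs(train, [p for p, _ in test], seed=rep_seed)
        hits = 0
        hits1 = 0
        for p, truth in test:
            pred = classify_from_probs(preds[_canon(*p)])
            hits += pred == truth
            if w1 is not None:
                hits1 += within_one_correct(pred, truth, net.alphabet)
        exact[rep] = hits / len(test)
        if w1 is not None:
            w1[rep] = hits1 / len(test)
    return ValidationResult(
        predictor=predictor.name,
        observed_fraction=f,
        exact=exact,
        within_one=w1,
    )


def relative_improvement(f_sbm: float, f_x: float, f_baseline: float) -> float:
    """Improvement of the block-model accuracy over method X, measured
    relative to the baseline: (F_SBM - F_X) / (F_X - F_B).

    Returns NaN (with a warning) when X ties the baseline.  When X is below
    the baseline the denominator is negative and the sign flips: a positive
    numerator then yields a negative "improvement", flagging that the
    comparison is against a method that underperforms the trivial rate.
    """
    denom = f_x - f_baseline
    if denom == 0.0:
        warnings.warn("method X ties the baseline; relative improvement undefined")
        return float("nan")
    return (f_sbm - f_x) / denom


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

def auroc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Mann-Whitney AUROC: probability that a random positive outscores a
    random negative, ties counted one half."""
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


@dataclass
class RocResult:
    """Sensitivity/specificity curve over all score thresholds."""

    thresholds: np.ndarray  # descending distinct scores
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float

    def specificity_at_sensitivity(self, s: float) -> float:
        """Best specificity among operating points with sensitivity >= s."""
        ok = self.sensitivity >= s
        if not ok.any():
            return 0.0
        return float(self.specificity[ok].max())

    def sensitivity_at_specificity(self, s: float) -> float:
        ok = self.specificity >= s
        if not ok.any():
            return 0.0
        return float(self.sensitivity[ok].max())

    def trapezoid_area(self) -> float:
        """Area under sensitivity vs (1 - specificity); equals the
        Mann-Whitney AUROC."""
        x = np.concatenate([[0.0], 1.0 - self.specificity, [1.0]])
        y = np.concatenate([[0.0], self.sensitivity, [1.0]])
        return float(np.trapezoid(y, x))


def sensitivity_specificity_curve(
    scores_pos: Sequence[float], scores_neg: Sequence[float]
) -> RocResult:
    """ROC curve: classify "positive" when score >= threshold, for every
    distinct score threshold (descending)."""
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auroc=auroc(pos, neg),
    )


# ---------------------------------------------------------------------------
# Snapshot evaluation
# ---------------------------------------------------------------------------

def _expanded_binary(net: InteractionNetwork) -> InteractionNetwork:
    """Binary network with explicit type-0 observations for absent pairs."""
    obs = {}
    for a, b in net.all_pairs():
        obs[(a, b)] = net.get(a, b, default=0)
    return InteractionNetwork(net.drugs, net.alphabet, obs)


def snapshot_scores(
    net1: InteractionNetwork,
    predictor: Predictor,
    seed: int = 0,
) -> dict[Pair, float]:
    """Interaction scores p(interaction) for every pair of a binary network,
    treating it as fully observed (absence = confirmed non-interaction)."""
    if len(net1.alphabet) != 2:
        raise ValueError("snapshot scoring requires a binary network")
    pairs = list(net1.all_pairs())
    if isinstance(predictor, SBMPredictor):
        pred = SBMPredictor(predictor.config, mode="fully_observed")
        probs = pred.predict_pairs(net1, pairs, seed=seed)
    elif isinstance(predictor, BaselinePredictor):
        rate = len(net1.edge_set()) / len(pairs)
        probs = {p: np.array([1 - rate, rate]) for p in pairs}
    else:
        expanded = _expanded_binary(net1)
        probs = predictor.predict_pairs(expanded, pairs, seed=seed)
    return {p: float(v[1]) for p, v in probs.items()}


def evaluate_snapshots(
    net1: InteractionNetwork,
    net2: InteractionNetwork,
    predictor: Predictor,
    seed: int = 0,
) -> tuple[RocResult, RocResult]:
    """Score the first snapshot and test against the second one's changes.

    Novel detection: positives are pairs added in the second snapshot,
    negatives pairs never added; score is p(interaction).  Spurious
    detection: positives are pairs removed in the second snapshot and should
    score LOW against the persistent edges, so the ROC is computed on
    negated scores.
    """
    diff = diff_snapshots(net1, net2)
    if not diff.novel or not diff.spurious:
        raise ValueError("snapshots must differ in both directions")
    shared = sorted(diff.shared_drugs)
    base = net1.restricted_to(shared)
    scores = snapshot_scores(base, predictor, seed=seed)
    novel_roc = sensitivity_specificity_curve(
        [scores[p] for p in sorted(diff.novel)],
        [scores[p] for p in sorted(diff.never_added)],
    )
    spurious_roc = sensitivity_specificity_curve(
        [-scores[p] for p in sorted(diff.spurious)],
        [-scores[p] for p in sorted(diff.persistent)],
    )
    return novel_roc, spurious_roc


# ---------------------------------------------------------------------------
# Discovery simulation
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryTrace:
    """Replay of the iterative suggest-test-update discovery loop."""

    target: str
    queried: list[str]
    hits: list[bool]
    cumulative: np.ndarray  # hits after each query
    upper_bound: np.ndarray  # all hits first
    lower_bound: np.ndarray  # expectation of uniformly random querying
    true_degree: int


def discovery_simulation(
    net: InteractionNetwork,
    target: str,
    seed_partner: str,
    n_iters: int,
    config: SamplerConfig | None = None,
    reuse_samples: bool = False,
) -> DiscoveryTrace:
    """Simulate guided discovery of a new drug's interactions.

    ``net`` is the binary ground truth.  All of the target's pairs start
    unknown except the seed interaction.  Each iteration runs the block-model
    sampler with the remaining unknown target pairs masked, scores them,
    queries the candidate with the highest p(interaction) (ties broken
    alphabetically), reveals the truth — interaction or confirmed
    non-interaction — and repeats.  With ``reuse_samples`` a single initial
    sampler run scores all iterations (faster, slightly stale).
    """
    if len(net.alphabet) != 2:
        raise ValueError("discovery simulation requires a binary network")
    config = config or SamplerConfig()
    edges = net.edge_set()
    true_partners = {
        (b if a == target else a) for a, b in edges if target in (a, b)
    }
    if not true_partners:
        raise ValueError(f"target {target!r} has no true interactions")
    if seed_partner not in true_partners:
        raise ValueError(
            f"seed partner {seed_partner!r} does not truly interact with the target"
        )
    candidates = sorted(set(net.drugs) - {target, seed_partner})
    # current knowledge: everything except the target's unqueried pairs
    known: dict[Pair, int] = {}
    known[_canon(target, seed_partner)] = 1
    queried: list[str] = []
    hits: list[bool] = []
    samples = None
    for it in range(n_iters):
        unknown = [z for z in candidates if z not in queried]
        if not unknown:
            break
        masked = [_canon(target, z) for z in unknown]
        current = net.updated(known)
        if samples is None or not reuse_samples:
            run_config = SamplerConfig(
                **{**config.__dict__, "seed": int(
                    np.random.SeedSequence([config.seed, it]).generate_state(1)[0]
                    % (2**31)
                )}
            )
            samples = run_sampler(
                current, run_config, mode="fully_observed", exclude_pairs=masked
            )
        from .sbm import _posterior_matrix  # local import to avoid cycle noise

        pair_idx = np.asarray(
            [[samples.drugs.index(target), samples.drugs.index(z)] for z in unknown],
            dtype=np.int64,
        )
        probs = _posterior_matrix(samples, pair_idx, exclude_self=False)
        order = np.lexsort((np.asarray(unknown), -probs[:, 1]))
        best = unknown[int(order[0])]
        hit = best in true_partners
        queried.append(best)
        hits.append(hit)
        known[_canon(target, best)] = 1 if hit else 0
        if reuse_samples and hit:
            samples = None  # re-run once new positive evidence arrives
    cumulative = np.cumsum(np.asarray(hits, dtype=np.int64)) if hits else np.zeros(0, dtype=np.int64)
    d = len(true_partners) - 1  # discoverable beyond the seed
    n_cand = len(candidates)
    q = np.arange(1, len(hits) + 1)
    upper = np.minimum(q, d)
    lower = q * d / n_cand if n_cand else np.zeros_like(q, dtype=float)
    return DiscoveryTrace(
        target=target,
        queried=queried,
        hits=hits,
        cumulative=cumulative,
        upper_bound=upper,
        lower_bound=lower,
        true_degree=len(true_partners),
    )
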