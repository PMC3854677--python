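"""Planted-partition generators: ground-truth networks for every protocol.

Two regimes mirror the kinds of data the predictors are meant for: small
exhaustive pairwise-interaction matrices with 3- or 4-type alphabets (the
anti-fungal and antibiotic combination screens), and large sparse binary
networks with planted group structure (interaction databases).  Every drug
pair draws its type from the distribution attached to its group pair, so the
generating partition is known exactly and recovery can be measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import (
    BINARY,
    InteractionNetwork,
    Pair,
    SnapshotDiff,
    TypeAlphabet,
    diff_snapshots,
)

__all__ = [
    "PlantedModel",
    "PlantedNetwork",
    "generate_planted_network",
    "monochromatic_theta",
    "planted_binary_network",
    "perturb_snapshot",
    "make_exhaustive_fixture",
    "COKOL_ALPHABET",
    "YEH_ALPHABET",
]

#: 3-type ordered alphabet of the anti-fungal combination screen.
COKOL_ALPHABET = TypeAlphabet(
    ("synergistic", "additive", "antagonistic"), ordered=True
)

#: 4-type ordered alphabet of the antibiotic combination screen.
YEH_ALPHABET = TypeAlphabet(
    ("synergistic", "additive", "antagonistic", "suppressing"), ordered=True
)


@dataclass(frozen=True)
class PlantedModel:
    """A stochastic block model read generatively.

    ``theta[a, b]`` is the length-K type distribution of pairs between
    groups a and b (symmetric; rows sum to 1).  ``observed_fraction`` marks
    a uniformly random share of pairs as observed.
    """

    group_sizes: tuple[int, ...]
    alphabet: TypeAlphabet
    theta: np.ndarray
    observed_fraction: float = 1.0
    seed: int = 0
    drug_prefix: str = "D"

    def __post_init__(self) -> None:
        g = len(self.group_sizes)
        theta = np.asarray(self.theta, dtype=np.float64)
        if theta.shape != (g, g, len(self.alphabet)):
            raise ValueError("theta must have shape (G, G, K)")
        if not np.allclose(theta, theta.swapaxes(0, 1)):
            raise ValueError("theta must be symmetric in the group indices")
        if not np.allclose(theta.sum(axis=-1), 1.0):
            raise ValueError("each theta row must sum to 1")
        if np.any(theta < 0):
            raise ValueError("theta entries must be nonnegative")
        if not 0.0 < self.observed_fraction <= 1.0:
            raise ValueError("observed_fraction must be in (0, 1]")
        object.__setattr__(self, "theta", theta)

    @property
    def n_drugs(self) -> int:
        return int(sum(self.group_sizes))


@dataclass(frozen=True)
class PlantedNetwork:
    """Ground truth plus the observed view drawn from a planted model."""

    truth: InteractionNetwork  # every pair typed
    observed: InteractionNetwork  # the observed_fraction subset
    assignment: dict[str, int]  # drug -> planted group


def monochromatic_theta(
    n_groups: int, n_types: int, dominant_prob: float, offset: int = 0
) -> np.ndarray:
    """Type distributions with one dominant type per group pair.

    The dominant type of groups (a, b) is ``(a + b + offset) mod K``, which
    gives every group a distinct interaction profile, so the planted
    partition is identifiable.  The remaining probability mass is spread
    evenly over the other types.
    """
    if not 1.0 / n_types <= dominant_prob <= 1.0:
        raise ValueError("dominant_prob must be in [1/K, 1]")
    theta = np.full(
        (n_groups, n_groups, n_types), (1.0 - dominant_prob) / (n_types - 1)
    )
    for a in range(n_groups):
        for b in range(n_groups):
            theta[a, b, (a + b + offset) % n_types] = dominant_prob
    return theta


def generate_planted_network(model: PlantedModel) -> PlantedNetwork:
    """Draw a full typed network (and its observed view) from the model."""
    rng = np.random.default_rng(model.seed)
    n = model.n_drugs
    width = max(3, len(str(n - 1)))
    drugs = [f"{model.drug_prefix}{i:0{width}d}" for i in range(n)]
    groups = np.repeat(np.arange(len(model.group_sizes)), model.group_sizes)
    k = len(model.alphabet)
    obs_full: dict[Pair, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            t = int(rng.choice(k, p=model.theta[groups[i], groups[j]]))
            obs_full[(drugs[i], drugs[j])] = t
    truth = InteractionNetwork(drugs, model.alphabet, obs_full)
    pairs = sorted(obs_full)
    if model.observed_fraction < 1.0:
        keep = math.ceil(model.observed_fraction * len(pairs))
        idx = rng.permutation(len(pairs))[:keep]
        observed = truth.keeping_pairs([pairs[i] for i in idx])
    else:
        observed = truth
    assignment = {d: int(g) for d, g in zip(drugs, groups)}
    return PlantedNetwork(truth=truth, observed=observed, assignment=assignment)


def planted_binary_network(
    n_drugs: int,
    n_groups: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
    drug_prefix: str = "D",
) -> tuple[InteractionNetwork, dict[str, int]]:
    """Assortative binary planted partition; only positive edges are stored
    (database-snapshot convention: absent pairs mean no reported
    interaction)."""
    if n_drugs % n_groups:
        raise ValueError("n_drugs must be divisible by n_groups")
    size = n_drugs // n_groups
    theta = np.empty((n_groups, n_groups, 2))
    for a in range(n_groups):
        for b in range(n_groups):
            p = p_in if a == b else p_out
            theta[a, b] = (1.0 - p, p)
    model = PlantedModel(
        group_sizes=(size,) * n_groups,
        alphabet=BINARY,
        theta=theta,
        seed=seed,
        drug_prefix=drug_prefix,
    )
    planted = generate_planted_network(model)
    positives = {
        p: 1 for p, t in planted.truth.observations().items() if t == 1
    }
    net = InteractionNetwork(planted.truth.drugs, BINARY, positives)
    return net, planted.assignment


def perturb_snapshot(
    net: InteractionNetwork, n_novel: int, n_spurious: int, seed: int = 0
) -> tuple[InteractionNetwork, SnapshotDiff]:
    """Degrade a binary network into an earlier snapshot of itself.

    ``n_novel`` randomly chosen true edges are hidden (they "appear" in the
    later snapshot, so they are its novel interactions and carry the
    network's structure) and ``n_spurious`` random non-edges are injected
    (they are "removed" later, i.e. spurious).  Returns the degraded
    snapshot and the exact diff against ``net``.
    """
    rng = np.random.default_rng(seed)
    edges = sorted(net.edge_set())
    non_edges = sorted(set(net.all_pairs()) - set(edges))
    if n_novel > len(edges):
        raise ValueError("not enough edges to hide")
    if n_spurious > len(non_edges):
        raise ValueError("not enough non-edges to inject")
    hide = {edges[i] for i in rng.choice(len(edges), size=n_novel, replace=False)}
    inject = {
        non_edges[i]
        for i in rng.choice(len(non_edges), size=n_spurious, replace=False)
    }
    obs = {p: 1 for p in net.edge_set() if p not in hide}
    obs.update({p: 1 for p in inject})
    earlier = InteractionNetwork(net.drugs, net.alphabet, obs)
    diff = diff_snapshots(earlier, net)
    return earlier, diff


def make_exhaustive_fixture(
    style: Literal["cokol", "yeh"], seed: int = 0
) -> InteractionNetwork:
    """Small exhaustively-typed interaction matrix, planted-model generated.

    ``cokol`` style: 13 drugs, 3 ordered types, all 78 pairs typed, four
    mechanism groups.  ``yeh`` style: 21 drugs, 4 ordered types, all 210
    pairs typed, six mechanism groups.  Group-pair type distributions put
    0.8 on a dominant type, matching the strong-but-imperfect
    monochromaticity of real combination screens.  These are synthetic
    stand-ins generated from documented parameters, not transcriptions of
    the published matrices.
    """
    if style == "cokol":
        sizes = (4, 3, 3, 3)
        alphabet = COKOL_ALPHABET
    elif style == "yeh":
        sizes = (4, 4, 4, 3, 3, 3)
        alphabet = YEH_ALPHABET
    else:
        raise ValueError(f"unknown fixture style {style!r}")
    theta = monochromatic_theta(len(sizes), len(alphabet), 0.8)
    model = PlantedModel(
        group_sizes=sizes, alphabet=alphabet, theta=theta, seed=seed
    )
    return generate_planted_network(model).truth
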