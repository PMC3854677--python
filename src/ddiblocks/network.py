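"""Typed undirected interaction networks: containers, edge-list I/O, snapshot diffs.

A network records, for a set of drugs, which unordered pairs have a reported
interaction and of which type.  Types come from a small alphabet that may be
linearly ordered (e.g. synergistic < additive < antagonistic < suppressing).
Binary interaction databases are represented with the two-letter alphabet
``{no-interaction, interaction}``, storing only the positive edges; absent
pairs are then interpreted as type 0 wherever a fully-observed reading of the
network is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "TypeAlphabet",
    "InteractionNetwork",
    "SnapshotDiff",
    "NetworkFormatError",
    "ConflictingObservationError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "diff_snapshots",
    "BINARY",
]

Pair = tuple[str, str]


class NetworkFormatError(ValueError):
    """Malformed edge-list input (bad columns, unknown type label)."""


class ConflictingObservationError(ValueError):
    """The same drug pair reported twice with two different types."""


class NetworkValidationError(ValueError):
    """Structurally invalid network content (self-loop, unknown drug...)."""


def _canon(a: str, b: str) -> Pair:
    """Canonical (sorted) form of an unordered drug pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class TypeAlphabet:
    """The alphabet of interaction types.

    Parameters
    ----------
    labels
        K distinct type names; their position is the type index.
    ordered
        Whether the label order is a semantic severity scale (enables the
        "within one level" classification metric).
    polarity
        Optional per-type role for the monochromaticity entropy of the
        Prism II predictor: ``'-'`` (synergistic-like), ``'+'``
        (antagonistic-like) or ``None`` (neutral, e.g. additive).  When not
        given, roles are inferred from the label names, and a two-letter
        alphabet maps to ``('-', '+')``.
    """

    labels: tuple[str, ...]
    ordered: bool = False
    polarity: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("alphabet needs at least two types")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("type labels must be unique")
        if self.polarity is not None:
            pol = tuple(self.polarity)
            if len(pol) != len(self.labels) or any(
                p not in ("-", "+", None) for p in pol
            ):
                raise ValueError("polarity must give '-', '+' or None per type")
            object.__setattr__(self, "polarity", pol)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown interaction type {label!r}") from None

    def roles(self) -> tuple[str | None, ...]:
        """Polarity of each type, inferring defaults when unset."""
        if self.polarity is not None:
            return self.polarity
        if len(self) == 2:
            return ("-", "+")
        out: list[str | None] = []
        for lab in self.labels:
            low = lab.lower()
            if low.startswith("syn"):
                out.append("-")
            elif low.startswith(("ant", "sup")):
                out.append("+")
            else:
                out.append(None)
        return tuple(out)


#: Alphabet for binary (interaction / no-interaction) networks.
BINARY = TypeAlphabet(("no-interaction", "interaction"), ordered=False)


@dataclass(frozen=True)
class SnapshotDiff:
    """Partition of shared-drug pairs between two snapshots of a network.

    ``persistent`` pairs are edges of both snapshots, ``novel`` pairs are
    edges of the second snapshot only, ``spurious`` of the first only, and
    ``never_added`` of neither.  The four sets tile all pairs of drugs
    present in both snapshots.
    """

    shared_drugs: frozenset[str]
    persistent: frozenset[Pair]
    novel: frozenset[Pair]
    spurious: frozenset[Pair]
    never_added: frozenset[Pair]


class InteractionNetwork:
    """An undirected network of typed drug-drug interactions.

    Drugs are opaque string identifiers.  Observations map unordered pairs to
    type indices of ``alphabet``; lookups are orientation-independent and
    self-pairs are rejected.
    """

    def __init__(
        self,
        drugs: Iterable[str],
        alphabet: TypeAlphabet,
        observations: Mapping[Pair, int] | Iterable[tuple[Pair, int]] = (),
    ) -> None:
        self.alphabet = alphabet
        obs_items = (
            observations.items() if isinstance(observations, Mapping) else observations
        )
        self._obs: dict[Pair, int] = {}
        drug_set = {str(d) for d in drugs}
        for (a, b), t in obs_items:
            if a == b:
                raise NetworkValidationError(f"self-interaction {a!r}-{b!r}")
            if not 0 <= int(t) < len(alphabet):
                raise NetworkValidationError(
                    f"type index {t} out of range for K={len(alphabet)}"
                )
            key = _canon(a, b)
            prev = self._obs.get(key)
            if prev is not None and prev != int(t):
                raise ConflictingObservationError(
                    f"pair {key} reported with conflicting types {prev} and {t}"
                )
            self._obs[key] = int(t)
            drug_set.add(a)
            drug_set.add(b)
        self.drugs: tuple[str, ...] = tuple(sorted(drug_set))
        self._index = {d: i for i, d in enumerate(self.drugs)}

    # -- basic protocol ---------------------------------------------------
    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_observations(self) -> int:
        return len(self._obs)

    def drug_index(self, drug: str) -> int:
        try:
            return self._index[drug]
        except KeyError:
            raise KeyError(f"unknown drug {drug!r}") from None

    def __contains__(self, drug: object) -> bool:
        return drug in self._index

    def observations(self) -> dict[Pair, int]:
        return dict(self._obs)

    def pairs(self) -> Iterator[Pair]:
        """Observed pairs, in canonical order."""
        return iter(sorted(self._obs))

    def all_pairs(self) -> Iterator[Pair]:
        """Every unordered drug pair, observed or not."""
        for i, a in enumerate(self.drugs):
            for b in self.drugs[i + 1 :]:
                yield (a, b)

    def has(self, a: str, b: str) -> bool:
        return _canon(a, b) in self._obs

    def get(self, a: str, b: str, default: int | None = None) -> int | None:
        if a == b:
            raise NetworkValidationError("self-pairs have no interaction type")
        return self._obs.get(_canon(a, b), default)

    def type_counts(self) -> np.ndarray:
        """Number of observed interactions of each type (length K)."""
        counts = np.zeros(len(self.alphabet), dtype=np.int64)
        for t in self._obs.values():
            counts[t] += 1
        return counts

    def edge_set(self) -> frozenset[Pair]:
        """Edges for presence/absence purposes.

        For a binary (K=2) alphabet only positive observations count as
        edges; for richer alphabets every observed pair is an edge.
        """
        if len(self.alphabet) == 2:
            return frozenset(p for p, t in self._obs.items() if t == 1)
        return frozenset(self._obs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            self.drugs == other.drugs
            and self.alphabet == other.alphabet
            and self._obs == other._obs
        )

    def __repr__(self) -> str:
        return (
            f"InteractionNetwork({self.n_drugs} drugs, "
            f"{self.n_observations} observations, K={len(self.alphabet)})"
        )

    # -- derived networks -------------------------------------------------
    def restricted_to(self, drugs: Iterable[str]) -> "InteractionNetwork":
        keep = set(drugs)
        obs = {p: t for p, t in self._obs.items() if p[0] in keep and p[1] in keep}
        return InteractionNetwork(keep & set(self.drugs), self.alphabet, obs)

    def keeping_pairs(self, pairs: Iterable[Pair]) -> "InteractionNetwork":
        keep = {_canon(*p) for p in pairs}
        obs = {p: t for p, t in self._obs.items() if p in keep}
        return InteractionNetwork(self.drugs, self.alphabet, obs)

    def updated(self, new_obs: Mapping[Pair, int]) -> "InteractionNetwork":
        obs = dict(self._obs)
        for p, t in new_obs.items():
            obs[_canon(*p)] = t
        return InteractionNetwork(self.drugs, self.alphabet, obs)


# -- I/O -------------------------------------------------------------------

def read_network(path: str | Path, alphabet: TypeAlphabet) -> InteractionNetwork:
    """Read a typed edge list.

    Format: UTF-8 text, one ``drug_a<TAB>drug_b<TAB>type`` row per line
    (comma-separated also accepted); ``#`` starts a comment.  The special
    comments ``#drugs: a,b,c`` and ``#alphabet: x,y,z`` declare isolated
    drugs and document the type order.  Duplicate rows with the same type
    collapse silently; conflicting duplicates are an error.
    """
    path = Path(path)
    drugs: set[str] = set()
    obs: dict[Pair, int] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("drugs:"):
                    names = body.split(":", 1)[1]
                    drugs.update(n.strip() for n in names.split(",") if n.strip())
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            fields = [f.strip() for f in fields]
            if len(fields) != 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            a, b, label = fields
            if a == b:
                raise NetworkValidationError(
                    f"{path}:{lineno}: self-interaction {a!r}"
                )
            if label not in alphabet:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown interaction type {label!r}"
                )
            t = alphabet.index(label)
            key = _canon(a, b)
            prev = obs.get(key)
            if prev is not None and prev != t:
                raise ConflictingObservationError(
                    f"{path}:{lineno}: pair {key} reported as both "
                    f"{alphabet.labels[prev]!r} and {label!r}"
                )
            obs[key] = t
    return InteractionNetwork(drugs, alphabet, obs)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write the edge-list format of :func:`read_network` (round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# drug_a\tdrug_b\ttype\n")
        fh.write(f"#alphabet: {','.join(net.alphabet.labels)}\n")
        fh.write(f"#drugs: {','.join(net.drugs)}\n")
        for a, b in net.pairs():
            t = net.get(a, b)
            fh.write(f"{a}\t{b}\t{net.alphabet.labels[t]}\n")


# -- snapshot diffing ------------------------------------------------------

def diff_snapshots(
    net1: InteractionNetwork, net2: InteractionNetwork
) -> SnapshotDiff:
    """Classify every shared-drug pair by its fate between two snapshots.

    Restricted to drugs listed in both snapshots.  ``novel`` pairs are edges
    of the second snapshot only, ``spurious`` of the first only.
    """
    shared = set(net1.drugs) & set(net2.drugs)
    if not shared:
        raise NetworkValidationError("snapshots share no drugs")

    def edges_over(net: InteractionNetwork) -> set[Pair]:
        return {
            p for p in net.edge_set() if p[0] in shared and p[1] in shared
        }

    e1, e2 = edges_over(net1), edges_over(net2)
    order = sorted(shared)
    everything = {
        (a, b) for i, a in enumerate(order) for b in order[i + 1 :]
    }
    persistent = e1 & e2
    spurious = e1 - e2
    novel = e2 - e1
    never = everything - e1 - e2
    return SnapshotDiff(
        shared_drugs=frozenset(shared),
        persistent=frozenset(persistent),
        novel=frozenset(novel),
        spurious=frozenset(spurious),
        never_added=frozenset(never),
    )
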