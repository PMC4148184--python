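"""Somatic aberration state space and its Markov transition model.

Aberration states are ordered pairs ``(c1, c2)`` of parent-specific copy
numbers in the aberrant cell population: ``c1`` is the copy count of the
haplotype arbitrarily labelled 1, ``c2`` of haplotype 2.  ``(1, 1)`` is the
normal diploid state.  With total copy number capped at 5 there are 21 ordered
states; because the haplotype labelling is arbitrary, each imbalanced state
and its mirror ``(c2, c1)`` describe the same unordered event, so posteriors
are reported over 12 collapsed categories (3 balanced states plus 9
imbalanced mirror pairs).

The transition model is a "normal hub" chain: events are entered from and
exited to the normal diploid state, with the entry probability set so that a
target fraction ``f`` of the genome is aberrant at stationarity and the exit
probability set so that events last ``L`` markers on average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AberrationState",
    "StateSpace",
    "AberrationTPMSpec",
    "enumerate_states",
    "reduced_state_space",
    "build_tpm",
    "stationary_distribution",
]


@dataclass(frozen=True, order=True)
class AberrationState:
    """Parent-specific copy numbers of the two haplotypes in aberrant cells."""

    c1: int
    c2: int

    @property
    def total(self) -> int:
        return self.c1 + self.c2

    @property
    def is_balanced(self) -> bool:
        return self.c1 == self.c2

    def mirror(self) -> "AberrationState":
        return AberrationState(self.c2, self.c1)

    @property
    def label(self) -> str:
        """Ordered label, e.g. '2-0'."""
        return f"{self.c1}-{self.c2}"

    @property
    def category(self) -> str:
        """Unordered (mirror-collapsed) category label, e.g. '2-0' for (0,2)."""
        hi, lo = max(self.c1, self.c2), min(self.c1, self.c2)
        return f"{hi}-{lo}"


NORMAL = AberrationState(1, 1)


class StateSpace:
    """An ordered list of aberration states with mirror pairing and categories."""

    def __init__(self, states: list[AberrationState]):
        self.states = list(states)
        self.index = {s: i for i, s in enumerate(self.states)}
        if len(self.index) != len(self.states):
            raise ValueError("duplicate states")
        for s in self.states:
            if s.mirror() not in self.index:
                raise ValueError(f"mirror of {s.label} missing from state space")
        if NORMAL not in self.index:
            raise ValueError("state space must contain the normal state 1-1")
        self.mirror_index = np.array(
            [self.index[s.mirror()] for s in self.states], dtype=np.int64
        )
        # categories ordered by (total copies, larger haplotype copy)
        cats: list[str] = []
        for s in sorted(self.states, key=lambda s: (s.total, max(s.c1, s.c2))):
            if s.category not in cats:
                cats.append(s.category)
        self.categories = cats
        cat_pos = {c: i for i, c in enumerate(cats)}
        self.category_of_state = np.array(
            [cat_pos[s.category] for s in self.states], dtype=np.int64
        )
        self.normal_state_index = self.index[NORMAL]
        self.normal_category_index = cat_pos[NORMAL.category]

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def c_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Copy numbers of haplotype 1 and 2 as float arrays (kernel inputs)."""
        c1 = np.array([s.c1 for s in self.states], dtype=np.float64)
        c2 = np.array([s.c2 for s in self.states], dtype=np.float64)
        return c1, c2

    def collapse(self, state_probs: np.ndarray) -> np.ndarray:
        """Sum per-state probabilities (last axis) into the report categories."""
        out = np.zeros(state_probs.shape[:-1] + (self.n_categories,))
        for i, c in enumerate(self.category_of_state):
            out[..., c] += state_probs[..., i]
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "states": self.labels,
                "mirror_index": self.mirror_index.tolist(),
                "categories": self.categories,
                "category_of_state": self.category_of_state.tolist(),
            },
            indent=1,
        )


def enumerate_states(max_total: int = 5) -> StateSpace:
    """All ordered parent-specific copy-number pairs with total <= ``max_total``.

    Canonical order is by total copy number, then by ``c1``.  ``max_total=5``
    gives the full 21-state space with 12 report categories.
    """
    if max_total < 2:
        raise ValueError(
            "max_total must be >= 2 so the normal diploid state is included"
        )
    states = [
        AberrationState(c1, t - c1)
        for t in range(max_total + 1)
        for c1 in range(t + 1)
    ]
    return StateSpace(states)


def reduced_state_space() -> StateSpace:
    """Normal, hemizygous deletion and cn-LOH only (5 ordered states).

    This is the restricted state space used by the BAF-only model variant.
    """
    return StateSpace(
        [
            AberrationState(0, 1),
            AberrationState(1, 0),
            AberrationState(1, 1),
            AberrationState(0, 2),
            AberrationState(2, 0),
        ]
    )


@dataclass
class AberrationTPMSpec:
    """Prior geometry of aberrant events along the marker sequence.

    mean_event_markers
        Expected sojourn length of an aberrant event, in markers.
    aberrant_fraction
        Expected fraction of markers in an aberrant state at stationarity.
    """

    mean_event_markers: float = 600.0
    aberrant_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.mean_event_markers < 1:
            raise ValueError("mean_event_markers must be >= 1")
        if not 0.0 < self.aberrant_fraction < 1.0:
            raise ValueError("aberrant_fraction must be in (0, 1)")


def build_tpm(spec: AberrationTPMSpec, space: StateSpace) -> np.ndarray:
    """Per-marker transition matrix of the normal-hub aberration chain.

    The normal state self-transitions with probability ``1 - p_enter`` where
    ``p_enter = f / ((1 - f) L)``, splitting ``p_enter`` equally over the
    aberrant states; each aberrant state exits back to normal with probability
    ``1 / L`` and otherwise stays.  Direct aberrant-to-aberrant transitions
    are disallowed.  The construction is invariant under mirror relabelling
    and has stationary aberrant mass ``f`` and mean aberrant sojourn ``L``.
    """
    L = len(space)
    n_ab = L - 1
    f = spec.aberrant_fraction
    mean_len = spec.mean_event_markers
    p_exit = 1.0 / mean_len
    p_enter = f / ((1.0 - f) * mean_len)
    if p_enter >= 1.0:
        raise ValueError(
            f"infeasible TPM spec: implied entry probability {p_enter:.3g} >= 1"
        )
    tpm = np.zeros((L, L))
    ni = space.normal_state_index
    for i in range(L):
        if i == ni:
            tpm[i, i] = 1.0 - p_enter
            for j in range(L):
                if j != ni:
                    tpm[i, j] = p_enter / n_ab
        else:
            tpm[i, ni] = p_exit
            tpm[i, i] = 1.0 - p_exit
    return tpm


def stationary_distribution(spec: AberrationTPMSpec, space: StateSpace) -> np.ndarray:
    """Closed-form stationary distribution of :func:`build_tpm`.

    Mass ``1 - f`` on the normal state and ``f`` split equally over the
    aberrant states.
    """
    L = len(space)
    f = spec.aberrant_fraction
    pi = np.full(L, f / (L - 1))
    pi[space.normal_state_index] = 1.0 - f
    return pi
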