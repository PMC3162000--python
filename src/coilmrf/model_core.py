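"""Hidden-state space of the coiled-coil Markov random field.

The chain has one non-coil state plus, for each oligomer class (dimer,
trimer), 63 coil states indexed by heptad register letter (a-g) and by a
location label 1-9 marking position within the coil: the first seven
residues of a coil are labelled 1-7, every middle residue 8, and the last
residue 9.  The transition graph forces every coil to run 1..7, then any
number of 8s, then 9 -- so a predicted coil is always at least nine
residues long -- and forces the heptad letter to advance cyclically by one
at each step.  A brute-force path enumerator over this graph serves as the
testing oracle for the forward-backward recursions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np

HEPTADS = "abcdefg"

#: Hard cap on the sequence length accepted by :func:`enumerate_valid_paths`.
MAX_ENUMERATION_LENGTH = 14


class OligomerClass(Enum):
    """Three-way outcome: not a coiled coil, two-helix or three-helix bundle."""

    NONCOIL = "noncoil"
    DIMER = "dimer"
    TRIMER = "trimer"


@dataclass(frozen=True)
class HiddenState:
    """One MRF hidden state.

    ``heptad`` and ``location`` are ``None`` exactly when the state is the
    non-coil state; coil states carry a register letter a-g and a location
    label in 1..9.
    """

    oligomer: OligomerClass
    heptad: str | None = None
    location: int | None = None

    def __post_init__(self) -> None:
        if self.oligomer is OligomerClass.NONCOIL:
            if self.heptad is not None or self.location is not None:
                raise ValueError("non-coil state carries no heptad/location")
        else:
            if self.heptad not in HEPTADS:
                raise ValueError(f"bad heptad {self.heptad!r}")
            if self.location not in range(1, 10):
                raise ValueError(f"bad location {self.location!r}")

    @property
    def is_coil(self) -> bool:
        return self.oligomer is not OligomerClass.NONCOIL

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if not self.is_coil:
            return "State(0)"
        return f"State({self.oligomer.value[0].upper()}{self.heptad}{self.location})"


def next_heptad(h: str) -> str:
    """Cyclic successor in the heptad repeat: a->b->...->g->a."""
    return HEPTADS[(HEPTADS.index(h) + 1) % 7]


NONCOIL_STATE = HiddenState(OligomerClass.NONCOIL)


class StateSpace:
    """The 127 hidden states with their allowed-transition structure.

    State ordering is fixed (non-coil first, then dimer a1..a9, b1..b9, ...,
    g9, then trimer likewise) so that potential and posterior matrices are
    reproducible bit-for-bit.
    """

    def __init__(self) -> None:
        states: list[HiddenState] = [NONCOIL_STATE]
        for oc in (OligomerClass.DIMER, OligomerClass.TRIMER):
            for h in HEPTADS:
                for loc in range(1, 10):
                    states.append(HiddenState(oc, h, loc))
        self.states: tuple[HiddenState, ...] = tuple(states)
        self.index: dict[HiddenState, int] = {s: i for i, s in enumerate(states)}
        self.n_states = len(states)

        # Initial/final restrictions: a coil may only enter the sequence at
        # location 1 and leave it at location 9, so truncated coils at the
        # sequence edges are unrepresentable (documented limitation).
        self.initial_allowed = frozenset(
            s for s in states if not s.is_coil or s.location == 1
        )
        self.final_allowed = frozenset(
            s for s in states if not s.is_coil or s.location == 9
        )

        T = np.zeros((self.n_states, self.n_states), dtype=bool)
        for i, s in enumerate(states):
            for j, t in enumerate(states):
                T[i, j] = _transition_allowed(s, t)
        self.transition_matrix = T
        self.initial_mask = np.array([s in self.initial_allowed for s in states])
        self.final_mask = np.array([s in self.final_allowed for s in states])
        # Index groups used by posterior summaries.
        self.coil_mask = np.array([s.is_coil for s in states])
        self.dimer_mask = np.array(
            [s.oligomer is OligomerClass.DIMER for s in states]
        )
        self.trimer_mask = np.array(
            [s.oligomer is OligomerClass.TRIMER for s in states]
        )

    def states_of(self, oligomer: OligomerClass) -> list[HiddenState]:
        return [s for s in self.states if s.oligomer is oligomer]


def _transition_allowed(s: HiddenState, t: HiddenState) -> bool:
    if not s.is_coil:
        # Leaving the non-coil state: stay, or start a coil at location 1
        # in any register (coils begin at arbitrary register positions).
        return (not t.is_coil) or t.location == 1
    if not t.is_coil:
        # A coil can only end after its final residue; consecutive coils are
        # therefore separated by at least one non-coil residue.
        return s.location == 9
    if s.oligomer is not t.oligomer:
        return False
    if t.heptad != next_heptad(s.heptad):
        return False
    if 1 <= s.location <= 7:
        return t.location == s.location + 1
    if s.location == 8:
        return t.location in (8, 9)
    return False  # location 9 exits only via non-coil


def build_state_space() -> StateSpace:
    """Construct the 1 + 63 + 63 state space with its transition predicate."""
    return StateSpace()


def is_valid_transition(
    s: HiddenState, t: HiddenState, space: StateSpace | None = None
) -> bool:
    """Indicator of the pairwise MRF potential: 1 for an allowed step s->t."""
    if space is not None:
        if s not in space.index or t not in space.index:
            raise KeyError(f"state not in state space: {s!r} or {t!r}")
    return _transition_allowed(s, t)


@lru_cache(maxsize=4)
def _space() -> StateSpace:
    return build_state_space()


def enumerate_valid_paths(length: int) -> list[tuple[HiddenState, ...]]:
    """Exhaustively list every valid state path of the given length.

    A valid path starts in an initial-allowed state, ends in a final-allowed
    state and takes only allowed transitions.  Exponential in principle, the
    transition structure keeps counts small for the guarded lengths; used as
    an independent oracle for the dynamic-programming recursions.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"length {length} exceeds the enumeration guard "
            f"({MAX_ENUMERATION_LENGTH})"
        )
    space = _space()
    succ: dict[HiddenState, list[HiddenState]] = {
        s: [t for t in space.states if _transition_allowed(s, t)]
        for s in space.states
    }
    paths: list[tuple[HiddenState, ...]] = []

    def extend(path: list[HiddenState]) -> None:
        if len(path) == length:
            if path[-1] in space.final_allowed:
                paths.append(tuple(path))
            return
        # prune: a coil at location p needs 9 - min(p, 8) more steps minimum
        for t in succ[path[-1]]:
            remaining = length - len(path) - 1
            if t.is_coil:
                needed = 0 if t.location == 9 else (8 - min(t.location, 8)) + 1
                if needed > remaining:
                    continue
            extend(path + [t])

    for s in space.states:
        if s in space.initial_allowed:
            extend([s])
    return paths


def coil_run_lengths(path: tuple[HiddenState, ...]) -> list[int]:
    """Lengths of the maximal contiguous coil segments of a state path."""
    return [
        sum(1 for _ in grp)
        for is_coil, grp in itertools.groupby(path, key=lambda s: s.is_coil)
        if is_coil
    ]
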