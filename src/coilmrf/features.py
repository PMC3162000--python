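"""The eight regression features of a register-assigned segment.

For a segment of residues x with heptad assignment h the features are

* f1, f2 — summed log probability of each residue under the dimer
  (resp. trimer) per-heptad tables,
* f3 — summed log probability under the heptad-free background table,
* f4, f5, f6 — summed pairwise correlation log-odds over all in-segment
  residue pairs at distances k = 1..7:
  ``log q(x[i-k], x[i] | k, h[i]) - log P(x[i-k]|h[i-k]) - log P(x[i]|h[i])``
  under the dimer, trimer and background tables respectively (the
  background form ignores heptads),
* f7, f8 — summed Eisenberg consensus hydrophobicity of the residues at
  the core a (resp. d) heptad positions.

Each feature decomposes into per-position summands gated by the hidden
state's location label: a residue at location p in a coil has exactly
min(p-1, 7) in-coil predecessors, so correlation distance k contributes
iff k < p (all seven distances for p in {8, 9}).  Summing the per-position
contributions along a coil's forced state path therefore reproduces the
segment features exactly; the MRF singleton potentials are built from
these summands.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .frequencies import N_AA, PairTable, SingleTable, aa_index
from .model_core import HEPTADS, HiddenState, OligomerClass
from .sequence_io import RegisterError, validate_register_continuity

N_FEATURES = 8
FEATURE_NAMES = (
    "log_p_dimer",
    "log_p_trimer",
    "log_p_background",
    "corr_dimer",
    "corr_trimer",
    "corr_background",
    "hydrophobicity_a",
    "hydrophobicity_d",
)

_HEPTAD_INDEX = {h: i for i, h in enumerate(HEPTADS)}


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydrophobicity values; X scores 0."""

    values: tuple[float, ...]  # indexed by aa_index, length 21

    def __getitem__(self, residue: str) -> float:
        return self.values[aa_index(residue)]

    @classmethod
    def eisenberg_consensus(cls) -> "HydropathyScale":
        """Load the bundled Eisenberg consensus scale."""
        text = (
            resources.files("coilmrf.data")
            .joinpath("eisenberg_consensus.tsv")
            .read_text()
        )
        table: dict[str, float] = {}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            res, val = line.split("\t")
            table[res] = float(val)
        vals = [table[c] for c in "ACDEFGHIKLMNPQRSTVWY"] + [0.0]
        return cls(tuple(vals))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


def _check_tables(single: SingleTable, pairs: PairTable) -> None:
    if single.background is None or pairs.background is None:
        raise ValueError("feature computation needs background tables attached")


def per_position_contribution(
    i: int,
    state: HiddenState,
    residues: str,
    single: SingleTable,
    pairs: PairTable,
    scale: HydropathyScale,
) -> np.ndarray:
    """Position-``i`` summands of the eight features under a coil state.

    The correlation terms at distance k are included exactly when the
    state's location label guarantees that position ``i - k`` lies inside
    the same coil: ``k < location`` for locations 1..7, every k for
    locations 8 and 9.  The tables are class-agnostic — a dimer state and a
    trimer state at the same heptad/location yield the same vector; only
    the regression coefficients applied to it differ.
    """
    if not state.is_coil:
        raise ValueError("the non-coil state is the reference class and has no features")
    _check_tables(single, pairs)
    h = _HEPTAD_INDEX[state.heptad]
    xi = aa_index(residues[i])
    out = np.zeros(N_FEATURES)
    p = single.p  # (2, 7, 21)
    pbg = single.pbg
    out[0] = np.log(p[0, h, xi])
    out[1] = np.log(p[1, h, xi])
    out[2] = np.log(pbg[xi])
    max_k = 7 if state.location >= 8 else state.location - 1
    for k in range(1, max_k + 1):
        if i - k < 0:
            # Location p > k at sequence position i implies i >= k for any
            # state reachable by a valid path; unreachable states may index
            # before the sequence start, and their potentials are irrelevant.
            continue
        xu = aa_index(residues[i - k])
        hu = (h - k) % 7
        out[3] += np.log(pairs.q[0, k - 1, h, xu, xi]) - np.log(p[0, hu, xu]) - np.log(p[0, h, xi])
        out[4] += np.log(pairs.q[1, k - 1, h, xu, xi]) - np.log(p[1, hu, xu]) - np.log(p[1, h, xi])
        out[5] += np.log(pairs.qbg[k - 1, xu, xi]) - np.log(pbg[xu]) - np.log(pbg[xi])
    if state.heptad == "a":
        out[6] = scale[residues[i]]
    elif state.heptad == "d":
        out[7] = scale[residues[i]]
    return out


def compute_features(
    residues: str,
    register: str,
    single: SingleTable,
    pairs: PairTable,
    scale: HydropathyScale,
) -> np.ndarray:
    """Whole-segment feature vector (length 8) of an annotated coil.

    ``register`` assigns a heptad letter to every residue of the segment and
    must be cyclically continuous.  Correlation sums run over all residue
    pairs at distances 1..7 that lie fully inside the segment.
    """
    if len(residues) != len(register):
        raise RegisterError("register length does not match segment length")
    validate_register_continuity(register)
    _check_tables(single, pairs)
    L = len(residues)
    h = np.array([_HEPTAD_INDEX[c] for c in register])
    x = np.array([aa_index(c) for c in residues])
    p = single.p
    pbg = single.pbg
    out = np.zeros(N_FEATURES)
    out[0] = np.log(p[0, h, x]).sum()
    out[1] = np.log(p[1, h, x]).sum()
    out[2] = np.log(pbg[x]).sum()
    for k in range(1, 8):
        if L <= k:
            break
        xu, xd = x[:-k], x[k:]
        hu, hd = h[:-k], h[k:]
        out[3] += (np.log(pairs.q[0, k - 1, hd, xu, xd]) - np.log(p[0, hu, xu]) - np.log(p[0, hd, xd])).sum()
        out[4] += (np.log(pairs.q[1, k - 1, hd, xu, xd]) - np.log(p[1, hu, xu]) - np.log(p[1, hd, xd])).sum()
        out[5] += (np.log(pairs.qbg[k - 1, xu, xd]) - np.log(pbg[xu]) - np.log(pbg[xd])).sum()
    hyd = scale.as_array()[x]
    out[6] = hyd[h == _HEPTAD_INDEX["a"]].sum()
    out[7] = hyd[h == _HEPTAD_INDEX["d"]].sum()
    return out


def forced_state_path(length: int, register: str, oligomer: OligomerClass):
    """The unique hidden-state path of a coil of known length and register.

    Locations read 1..7, then 8 for every middle residue, then 9 last.
    """
    if length < 9:
        raise ValueError("a coil must span at least 9 residues")
    states = []
    for i in range(length):
        loc = 9 if i == length - 1 else min(i + 1, 8)
        states.append(HiddenState(oligomer, register[i], loc))
    return states
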