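"""Exact posterior decoding over the 127-state coiled-coil chain.

The joint model is a chain Markov random field: singleton potentials
psi1(i, state) score each residue under a hidden heptad/location state
using the fitted regression (exp of the class score contribution), and the
pairwise potential is the 0/1 allowed-transition indicator.  Forward and
backward recursions in log space yield per-residue state posteriors and
the log normalizer; an explicit sum over all valid state paths provides an
independent oracle for short sequences.

Singleton log-potentials for a coil state at position i are the dot
product of the regression coefficients (alpha for dimer states, beta for
trimer states) with the per-position feature contributions, plus the class
constant exactly when the state's location label is 1 — so a full coil
path accumulates its segment's features once and its constant once, and
the path score equals the regression score of the segment.  The non-coil
state is the reference class with log-potential 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .features import HydropathyScale, _HEPTAD_INDEX
from .frequencies import PairTable, SingleTable, aa_index
from .model_core import (
    HiddenState,
    OligomerClass,
    StateSpace,
    coil_run_lengths,
    enumerate_valid_paths,
)
from .sequence_io import PredictionRow, ProteinSequence
from .training import RegressionModel

_NEG_INF = -np.inf


@dataclass
class PotentialTable:
    """Per-position singleton log-potentials over the ordered state space."""

    log_psi1: np.ndarray  # (L, 127)
    space: StateSpace

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.log_psi1)):
            raise ValueError("singleton log-potentials must be finite")


@dataclass
class PosteriorMatrix:
    """Per-residue state posteriors gamma and the log normalizer."""

    gamma: np.ndarray  # (L, 127)
    logZ: float
    space: StateSpace


def _per_heptad_arrays(
    x: np.ndarray, single: SingleTable, pairs: PairTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-position, per-heptad feature summands.

    Returns B1, B2 of shape (L, 7) (single-residue dimer/trimer log
    probabilities), B3 of shape (L,) (background), and cumulative
    correlation sums S_d, S_t of shape (L, 7, 8) and S_bg of shape (L, 8),
    where the last axis indexes the maximum in-coil distance K = 0..7
    admitted by a state's location label.
    """
    L = len(x)
    logp = np.log(single.p)  # (2, 7, 21)
    logbg = np.log(single.pbg)  # (21,)
    B1 = logp[0][:, x].T  # (L, 7)
    B2 = logp[1][:, x].T
    B3 = logbg[x]
    S_d = np.zeros((L, 7, 8))
    S_t = np.zeros((L, 7, 8))
    S_bg = np.zeros((L, 8))
    logq = np.log(pairs.q)  # (2, 7, 7, 21, 21)
    logqbg = np.log(pairs.qbg)  # (7, 21, 21)
    hs = np.arange(7)
    for k in range(1, 8):
        S_d[:, :, k] = S_d[:, :, k - 1]
        S_t[:, :, k] = S_t[:, :, k - 1]
        S_bg[:, k] = S_bg[:, k - 1]
        if L <= k:
            continue
        xu, xd = x[:-k], x[k:]
        hu = (hs - k) % 7
        # term[h, i] for downstream position index i (absolute position i+k)
        td = logq[0, k - 1][:, xu, xd] - logp[0][hu][:, xu] - logp[0][:, xd]
        tt = logq[1, k - 1][:, xu, xd] - logp[1][hu][:, xu] - logp[1][:, xd]
        tb = logqbg[k - 1][xu, xd] - logbg[xu] - logbg[xd]
        S_d[k:, :, k] += td.T
        S_t[k:, :, k] += tt.T
        S_bg[k:, k] += tb
    return B1, B2, B3, S_d, S_t, S_bg


def build_potentials(
    sequence: ProteinSequence,
    model: RegressionModel,
    single: SingleTable,
    pairs: PairTable,
    scale: HydropathyScale,
    space: StateSpace,
) -> PotentialTable:
    """Singleton log-potentials for every position and hidden state."""
    if model.pseudocount is not None and model.pseudocount != single.pseudocount:
        raise ValueError(
            "model was trained against tables with a different pseudocount"
        )
    x = np.array([aa_index(c) for c in sequence.residues])
    L = len(x)
    B1, B2, B3, S_d, S_t, S_bg = _per_heptad_arrays(x, single, pairs)
    hyd = scale.as_array()[x]  # (L,)
    a_idx, d_idx = _HEPTAD_INDEX["a"], _HEPTAD_INDEX["d"]

    # Feature tensor F[i, h, K, :]: the 8 per-position summands under a
    # state with heptad h whose location admits correlation distances <= K.
    F = np.zeros((L, 7, 8, 8))
    F[:, :, :, 0] = B1[:, :, None]
    F[:, :, :, 1] = B2[:, :, None]
    F[:, :, :, 2] = B3[:, None, None]
    F[:, :, :, 3] = S_d
    F[:, :, :, 4] = S_t
    F[:, :, :, 5] = S_bg[:, None, :]
    F[:, a_idx, :, 6] = hyd[:, None]
    F[:, d_idx, :, 7] = hyd[:, None]

    score_d = F @ model.alpha  # (L, 7, 8)
    score_t = F @ model.beta

    log_psi1 = np.zeros((L, space.n_states))
    for idx, state in enumerate(space.states):
        if not state.is_coil:
            continue
        h = _HEPTAD_INDEX[state.heptad]
        K = 7 if state.location >= 8 else state.location - 1
        if state.oligomer is OligomerClass.DIMER:
            col = score_d[:, h, K] + (model.c_dimer if state.location == 1 else 0.0)
        else:
            col = score_t[:, h, K] + (model.c_trimer if state.location == 1 else 0.0)
        log_psi1[:, idx] = col
    return PotentialTable(log_psi1, space)


def _log_transition(space: StateSpace) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(space.transition_matrix, 0.0, _NEG_INF)


def _mask_log(mask: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(mask, 0.0, _NEG_INF)


def forward_backward(
    sequence: ProteinSequence, potentials: PotentialTable, space: StateSpace
) -> PosteriorMatrix:
    """Exact per-residue state posteriors by log-space dynamic programming.

    The forward and backward log normalizers agree to numerical precision;
    the forward value is reported.
    """
    log_psi1 = potentials.log_psi1
    L = log_psi1.shape[0]
    if L < 1:
        raise ValueError("empty sequence")
    logT = _log_transition(space)
    init = _mask_log(space.initial_mask)
    final = _mask_log(space.final_mask)

    fwd = np.full((L, space.n_states), _NEG_INF)
    fwd[0] = init + log_psi1[0]
    for i in range(1, L):
        fwd[i] = logsumexp(fwd[i - 1][:, None] + logT, axis=0) + log_psi1[i]
    logZ = float(logsumexp(fwd[L - 1] + final))

    bwd = np.full((L, space.n_states), _NEG_INF)
    bwd[L - 1] = final
    for i in range(L - 2, -1, -1):
        bwd[i] = logsumexp(logT + (log_psi1[i + 1] + bwd[i + 1])[None, :], axis=1)
    logZ_bwd = float(logsumexp(init + log_psi1[0] + bwd[0]))
    assert abs(logZ - logZ_bwd) < 1e-8 * max(1.0, abs(logZ)), "forward/backward normalizer mismatch"

    gamma = np.exp(fwd + bwd - logZ)
    return PosteriorMatrix(gamma, logZ, space)


def brute_force_posterior(
    sequence: ProteinSequence, potentials: PotentialTable, space: StateSpace
) -> PosteriorMatrix:
    """Posteriors by explicit summation over every valid state path.

    Exponential-time oracle used to validate the recursions on short
    sequences.
    """
    log_psi1 = potentials.log_psi1
    L = log_psi1.shape[0]
    paths = enumerate_valid_paths(L)
    scores = np.array(
        [sum(log_psi1[i, space.index[s]] for i, s in enumerate(p)) for p in paths]
    )
    logZ = float(logsumexp(scores))
    gamma = np.zeros((L, space.n_states))
    weights = np.exp(scores - logZ)
    for p, w in zip(paths, weights):
        for i, s in enumerate(p):
            gamma[i, space.index[s]] += w
    return PosteriorMatrix(gamma, logZ, space)


def posterior_oligomer_probs(
    posterior: PosteriorMatrix, sequence: ProteinSequence, register_threshold: float = 0.5
) -> list[PredictionRow]:
    """Collapse state posteriors to per-residue dimer/trimer probabilities.

    The oligomer probability is the posterior mass summed over the 63
    states of that class; the displayed register is the heptad of the
    highest-posterior coil state when the total coil probability exceeds
    the display threshold, '-' otherwise.
    """
    space = posterior.space
    gamma = posterior.gamma
    p_dimer = gamma[:, space.dimer_mask].sum(axis=1)
    p_trimer = gamma[:, space.trimer_mask].sum(axis=1)
    coil_idx = np.flatnonzero(space.coil_mask)
    rows: list[PredictionRow] = []
    for i, residue in enumerate(sequence.residues):
        p_coil = p_dimer[i] + p_trimer[i]
        if p_coil > register_threshold:
            best = space.states[coil_idx[np.argmax(gamma[i, coil_idx])]]
            register = best.heptad
        else:
            register = "-"
        rows.append(
            PredictionRow(i + 1, residue, register, float(p_dimer[i]), float(p_trimer[i]))
        )
    return rows


def predict_sequence(
    sequence: ProteinSequence,
    model: RegressionModel,
    single: SingleTable,
    pairs: PairTable,
    scale: HydropathyScale,
    space: StateSpace,
) -> list[PredictionRow]:
    """Convenience: potentials -> forward-backward -> per-residue rows."""
    pot = build_potentials(sequence, model, single, pairs, scale, space)
    post = forward_backward(sequence, pot, space)
    return posterior_oligomer_probs(post, sequence)
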