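"""Training-set assembly and the weighted multinomial logistic regression.

Positive examples are annotated dimer and trimer coils; negative examples
are windows cut from non-coiled-coil sequences and given a random (but
cyclically continuous) heptad register, because every feature is
register-dependent.  Class weights normalize the total weight of the dimer
and trimer classes to 1 each and of the negative class to 1000, encoding a
strong prior that most residues in real sequences are not in coiled coils.

The regression fits class scores

    s_dimer  = alpha . f + c_dimer
    s_trimer = beta  . f + c_trimer
    s_none   = 0                       (reference class)

by maximizing the weight-normalized multinomial log-likelihood (plus a tiny
ridge on the coefficients to guard against perfect separation).  Because
summing over all hidden-state paths heavily favors coil predictions — many
paths place a residue in a coil, only one places it outside — a fixed
offset (default 20) is subtracted from both constants before the model is
used to build MRF potentials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .features import N_FEATURES
from .model_core import HEPTADS, OligomerClass, next_heptad
from .sequence_io import ProteinSequence

DEFAULT_OFFSET = 20.0
DEFAULT_RIDGE = 1e-6
#: class weight totals: dimer, trimer, negative
CLASS_TOTALS = {OligomerClass.DIMER: 1.0, OligomerClass.TRIMER: 1.0, OligomerClass.NONCOIL: 1000.0}
#: negative window length is uniform on this inclusive range
WINDOW_LENGTH_RANGE = (0, 249)
#: windows too short to host a valid coil path are resampled
MIN_WINDOW_LENGTH = 9

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingExample:
    features: np.ndarray  # (8,)
    label: OligomerClass
    weight: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("example weight must be positive")


@dataclass(frozen=True)
class RegressionModel:
    """Fitted coefficients of the three-class score model.

    ``c_dimer``/``c_trimer`` are the constants as fitted minus any offset
    already applied via :func:`apply_offset`; ``offset_applied`` records the
    cumulative subtraction for provenance.
    """

    alpha: np.ndarray  # (8,) dimer-class coefficients
    beta: np.ndarray  # (8,) trimer-class coefficients
    c_dimer: float
    c_trimer: float
    offset_applied: float = 0.0
    pseudocount: float | None = None
    seed: int | None = None
    converged: bool = True
    n_iterations: int = 0
    final_objective: float = float("nan")

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Class scores (noncoil, dimer, trimer) for feature rows."""
        f = np.atleast_2d(features)
        s = np.zeros((f.shape[0], 3))
        s[:, 1] = f @ self.alpha + self.c_dimer
        s[:, 2] = f @ self.beta + self.c_trimer
        return s

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        s = self.scores(features)
        return np.exp(s - logsumexp(s, axis=1, keepdims=True))


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, gradient_norm: float):
        super().__init__(f"{msg} (gradient norm {gradient_norm:.3e})")
        self.gradient_norm = gradient_norm


def sample_negative_window(
    sequence: ProteinSequence, rng: np.random.Generator
) -> tuple[str, str]:
    """Cut a random-length prefix of a negative sequence and invent a register.

    The length L is uniform on 0..249 (the whole sequence if shorter than
    L); the register starts at a uniformly drawn heptad letter and runs
    cyclically without skips.  Draws with L < 9 cannot host a valid coil
    path and are resampled.
    """
    lo, hi = WINDOW_LENGTH_RANGE
    while True:
        L = int(rng.integers(lo, hi + 1))
        window = sequence.residues[:L]
        if len(window) >= MIN_WINDOW_LENGTH:
            break
    start = HEPTADS[int(rng.integers(0, 7))]
    register = []
    h = start
    for _ in window:
        register.append(h)
        h = next_heptad(h)
    return window, "".join(register)


def assemble_training_set(
    dimer_features: Sequence[np.ndarray],
    trimer_features: Sequence[np.ndarray],
    negative_features: Sequence[np.ndarray],
    provenance: dict[OligomerClass, Sequence[str]] | None = None,
) -> list[TrainingExample]:
    """Attach class-normalized weights: totals 1 (dimer), 1 (trimer), 1000 (negative)."""
    groups = {
        OligomerClass.DIMER: dimer_features,
        OligomerClass.TRIMER: trimer_features,
        OligomerClass.NONCOIL: negative_features,
    }
    examples: list[TrainingExample] = []
    for label, feats in groups.items():
        if len(feats) == 0:
            raise ValueError(f"no training examples for class {label.value}")
        w = CLASS_TOTALS[label] / len(feats)
        names = (provenance or {}).get(label, [""] * len(feats))
        for f, name in zip(feats, names):
            examples.append(TrainingExample(np.asarray(f, dtype=float), label, w, name))
    return examples


_LABEL_COLUMN = {OligomerClass.NONCOIL: 0, OligomerClass.DIMER: 1, OligomerClass.TRIMER: 2}


def _pack(alpha, beta, c_d, c_t) -> np.ndarray:
    return np.concatenate([alpha, beta, [c_d, c_t]])


def _unpack(theta: np.ndarray):
    return (
        theta[:N_FEATURES],
        theta[N_FEATURES : 2 * N_FEATURES],
        theta[2 * N_FEATURES],
        theta[2 * N_FEATURES + 1],
    )


def fit_multinomial(
    examples: Sequence[TrainingExample],
    tolerance: float = 1e-12,
    max_iterations: int = 2000,
    ridge: float = DEFAULT_RIDGE,
) -> RegressionModel:
    """Weighted multinomial logistic regression with the non-coil reference.

    Minimizes the weight-normalized negative log-likelihood plus
    ``ridge * ||coefficients||^2`` (constants unpenalized, so the fitted
    class probabilities still average to the weighted class frequencies).
    Normalizing by the total weight makes the optimum invariant to scaling
    all weights by a common constant.
    """
    labels = {e.label for e in examples}
    if labels != set(_LABEL_COLUMN):
        missing = set(_LABEL_COLUMN) - labels
        raise ValueError(f"missing training class(es): {sorted(m.value for m in missing)}")
    X = np.stack([e.features for e in examples])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training set")
    y = np.array([_LABEL_COLUMN[e.label] for e in examples])
    w = np.array([e.weight for e in examples])
    w = w / w.sum()
    Y = np.zeros((len(examples), 3))
    Y[np.arange(len(examples)), y] = 1.0

    def objective(theta: np.ndarray):
        alpha, beta, c_d, c_t = _unpack(theta)
        s = np.zeros((X.shape[0], 3))
        s[:, 1] = X @ alpha + c_d
        s[:, 2] = X @ beta + c_t
        lse = logsumexp(s, axis=1)
        nll = -np.sum(w * (s[np.arange(len(y)), y] - lse))
        P = np.exp(s - lse[:, None])
        R = w[:, None] * (P - Y)  # residuals, (n, 3)
        grad = np.concatenate(
            [X.T @ R[:, 1], X.T @ R[:, 2], [R[:, 1].sum(), R[:, 2].sum()]]
        )
        coef_mask = np.ones_like(theta)
        coef_mask[-2:] = 0.0
        nll += ridge * np.sum((theta * coef_mask) ** 2)
        grad += 2.0 * ridge * theta * coef_mask
        return nll, grad

    theta0 = np.zeros(2 * N_FEATURES + 2)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iterations, "ftol": tolerance, "gtol": 1e-10},
    )
    grad_norm = float(np.linalg.norm(res.jac))
    if not res.success and grad_norm > 1e-5:
        raise ConvergenceError("multinomial regression did not converge", grad_norm)
    alpha, beta, c_d, c_t = _unpack(res.x)
    return RegressionModel(
        alpha=alpha.copy(),
        beta=beta.copy(),
        c_dimer=float(c_d),
        c_trimer=float(c_t),
        converged=bool(res.success),
        n_iterations=int(res.nit),
        final_objective=float(res.fun),
    )


def apply_offset(model: RegressionModel, offset: float = DEFAULT_OFFSET) -> RegressionModel:
    """Subtract the coil-bias offset from both per-coil constants."""
    return replace(
        model,
        c_dimer=model.c_dimer - offset,
        c_trimer=model.c_trimer - offset,
        offset_applied=model.offset_applied + offset,
    )


def save_model(model: RegressionModel, sink: TextIO) -> None:
    json.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "alpha": model.alpha.tolist(),
            "beta": model.beta.tolist(),
            "c_dimer": model.c_dimer,
            "c_trimer": model.c_trimer,
            "offset_applied": model.offset_applied,
            "pseudocount": model.pseudocount,
            "seed": model.seed,
        },
        sink,
    )


def load_model(source: TextIO) -> RegressionModel:
    obj = json.load(source)
    if obj.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {obj.get('format_version')}")
    return RegressionModel(
        alpha=np.asarray(obj["alpha"], dtype=float),
        beta=np.asarray(obj["beta"], dtype=float),
        c_dimer=float(obj["c_dimer"]),
        c_trimer=float(obj["c_trimer"]),
        offset_applied=float(obj["offset_applied"]),
        pseudocount=obj.get("pseudocount"),
        seed=obj.get("seed"),
    )
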