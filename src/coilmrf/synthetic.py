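"""Synthetic register-annotated coiled-coil families and negative sequences.

The generator emulates the shape of a curated coiled-coil training corpus:
families of dimer and trimer sequences, each carrying one annotated coil
with a continuous heptad register embedded between unannotated flanks, plus
a pool of negative (non-coil) sequences.  Residues are drawn independently
from per-class, per-heptad compositions; dimer coils are Leu-heavy at the
core a/d positions and trimer coils Ile-heavy, echoing the known
beta-branched core preference of trimers — the compositions are chosen to
make the classes separable, not to model real coil statistics.  Families
within a class differ by a small Dirichlet perturbation of the class
composition.  An optional pairwise coupling plants correlations between
in-coil residues a fixed distance apart to exercise the correlation
features.

Everything is deterministic given the spec's seed, and datasets can be
written through the standard family-file/FASTA writers so synthetic data
flows through the same parsers as real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import HEPTADS, OligomerClass
from .sequence_io import CANONICAL_AA, CoilAnnotation, NpsRecord, ProteinSequence

_AA = np.array(list(CANONICAL_AA))
_N_AA = len(CANONICAL_AA)


def _composition(**shares: float) -> np.ndarray:
    """Probability vector with named residues taking fixed shares.

    The remaining mass is spread uniformly over the other residues, so
    every amino acid keeps strictly positive probability.
    """
    v = np.zeros(_N_AA)
    for res, s in shares.items():
        v[CANONICAL_AA.index(res)] = s
    rest = 1.0 - v.sum()
    if rest < 0:
        raise ValueError("shares exceed 1")
    free = v == 0
    v[free] = rest / free.sum()
    return v


def default_class_compositions() -> dict[OligomerClass, np.ndarray]:
    """Per-heptad residue compositions, shape (7, 20) per coil class."""
    polar_d = _composition(E=0.14, K=0.12, Q=0.10, A=0.10, R=0.08, S=0.06, L=0.05)
    polar_t = _composition(Q=0.14, E=0.10, T=0.10, A=0.10, K=0.08, N=0.06, S=0.06)
    dimer = np.stack(
        [
            _composition(L=0.55, I=0.08, V=0.08, N=0.05),  # a
            polar_d,  # b
            polar_d,  # c
            _composition(L=0.55, A=0.08, M=0.06, V=0.05),  # d
            polar_d,  # e
            polar_d,  # f
            polar_d,  # g
        ]
    )
    trimer = np.stack(
        [
            _composition(I=0.55, V=0.10, L=0.08),  # a
            polar_t,  # b
            polar_t,  # c
            _composition(I=0.40, L=0.15, T=0.10, V=0.08),  # d
            polar_t,  # e
            polar_t,  # f
            polar_t,  # g
        ]
    )
    return {OligomerClass.DIMER: dimer, OligomerClass.TRIMER: trimer}


def uniform_background() -> np.ndarray:
    return np.full(_N_AA, 1.0 / _N_AA)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_families_per_class: int = 6
    sequences_per_family: int = 8
    coil_length_range: tuple[int, int] = (30, 90)  # inclusive
    flank_length_range: tuple[int, int] = (10, 40)
    negative_length_range: tuple[int, int] = (60, 200)
    n_negatives: int = 100
    class_compositions: dict[OligomerClass, np.ndarray] = field(
        default_factory=default_class_compositions
    )
    background_composition: np.ndarray = field(default_factory=uniform_background)
    family_jitter: float = 300.0  # Dirichlet concentration; np.inf = no jitter
    coupling_distance: int | None = None
    coupling_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coil_length_range", "flank_length_range", "negative_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"empty {name}")
        if self.coil_length_range[0] < 9:
            raise ValueError("coils must be at least 9 residues long")
        for comp in self.class_compositions.values():
            if comp.shape != (7, _N_AA) or np.any(comp <= 0):
                raise ValueError("compositions must be positive (7, 20) stochastic rows")
            if not np.allclose(comp.sum(axis=1), 1.0):
                raise ValueError("composition rows must sum to 1")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")


def plant_correlations(spec: SyntheticSpec, k: int, strength: float) -> SyntheticSpec:
    """Couple in-coil residue pairs at distance ``k``.

    With probability ``strength`` a coil residue copies the residue ``k``
    positions upstream (when that position is inside the coil) instead of
    being drawn from the composition; strength 0 recovers independence and
    the mutual information of the planted joint grows with strength.
    """
    if not 1 <= k <= 7:
        raise ValueError("coupling distance must lie in 1..7")
    return replace(spec, coupling_distance=k, coupling_strength=strength)


def _draw_from_rows(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a stochastic matrix (vectorized)."""
    u = rng.random(rows.shape[0])
    return (rows.cumsum(axis=1) > u[:, None]).argmax(axis=1)


def _sample_coil(
    length: int,
    start_heptad: int,
    comp: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[str, str]:
    heptads = (start_heptad + np.arange(length)) % 7
    x = _draw_from_rows(comp[heptads], rng)
    if spec.coupling_distance is not None and spec.coupling_strength > 0:
        k = spec.coupling_distance
        copy = rng.random(length) < spec.coupling_strength
        for i in range(k, length):  # left-to-right so chained copies resolve
            if copy[i]:
                x[i] = x[i - k]
    register = "".join(HEPTADS[h] for h in heptads)
    return "".join(_AA[x]), register


def _sample_background(length: int, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    x = rng.choice(_N_AA, size=length, p=spec.background_composition)
    return "".join(_AA[x])


def _family_composition(
    base: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    if not np.isfinite(spec.family_jitter):
        return base
    return np.stack([rng.dirichlet(row * spec.family_jitter) for row in base])


_DESCRIPTORS = {
    OligomerClass.DIMER: frozenset({"long", "parallel", "homo", "dimer"}),
    OligomerClass.TRIMER: frozenset({"long", "parallel", "homo", "trimer"}),
}


def sample_dataset(
    spec: SyntheticSpec,
) -> tuple[dict[str, list[NpsRecord]], list[ProteinSequence]]:
    """Draw families of annotated records plus negative sequences.

    Deterministic given ``spec.seed``: the same spec yields a byte-identical
    dataset when written out.
    """
    rng = np.random.default_rng(spec.seed)
    families: dict[str, list[NpsRecord]] = {}
    for oligomer in (OligomerClass.DIMER, OligomerClass.TRIMER):
        base = spec.class_compositions[oligomer]
        for fi in range(spec.n_families_per_class):
            fam_name = f"{oligomer.value}_fam{fi}"
            comp = _family_composition(base, spec, rng)
            records = []
            for si in range(spec.sequences_per_family):
                coil_len = int(rng.integers(spec.coil_length_range[0], spec.coil_length_range[1] + 1))
                left = int(rng.integers(spec.flank_length_range[0], spec.flank_length_range[1] + 1))
                right = int(rng.integers(spec.flank_length_range[0], spec.flank_length_range[1] + 1))
                start_h = int(rng.integers(0, 7))
                coil, register = _sample_coil(coil_len, start_h, comp, spec, rng)
                seq = (
                    _sample_background(left, spec, rng)
                    + coil
                    + _sample_background(right, spec, rng)
                )
                records.append(
                    NpsRecord(
                        name=f"{fam_name}_seq{si}",
                        descriptors=_DESCRIPTORS[oligomer],
                        sequence=ProteinSequence(f"{fam_name}_seq{si}", seq),
                        annotations=[CoilAnnotation(left, left + coil_len, register)],
                        oligomer=oligomer,
                        family=fam_name,
                    )
                )
            families[fam_name] = records
    negatives = []
    for ni in range(spec.n_negatives):
        length = int(rng.integers(spec.negative_length_range[0], spec.negative_length_range[1] + 1))
        negatives.append(ProteinSequence(f"neg{ni}", _sample_background(length, spec, rng)))
    return families, negatives
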