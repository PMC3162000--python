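"""Residue frequency tables estimated from annotated coils and negatives.

Three kinds of table feed the sequence features:

* per-class (dimer/trimer) per-heptad single-residue probabilities,
* per-class joint probabilities of residue pairs at sequence distances
  1..7 inside a coil, indexed by the heptad of the downstream residue
  (the upstream heptad is implied by the distance modulo 7),
* heptad-free background single and pair probabilities tallied from
  non-coiled-coil sequences.

All tables carry their raw counts alongside additively smoothed
probabilities, so tallies merge exactly before smoothing.  The single
``pseudocount`` knob fixes the total smoothing mass per distribution:
single-residue columns receive ``pseudocount`` per cell (20 per column),
and each 20x20 pair slice receives the same total mass, i.e.
``pseudocount / 20`` per pair cell.  Spreading a full pseudocount over
every pair cell would put 400 pseudo-observations against the few hundred
real pair counts a desk-scale corpus provides, swamping the joint
distributions and biasing the correlation log-odds.  The residue X
(unknown / non-standard) is never counted; on lookup it receives the
average probability of its table slice, realized here as an extra row and
column of axis means on the extended arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

from .model_core import HEPTADS, OligomerClass
from .sequence_io import CANONICAL_AA, NpsRecord, ProteinSequence

TABLE_FORMAT_VERSION = 1

N_AA = len(CANONICAL_AA)  # 20
N_DISTANCES = 7
_AA_INDEX = {c: i for i, c in enumerate(CANONICAL_AA)}
_CLASS_INDEX = {OligomerClass.DIMER: 0, OligomerClass.TRIMER: 1}
_HEPTAD_INDEX = {h: i for i, h in enumerate(HEPTADS)}


def aa_index(residue: str) -> int:
    """0..19 for the canonical alphabet, 20 for X."""
    return _AA_INDEX.get(residue, N_AA)


def _smooth(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Additive smoothing and normalization along the last axis.

    A slice with no observations and pseudocount 0 carries no information
    and falls back to the uniform distribution.
    """
    c = counts + pseudocount
    tot = c.sum(axis=-1, keepdims=True)
    empty = tot == 0
    if np.any(empty):
        c = np.where(empty, 1.0, c)
        tot = np.where(empty, c.shape[-1], tot)
    return c / tot


def _smooth_pair(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Smooth a trailing 20x20 joint with total mass matched to a single column."""
    q = counts + pseudocount / N_AA
    tot = q.sum(axis=(-2, -1), keepdims=True)
    empty = tot == 0
    if np.any(empty):
        q = np.where(empty, 1.0, q)
        tot = np.where(empty, q.shape[-1] * q.shape[-2], tot)
    return q / tot

def _extend_single(p: np.ndarray) -> np.ndarray:
    """Append an X entry holding the mean of the 20 canonical entries."""
    return np.concatenate([p, p.mean(axis=-1, keepdims=True)], axis=-1)


def _extend_pair(q: np.ndarray) -> np.ndarray:
    """Append X row/column of axis means to the trailing 20x20 block."""
    q = np.concatenate([q, q.mean(axis=-2, keepdims=True)], axis=-2)
    return np.concatenate([q, q.mean(axis=-1, keepdims=True)], axis=-1)


@dataclass
class BackgroundTables:
    """Heptad-free residue statistics from negative (non-coil) sequences."""

    single_counts: np.ndarray  # (20,)
    pair_counts: np.ndarray  # (7, 20, 20), axis 0 is distance k-1
    pseudocount: float
    pbg: np.ndarray = field(init=False)  # (21,)
    qbg: np.ndarray = field(init=False)  # (7, 21, 21)

    def __post_init__(self) -> None:
        self.pbg = _extend_single(_smooth(self.single_counts, self.pseudocount))
        self.qbg = _extend_pair(_smooth_pair(self.pair_counts, self.pseudocount))


@dataclass
class SingleTable:
    """P(residue | heptad, class) plus the background distribution."""

    counts: np.ndarray  # (2, 7, 20): class, heptad, residue
    pseudocount: float
    background: BackgroundTables | None = None
    p: np.ndarray = field(init=False)  # (2, 7, 21)

    def __post_init__(self) -> None:
        self.p = _extend_single(_smooth(self.counts, self.pseudocount))

    @property
    def pbg(self) -> np.ndarray:
        if self.background is None:
            raise ValueError("no background tables attached")
        return self.background.pbg

    def prob(self, oligomer: OligomerClass, heptad: str, residue: str) -> float:
        return float(self.p[_CLASS_INDEX[oligomer], _HEPTAD_INDEX[heptad], aa_index(residue)])


@dataclass
class PairTable:
    """Joint pair probabilities at distances 1..7 inside annotated coils.

    ``counts[c, k-1, h, i, j]`` counts residue i at position p-k and residue
    j at position p, where h is the heptad of the downstream position p.
    Each (class, distance, heptad) slice normalizes to a 20x20 joint.
    """

    counts: np.ndarray  # (2, 7, 7, 20, 20)
    pseudocount: float
    background: BackgroundTables | None = None
    q: np.ndarray = field(init=False)  # (2, 7, 7, 21, 21)

    def __post_init__(self) -> None:
        self.q = _extend_pair(_smooth_pair(self.counts, self.pseudocount))

    @property
    def qbg(self) -> np.ndarray:
        if self.background is None:
            raise ValueError("no background tables attached")
        return self.background.qbg


def _annotation_arrays(rec: NpsRecord):
    """Yield (residue index array, heptad index array) per annotation."""
    seq = rec.sequence.residues
    for ann in rec.annotations:
        x = np.fromiter(
            (aa_index(c) for c in seq[ann.start : ann.end]), dtype=np.intp, count=len(ann)
        )
        h = np.fromiter(
            (_HEPTAD_INDEX[c] for c in ann.register), dtype=np.intp, count=len(ann)
        )
        yield x, h


def _training_class(rec: NpsRecord) -> int | None:
    if isinstance(rec.oligomer, OligomerClass) and rec.oligomer in _CLASS_INDEX:
        return _CLASS_INDEX[rec.oligomer]
    return None  # tetramer-tagged or unlabeled records are skipped


def tally_single(
    records: Iterable[NpsRecord],
    pseudocount: float = 1.0,
    negatives: list[ProteinSequence] | None = None,
    require_all_classes: bool = True,
) -> SingleTable:
    """Accumulate per-heptad residue counts over annotated coil residues.

    If ``negatives`` is given, background tables are tallied from them and
    attached; otherwise the caller attaches a shared
    :class:`BackgroundTables` later.  With ``require_all_classes=False`` a
    class without any annotated residues is tolerated and its columns fall
    back to the smoothing prior (the cross-validation harness needs this
    when a nested table set happens to hold families of one class only).
    """
    counts = np.zeros((2, N_DISTANCES, N_AA))
    for rec in records:
        c = _training_class(rec)
        if c is None:
            continue
        for x, h in _annotation_arrays(rec):
            ok = x < N_AA
            np.add.at(counts[c], (h[ok], x[ok]), 1)
    if require_all_classes:
        for c, name in ((0, "dimer"), (1, "trimer")):
            if counts[c].sum() == 0:
                raise ValueError(f"no annotated {name} residues to tally")
    background = tally_background(negatives, pseudocount) if negatives else None
    return SingleTable(counts, pseudocount, background)


def tally_pairs(
    records: Iterable[NpsRecord],
    pseudocount: float = 1.0,
    negatives: list[ProteinSequence] | None = None,
    require_all_classes: bool = True,
) -> PairTable:
    """Accumulate in-coil residue-pair counts at distances 1..7.

    A pair (p-k, p) contributes only when both positions fall inside the
    same annotation, so pairs never straddle disjoint coils.
    """
    counts = np.zeros((2, N_DISTANCES, N_DISTANCES, N_AA, N_AA))
    for rec in records:
        c = _training_class(rec)
        if c is None:
            continue
        for x, h in _annotation_arrays(rec):
            for k in range(1, N_DISTANCES + 1):
                if len(x) <= k:
                    break
                xu, xd, hd = x[:-k], x[k:], h[k:]
                good = (xu < N_AA) & (xd < N_AA)
                np.add.at(counts[c, k - 1], (hd[good], xu[good], xd[good]), 1)
    if require_all_classes:
        for c, name in ((0, "dimer"), (1, "trimer")):
            if counts[c].sum() == 0:
                raise ValueError(f"no annotated {name} residue pairs to tally")
    background = tally_background(negatives, pseudocount) if negatives else None
    return PairTable(counts, pseudocount, background)


def tally_background(
    negatives: Iterable[ProteinSequence] | None, pseudocount: float = 1.0
) -> BackgroundTables:
    """Heptad-free single and distance-1..7 pair counts over negatives."""
    if not negatives:
        raise ValueError("no negative sequences to tally")
    single = np.zeros(N_AA)
    pair = np.zeros((N_DISTANCES, N_AA, N_AA))
    for seq in negatives:
        idx = np.array([aa_index(c) for c in seq.residues])
        ok = idx < N_AA
        np.add.at(single, idx[ok], 1)
        for k in range(1, N_DISTANCES + 1):
            if len(idx) <= k:
                continue
            i, j = idx[:-k], idx[k:]
            good = (i < N_AA) & (j < N_AA)
            np.add.at(pair, (k - 1, i[good], j[good]), 1)
    return BackgroundTables(single, pair, pseudocount)


def merge_single(a: SingleTable, b: SingleTable) -> SingleTable:
    """Add raw counts (pre-smoothing additivity of tallies)."""
    if a.pseudocount != b.pseudocount:
        raise ValueError("pseudocount mismatch")
    return SingleTable(a.counts + b.counts, a.pseudocount, a.background)


def merge_pairs(a: PairTable, b: PairTable) -> PairTable:
    if a.pseudocount != b.pseudocount:
        raise ValueError("pseudocount mismatch")
    return PairTable(a.counts + b.counts, a.pseudocount, a.background)


# -- serialization -----------------------------------------------------------

def save_tables(single: SingleTable, pairs: PairTable, sink: TextIO) -> None:
    bg = single.background
    if bg is None or pairs.background is not bg:
        raise ValueError("tables must share one attached background")
    json.dump(
        {
            "format_version": TABLE_FORMAT_VERSION,
            "pseudocount": single.pseudocount,
            "alphabet": CANONICAL_AA,
            "single_counts": single.counts.tolist(),
            "pair_counts": pairs.counts.tolist(),
            "background_single_counts": bg.single_counts.tolist(),
            "background_pair_counts": bg.pair_counts.tolist(),
        },
        sink,
    )


def load_tables(source: TextIO) -> tuple[SingleTable, PairTable]:
    obj = json.load(source)
    if obj.get("format_version") != TABLE_FORMAT_VERSION:
        raise ValueError(f"unsupported table format version {obj.get('format_version')}")
    pc = obj["pseudocount"]
    bg = BackgroundTables(
        np.asarray(obj["background_single_counts"], dtype=float),
        np.asarray(obj["background_pair_counts"], dtype=float),
        pc,
    )
    single = SingleTable(np.asarray(obj["single_counts"], dtype=float), pc, bg)
    pairs = PairTable(np.asarray(obj["pair_counts"], dtype=float), pc, bg)
    return single, pairs
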