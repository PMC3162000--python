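"""Sequence-level classification, detection tests and leave-family-out CV.

Dimer-vs-trimer classification of a known coil region reduces the
per-residue posteriors to a single statistic: each coil residue's dimer
ratio p_dimer / (p_dimer + p_trimer) is summed into a dimer score, the
complementary trimer ratios into a trimer score, and the ratio of the two
scores is compared against a threshold (default 1).

Coiled-coil detection uses the total coil probability per residue.  The
sequence-level test is deliberately strict: a positive sequence counts as
detected only if every residue of its annotated coil exceeds the cutoff,
and a negative counts as a false positive if any 28-residue window lies
entirely above the cutoff.

The cross-validation harness holds out one protein family at a time and is
nested to avoid optimistic bias: within a fold, the regression features of
each training family are computed from frequency tables tallied over the
*other* training families (the n-2 sets), while the tables used to score
the held-out family are tallied over all n-1 training families.  Families
with four or fewer sequences are pooled into a single miscellaneous family
before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import HydropathyScale, compute_features
from .frequencies import PairTable, SingleTable, tally_background, tally_pairs, tally_single
from .inference import predict_sequence
from .model_core import OligomerClass, StateSpace, build_state_space
from .sequence_io import NpsRecord, PredictionRow, ProteinSequence
from .training import (
    RegressionModel,
    apply_offset,
    assemble_training_set,
    fit_multinomial,
    sample_negative_window,
)

MISCELLANEOUS_FAMILY = "miscellaneous"


class UndefinedStatisticError(ValueError):
    """The scored interval carries no coil posterior mass."""


@dataclass(frozen=True)
class SequenceScore:
    dimer_score: float
    trimer_score: float

    @property
    def statistic(self) -> float:
        if self.trimer_score == 0.0:
            return float("inf")
        return self.dimer_score / self.trimer_score


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float


def dimer_trimer_statistic(
    rows: list[PredictionRow], coil_interval: tuple[int, int]
) -> SequenceScore:
    """Sum per-residue dimer ratios over a known coil region.

    ``coil_interval`` is 0-based half-open over the sequence.  Residues
    with zero coil posterior carry no oligomer information and are
    skipped; an interval with no scorable residue raises
    :class:`UndefinedStatisticError`.
    """
    start, end = coil_interval
    if not 0 <= start < end <= len(rows):
        raise ValueError("coil interval outside the sequence")
    dimer = trimer = 0.0
    scored = 0
    for row in rows[start:end]:
        p_coil = row.p_dimer + row.p_trimer
        if p_coil == 0.0:
            continue
        r = row.p_dimer / p_coil
        dimer += r
        trimer += 1.0 - r
        scored += 1
    if scored == 0:
        raise UndefinedStatisticError("no residue in the interval has coil posterior > 0")
    return SequenceScore(dimer, trimer)


def classify_sequence(score: SequenceScore, threshold: float = 1.0) -> OligomerClass:
    """Dimer if the score ratio exceeds the threshold, trimer below; ties -> dimer."""
    if score.statistic >= threshold:
        return OligomerClass.DIMER
    return OligomerClass.TRIMER


def detect_residues(rows: list[PredictionRow], cutoff: float = 0.5) -> np.ndarray:
    """Boolean coil call per residue: total coil probability strictly above cutoff."""
    return np.array([row.p_coil > cutoff for row in rows])


def detect_sequence(
    rows: list[PredictionRow],
    cutoff: float = 0.5,
    annotation: tuple[int, int] | None = None,
    window: int = 28,
) -> bool:
    """Strict sequence-level verdict.

    With an annotated interval (positive test): True iff every residue of
    the interval exceeds the cutoff.  Without (negative test): True (a true
    negative) iff no ``window``-residue stretch lies entirely above the
    cutoff; sequences shorter than the window are trivially true negatives.
    """
    calls = detect_residues(rows, cutoff)
    if annotation is not None:
        start, end = annotation
        return bool(calls[start:end].all())
    if len(calls) < window:
        return True
    run = np.convolve(calls.astype(int), np.ones(window, dtype=int), mode="valid")
    return not bool((run == window).any())


def roc_curve(
    positive_scores: np.ndarray, negative_scores: np.ndarray
) -> list[RocPoint]:
    """Threshold sweep over the pooled unique scores plus the infinities.

    A score counts as a positive call when it is strictly greater than the
    threshold, so threshold -inf gives (tpr, fpr) = (1, 1) and +inf (0, 0).
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    thresholds = np.concatenate(
        [[-np.inf], np.unique(np.concatenate([pos, neg])), [np.inf]]
    )
    points = [
        RocPoint(float(t), float(np.mean(pos > t)), float(np.mean(neg > t)))
        for t in thresholds
    ]
    return points


def roc_auc(positive_scores: np.ndarray, negative_scores: np.ndarray) -> float:
    """Area under the ROC curve (trapezoid over the sweep of `roc_curve`)."""
    pts = roc_curve(positive_scores, negative_scores)
    fpr = np.array([p.fpr for p in pts])[::-1]
    tpr = np.array([p.tpr for p in pts])[::-1]
    return float(np.trapezoid(tpr, fpr))


def group_small_families(
    families: dict[str, list[NpsRecord]], min_size: int = 5
) -> dict[str, list[NpsRecord]]:
    """Pool families with fewer than ``min_size`` sequences into one bucket."""
    grouped: dict[str, list[NpsRecord]] = {}
    misc: list[NpsRecord] = []
    for name, records in families.items():
        if len(records) < min_size:
            misc.extend(records)
        else:
            grouped[name] = list(records)
    if misc:
        grouped[MISCELLANEOUS_FAMILY] = grouped.get(MISCELLANEOUS_FAMILY, []) + misc
    return grouped


@dataclass
class CvConfig:
    pseudocount: float = 1.0
    offset: float = 20.0
    ridge: float = 1e-6
    classification_threshold: float = 1.0
    detection_cutoff: float = 0.5
    seed: int = 0


@dataclass
class FoldResult:
    """Held-out predictions and provenance for one cross-validation fold."""

    held_out_family: str
    sequence_calls: list[tuple[str, OligomerClass, OligomerClass, float]]
    residues_correct: int
    residues_incorrect: int
    coil_p_coil: np.ndarray  # per annotated coil residue of the held-out family
    model: RegressionModel
    table_record_ids: frozenset[str]  # inference-table provenance
    regression_record_ids: frozenset[str]  # positive-example provenance
    feature_table_ids: dict[str, frozenset[str]]  # per training family: n-2 set

    @property
    def sequences_correct(self) -> int:
        return sum(1 for _, truth, call, _ in self.sequence_calls if truth is call)

    @property
    def sequences_incorrect(self) -> int:
        return len(self.sequence_calls) - self.sequences_correct


@dataclass
class CvResult:
    folds: list[FoldResult]
    family_labels: dict[str, OligomerClass]
    negative_p_coil: np.ndarray = field(default_factory=lambda: np.array([]))
    final_model: RegressionModel | None = None

    @property
    def sequence_accuracy(self) -> float:
        correct = sum(f.sequences_correct for f in self.folds)
        total = sum(len(f.sequence_calls) for f in self.folds)
        return correct / total

    @property
    def positive_p_coil(self) -> np.ndarray:
        return np.concatenate([f.coil_p_coil for f in self.folds])

    def detection_auc(self) -> float:
        return roc_auc(self.positive_p_coil, self.negative_p_coil)

    def confusion_table(self) -> pd.DataFrame:
        """Per-family correct/incorrect counts at sequence and residue level."""
        rows = []
        for f in self.folds:
            rows.append(
                {
                    "family": f.held_out_family,
                    "class": self.family_labels[f.held_out_family].value,
                    "seqs_correct": f.sequences_correct,
                    "seqs_incorrect": f.sequences_incorrect,
                    "residues_correct": f.residues_correct,
                    "residues_incorrect": f.residues_incorrect,
                }
            )
        df = pd.DataFrame(rows).set_index("family")
        total = df.drop(columns="class").sum()
        total["class"] = "all"
        df.loc["Total"] = total
        return df


def _majority_label(records: list[NpsRecord]) -> OligomerClass:
    counts: dict[OligomerClass, int] = {}
    for r in records:
        if isinstance(r.oligomer, OligomerClass):
            counts[r.oligomer] = counts.get(r.oligomer, 0) + 1
    return max(counts, key=counts.get)


def _record_features(
    rec: NpsRecord, single: SingleTable, pairs: PairTable, scale: HydropathyScale
) -> np.ndarray:
    """Feature vector of a record: summed over its annotated coils."""
    total = np.zeros(8)
    for ann in rec.annotations:
        total += compute_features(
            rec.sequence.residues[ann.start : ann.end], ann.register, single, pairs, scale
        )
    return total


def _tally(
    records: list[NpsRecord],
    negatives: list[ProteinSequence],
    pseudocount: float,
    require_all_classes: bool = True,
) -> tuple[SingleTable, PairTable]:
    bg = tally_background(negatives, pseudocount)
    single = tally_single(records, pseudocount, require_all_classes=require_all_classes)
    pairs = tally_pairs(records, pseudocount, require_all_classes=require_all_classes)
    single.background = bg
    pairs.background = bg
    return single, pairs


def _fit_fold_model(
    training: dict[str, list[NpsRecord]],
    negatives: list[ProteinSequence],
    config: CvConfig,
    scale: HydropathyScale,
    rng: np.random.Generator,
) -> tuple[RegressionModel, dict[str, frozenset[str]], frozenset[str]]:
    """Nested regression: each family's features come from the other families."""
    dimer_feats: list[np.ndarray] = []
    trimer_feats: list[np.ndarray] = []
    pos_ids: set[str] = set()
    feature_table_ids: dict[str, frozenset[str]] = {}
    names = sorted(training)
    for fam in names:
        others = [r for g in names if g != fam for r in training[g]]
        feature_table_ids[fam] = frozenset(r.name for r in others)
        single_f, pairs_f = _tally(
            others, negatives, config.pseudocount, require_all_classes=False
        )
        for rec in training[fam]:
            f = _record_features(rec, single_f, pairs_f, scale)
            if rec.oligomer is OligomerClass.DIMER:
                dimer_feats.append(f)
            elif rec.oligomer is OligomerClass.TRIMER:
                trimer_feats.append(f)
            pos_ids.add(rec.name)
    all_training = [r for g in names for r in training[g]]
    single_all, pairs_all = _tally(
        all_training, negatives, config.pseudocount, require_all_classes=False
    )
    neg_feats = []
    for seq in negatives:
        window, register = sample_negative_window(seq, rng)
        neg_feats.append(compute_features(window, register, single_all, pairs_all, scale))
    examples = assemble_training_set(dimer_feats, trimer_feats, neg_feats)
    model = apply_offset(fit_multinomial(examples, ridge=config.ridge), config.offset)
    return model, feature_table_ids, frozenset(pos_ids)


def leave_family_out(
    families: dict[str, list[NpsRecord]],
    negatives: list[ProteinSequence],
    config: CvConfig | None = None,
    *,
    score_negatives: bool = True,
) -> CvResult:
    """Nested leave-family-out cross-validation.

    For each held-out family the remaining n-1 families are the training
    set; regression features of each training family are computed from
    tables over the other n-2, and the held-out family is scored with
    tables over all n-1.  Negative sequences contribute the background
    tables and the register-randomized negative training windows; with
    ``score_negatives`` they are additionally scored under a model trained
    on all families (for detection specificity).
    """
    config = config or CvConfig()
    if len(families) < 3:
        raise ValueError("nested cross-validation needs at least 3 families")
    scale = HydropathyScale.eisenberg_consensus()
    space = build_state_space()
    family_labels = {name: _majority_label(recs) for name, recs in families.items()}
    folds: list[FoldResult] = []
    for fold_i, held in enumerate(sorted(families)):
        training = {g: families[g] for g in families if g != held}
        rng = np.random.default_rng([config.seed, fold_i])
        model, feat_ids, pos_ids = _fit_fold_model(training, negatives, config, scale, rng)
        train_records = [r for recs in training.values() for r in recs]
        single, pairs = _tally(
            train_records, negatives, config.pseudocount, require_all_classes=False
        )
        calls = []
        res_correct = res_incorrect = 0
        coil_pcoils: list[float] = []
        for rec in families[held]:
            rows = predict_sequence(rec.sequence, model, single, pairs, scale, space)
            lo = min(a.start for a in rec.annotations)
            hi = max(a.end for a in rec.annotations)
            score = dimer_trimer_statistic(rows, (lo, hi))
            call = classify_sequence(score, config.classification_threshold)
            calls.append((rec.name, rec.oligomer, call, score.statistic))
            for ann in rec.annotations:
                for row in rows[ann.start : ann.end]:
                    coil_pcoils.append(row.p_coil)
                    res_call = (
                        OligomerClass.DIMER
                        if row.p_dimer >= row.p_trimer
                        else OligomerClass.TRIMER
                    )
                    if res_call is rec.oligomer:
                        res_correct += 1
                    else:
                        res_incorrect += 1
        folds.append(
            FoldResult(
                held_out_family=held,
                sequence_calls=calls,
                residues_correct=res_correct,
                residues_incorrect=res_incorrect,
                coil_p_coil=np.array(coil_pcoils),
                model=model,
                table_record_ids=frozenset(r.name for r in train_records),
                regression_record_ids=pos_ids,
                feature_table_ids=feat_ids,
            )
        )
    result = CvResult(folds, family_labels)
    if score_negatives:
        rng = np.random.default_rng([config.seed, len(families)])
        final_model, _, _ = _fit_fold_model(families, negatives, config, scale, rng)
        all_records = [r for recs in families.values() for r in recs]
        single, pairs = _tally(all_records, negatives, config.pseudocount)
        neg_pcoil: list[float] = []
        for seq in negatives:
            rows = predict_sequence(seq, final_model, single, pairs, scale, space)
            neg_pcoil.extend(row.p_coil for row in rows)
        result.negative_p_coil = np.array(neg_pcoil)
        result.final_model = final_model
    return result
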