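"""Scoring slide predictions against ground truth.

Covers the multiclass ROC (macro-averaged one-vs-rest AUC, an approximation
of the mROC construction), accuracy/coverage sweeps over confidence cutoffs,
and the three-way error taxonomy: Type A (normal tissue called a lesion),
Type B (misclassification between trained types), Type C (a never-trained
class called a trained one). Slides whose verdict is a differential,
undefined or insufficient-tile status are EXCLUDED from accuracy — the
workflow deliberately abstains on them.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._types import DecisionStatus, SlideTruth

__all__ = ["mroc_auc", "accuracy_sweep", "type_errors", "evaluation_report"]

#: Predictions that count as abstentions rather than class calls.
ABSTAIN = {
    DecisionStatus.DIFFERENTIAL.value,
    DecisionStatus.UNDEFINED.value,
    DecisionStatus.INSUFFICIENT_LESIONAL.value,
}


def mroc_auc(
    scores: pd.DataFrame, truths: Sequence[str], per_class: bool = False
) -> float | dict[str, float]:
    """Macro-averaged one-vs-rest AUC over per-slide class-score vectors.

    ``scores`` has one row per slide and one column per class; class c's
    column is the discriminant for the c-vs-rest curve. Classes absent from
    the truth labels (or present in every slide) are skipped; score ties use
    the midrank convention.
    """
    truths = np.asarray(list(truths))
    if len(truths) != len(scores):
        raise ValueError("scores and truths disagree in length")
    present = sorted(set(truths.tolist()))
    if len(present) < 2:
        raise ValueError("need at least two distinct truth classes to build an mROC")
    aucs: dict[str, float] = {}
    for cls in scores.columns:
        y = (truths == cls).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            continue
        aucs[str(cls)] = float(roc_auc_score(y, scores[cls].to_numpy(dtype=float)))
    if per_class:
        return aucs
    return float(np.mean(list(aucs.values())))


def accuracy_sweep(
    rows: pd.DataFrame, cutoffs: Sequence[float]
) -> pd.DataFrame:
    """Accuracy / error / coverage at each confidence cutoff.

    ``rows`` needs columns ``prediction`` (class label, or an abstention
    status), ``score`` (the mode's confidence: top mean probability, or the
    fraction of tiles in defined space for the map-based mode) and
    ``truth``. At each cutoff, slides abstaining or scoring below the cutoff
    are EXCLUDED; accuracy is correct/classified (absent when nothing is
    classified) and coverage classified/total.
    """
    if len(list(cutoffs)) == 0:
        raise ValueError("cutoff grid is empty")
    for col in ("prediction", "score", "truth"):
        if col not in rows.columns:
            raise ValueError(f"rows is missing column {col!r}")
    total = len(rows)
    out = []
    classifiable = ~rows["prediction"].isin(ABSTAIN)
    correct = classifiable & (rows["prediction"] == rows["truth"])
    for cutoff in cutoffs:
        passed = classifiable & (rows["score"].to_numpy(dtype=float) >= cutoff)
        n_classified = int(passed.sum())
        n_correct = int((passed & correct).sum())
        acc = n_correct / n_classified if n_classified else np.nan
        out.append(
            {
                "cutoff": float(cutoff),
                "accuracy": acc,
                "error": 1.0 - acc if n_classified else np.nan,
                "coverage": n_classified / total if total else np.nan,
            }
        )
    return pd.DataFrame(out)


def type_errors(
    prediction: str, truth: SlideTruth, lesion_classes: Sequence[str]
) -> str:
    """Label one slide's outcome under the A/B/C error taxonomy.

    CORRECT: prediction matches the truth class. EXCLUDED: the workflow
    abstained (differential / undefined / insufficient tiles). TYPE_A: a
    non-lesional truth called a lesion class. TYPE_B: misclassification
    between trained classes (canonically a trained tumor called a different
    tumor type). TYPE_C: a class never seen in training called any trained
    class.
    """
    if prediction in ABSTAIN:
        return "EXCLUDED"
    lesions = set(lesion_classes)
    if not truth.is_trained_class:
        return "TYPE_C"
    if prediction == truth.truth_class:
        return "CORRECT"
    if not truth.is_lesional and prediction in lesions:
        return "TYPE_A"
    return "TYPE_B"


def evaluation_report(
    predictions: Mapping[str, Mapping[str, str]],
    truths: Mapping[str, SlideTruth],
    lesion_classes: Sequence[str],
) -> pd.DataFrame:
    """Per-slide outcome table across methods.

    ``predictions`` maps method name -> {slide_id -> predicted label or
    abstention status}. Returns one row per (method, slide) with the truth
    and the taxonomy outcome; per method, CORRECT + TYPE_A + TYPE_B +
    TYPE_C + EXCLUDED partitions the cohort.
    """
    rows = []
    for method, preds in predictions.items():
        for slide_id, truth in truths.items():
            if slide_id not in preds:
                raise ValueError(f"method {method!r} has no prediction for slide {slide_id!r}")
            pred = preds[slide_id]
            rows.append(
                {
                    "method": method,
                    "slide_id": slide_id,
                    "prediction": pred,
                    "truth": truth.truth_class,
                    "outcome": type_errors(pred, truth, lesion_classes),
                }
            )
    return pd.DataFrame(rows)
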