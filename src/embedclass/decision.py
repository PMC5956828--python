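"""Slide-level verdicts from tile contingency tables.

The core statistic is a chi-square goodness-of-fit of the observed tile
counts against a uniform split over the remaining categories. The verdict
procedure is iterative: while the distribution is significantly non-uniform
(p < alpha) the smallest class is removed and the rest retested, ending in
either a single DIAGNOSIS or a DIFFERENTIAL list of statistically
indistinguishable classes. A slide whose first-iteration distribution is
significantly dominated by outlier tiles is UNDEFINED — the open-set escape
hatch. Alpha is fixed a priori; nothing is tuned per cohort.

Alongside the map-based verdict, the module computes the softmax-averaging
baseline (mean probability vector over gated tiles), the conservative
combined call (agreement of both methods, else UNDEFINED) and the hybrid
blend of tile fractions and mean probabilities.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._types import OUTLIER, DecisionStatus, IterationRecord, SlideDecision

__all__ = [
    "chi2_uniform",
    "decide",
    "probability_diagnosis",
    "combined_decision",
    "hybrid_scores",
    "tile_fractions",
]


def chi2_uniform(counts: Sequence[float]) -> tuple[float, int, float]:
    """Goodness-of-fit of counts against an equal split.

    Returns ``(statistic, df, p)`` with statistic Σ(O_i − E)²/E, E = total/k
    and df = k − 1. A single category is degenerate (df 0) and returns
    ``(0.0, 0, 1.0)`` by convention. No continuity correction and no
    minimum-expected-count guard: tables here are small by design (15–100
    tiles) and the plain statistic is the procedure.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    total = arr.sum()
    if total < 1:
        raise ValueError("total count must be >= 1")
    k = arr.size
    if k == 1:
        return 0.0, 0, 1.0
    expected = total / k
    statistic = float(((arr - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def _validated_table(table: Mapping[str, int]) -> dict[str, int]:
    if not table:
        raise ValueError("contingency table is empty")
    clean = {}
    for label, count in table.items():
        c = int(count)
        if c != count or c < 0:
            raise ValueError(f"count for {label!r} must be a non-negative integer")
        if c > 0:
            clean[str(label)] = c
    if not clean:
        raise ValueError("contingency table has no positive counts")
    return clean


def decide(table: Mapping[str, int], alpha: float = 0.01) -> SlideDecision:
    """Render the slide verdict from its contingency table.

    Step 1 — outlier check: chi-square over all present categories,
    including OUTLIER; if significant (p < alpha) *and* OUTLIER is a modal
    category, the slide carries too many anomalous tiles → UNDEFINED.

    Step 2 — OUTLIER is set aside; if no real class remains → UNDEFINED.

    Step 3 — iterative elimination over the classes: a singleton is a
    DIAGNOSIS; otherwise test against uniform, stop with a DIFFERENTIAL
    (classes sorted by count, descending) once p >= alpha, else remove the
    smallest-count class (ties by label order) and repeat.
    """
    clean = _validated_table(table)
    trail: list[IterationRecord] = []

    if OUTLIER in clean:
        labels = sorted(clean)
        counts = [clean[c] for c in labels]
        statistic, df, p = chi2_uniform(counts)
        outlier_modal = clean[OUTLIER] == max(clean.values())
        if p < alpha and outlier_modal:
            trail.append(IterationRecord(labels, counts, statistic, df, p, removed=None))
            return SlideDecision(DecisionStatus.UNDEFINED, [], trail, alpha)
        trail.append(IterationRecord(labels, counts, statistic, df, p, removed=OUTLIER))

    classes = {c: n for c, n in clean.items() if c != OUTLIER}
    if not classes:
        return SlideDecision(DecisionStatus.UNDEFINED, [], trail, alpha)

    while True:
        labels = sorted(classes)
        counts = [classes[c] for c in labels]
        statistic, df, p = chi2_uniform(counts)
        if len(labels) == 1:
            trail.append(IterationRecord(labels, counts, statistic, df, p, removed=None))
            return SlideDecision(DecisionStatus.DIAGNOSIS, labels, trail, alpha)
        if p >= alpha:
            trail.append(IterationRecord(labels, counts, statistic, df, p, removed=None))
            ordered = sorted(labels, key=lambda c: (-classes[c], c))
            return SlideDecision(DecisionStatus.DIFFERENTIAL, ordered, trail, alpha)
        smallest = min(labels, key=lambda c: (classes[c], c))
        trail.append(IterationRecord(labels, counts, statistic, df, p, removed=smallest))
        del classes[smallest]


def probability_diagnosis(
    class_probs: np.ndarray, class_names: Sequence[str]
) -> tuple[np.ndarray, str]:
    """Softmax-averaging baseline over the gated tiles.

    Returns the arithmetic-mean probability vector and the top class
    (argmax; exact ties resolved by class order).
    """
    arr = np.atleast_2d(np.asarray(class_probs, dtype=float))
    if arr.shape[0] == 0:
        raise ValueError("need at least one gated tile")
    if arr.shape[1] != len(class_names):
        raise ValueError("probability width disagrees with class_names")
    mean = arr.mean(axis=0)
    return mean, str(class_names[int(np.argmax(mean))])


def combined_decision(tsne_decision: SlideDecision, prob_top: str) -> str:
    """Conservative concordance call: both methods must agree on one class.

    Returns the shared class iff the map-based verdict is a DIAGNOSIS of the
    probability baseline's top class; any discordance or uncertainty is
    UNDEFINED.
    """
    if (
        tsne_decision.status is DecisionStatus.DIAGNOSIS
        and tsne_decision.classes
        and tsne_decision.classes[0] == prob_top
    ):
        return tsne_decision.classes[0]
    return "UNDEFINED"


def tile_fractions(table: Mapping[str, int], class_names: Sequence[str]) -> np.ndarray:
    """Per-class fraction of class-called tiles (OUTLIER excluded entirely).

    An all-outlier slide has no called tiles; its fraction vector is zero.
    """
    called = {c: n for c, n in table.items() if c != OUTLIER}
    total = sum(called.values())
    out = np.zeros(len(class_names), dtype=float)
    if total == 0:
        return out
    for i, name in enumerate(class_names):
        out[i] = called.get(name, 0) / total
    return out


def hybrid_scores(
    tile_frac: np.ndarray, mean_probs: np.ndarray, weight: float = 0.5
) -> np.ndarray:
    """Blend tile-distribution fractions with mean probability scores.

    ``s_c = w * frac_c + (1 − w) * meanprob_c`` with both vectors over the
    same class order.
    """
    tile_frac = np.asarray(tile_frac, dtype=float)
    mean_probs = np.asarray(mean_probs, dtype=float)
    if tile_frac.shape != mean_probs.shape:
        raise ValueError("tile fractions and mean probabilities disagree in shape")
    if not (0.0 <= weight <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    return weight * tile_frac + (1.0 - weight) * mean_probs
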