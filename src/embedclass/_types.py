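"""Core record types shared across the pipeline.

Labels are plain strings throughout; the sentinel :data:`OUTLIER` marks a tile
that could not be discretized into any trained class, and the verdict statuses
mirror the graded reporting scheme a pathologist would use (a single diagnosis,
a differential, or an explicit admission of uncertainty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Sentinel label for tiles that fall in unoccupied embedding space or whose
#: neighborhood is not pure enough to support a class call.
OUTLIER = "OUTLIER"

#: Sentinel truth label for slides of a class the model was never trained on.
NOVEL = "NOVEL"


class DecisionStatus(str, Enum):
    """Graded slide-level verdicts."""

    DIAGNOSIS = "DIAGNOSIS"
    DIFFERENTIAL = "DIFFERENTIAL"
    UNDEFINED = "UNDEFINED"
    INSUFFICIENT_LESIONAL = "INSUFFICIENT_LESIONAL"


class GateStatus(str, Enum):
    """Outcome of the minimum-lesional-tile check."""

    PROCEED = "PROCEED"
    INSUFFICIENT_LESIONAL = "INSUFFICIENT_LESIONAL"


@dataclass(frozen=True)
class TileRecord:
    """One image tile: grid position, embedding and classifier outputs.

    Parameters
    ----------
    tile_id
        Unique identifier within its slide.
    row, col
        0-based grid indices of the tile on the slide.
    feature_vector
        The embedding-provider feature vector (the representation that is
        later reduced to 2-D).
    class_probs
        Softmax probability vector over the trained classes; sums to 1
        within 1e-6.
    p_lesional
        Probability, in [0, 1], that the tile shows lesional tissue
        (the grouped-lesion model's output).
    """

    tile_id: str
    row: int
    col: int
    feature_vector: np.ndarray
    class_probs: np.ndarray
    p_lesional: float

    def __post_init__(self) -> None:
        s = float(np.sum(self.class_probs))
        if abs(s - 1.0) > 1e-6:
            raise ValueError(
                f"tile {self.tile_id}: class_probs sums to {s!r}, expected 1 within 1e-6"
            )
        if not (0.0 <= self.p_lesional <= 1.0):
            raise ValueError(
                f"tile {self.tile_id}: p_lesional {self.p_lesional!r} outside [0, 1]"
            )


@dataclass(frozen=True)
class TileGeometry:
    """Pixel footprint of one grid tile; bounds are half-open intervals."""

    row: int
    col: int
    y0: int
    x0: int
    y1: int
    x1: int


@dataclass
class GateResult:
    """Result of the minimum-lesional-tile rule.

    When a slide fails the rule it is not classified; instead a handful of
    the highest-scoring lesional tiles are carried along for manual review.
    """

    status: GateStatus
    n_tiles: int
    review_tiles: list[TileRecord] = field(default_factory=list)


@dataclass(frozen=True)
class TileAssignment:
    """Per-tile discretization on the 2-D map.

    ``neighbor_class_counts`` counts the class labels among the k examined
    reference neighbors; ``purity`` is the modal class's fraction of k.
    A non-outlier ``call`` always equals the modal class and satisfies
    ``purity >= knn_purity``.
    """

    tile_id: str
    call: str
    neighbor_class_counts: dict[str, int]
    purity: float


@dataclass
class IterationRecord:
    """One round of the iterative chi-square elimination."""

    classes: list[str]
    counts: list[int]
    statistic: float
    df: int
    p_value: float
    removed: str | None


@dataclass
class SlideDecision:
    """Slide-level verdict with its full statistical trail.

    ``classes`` is a singleton for DIAGNOSIS, two or more classes (sorted by
    tile count, descending) for DIFFERENTIAL, and empty otherwise. The trail
    records every chi-square iteration so a reviewer can audit the verdict.
    """

    status: DecisionStatus
    classes: list[str]
    trail: list[IterationRecord]
    alpha: float

    def to_dict(self) -> dict:
        return {
            "status": self.status.value,
            "classes": list(self.classes),
            "alpha": self.alpha,
            "trail": [
                {
                    "classes": it.classes,
                    "counts": it.counts,
                    "statistic": it.statistic,
                    "df": it.df,
                    "p_value": it.p_value,
                    "removed": it.removed,
                }
                for it in self.trail
            ],
        }


@dataclass(frozen=True)
class SlideTruth:
    """Ground-truth annotation for one slide."""

    slide_id: str
    truth_class: str
    is_lesional: bool
    is_trained_class: bool

    def __post_init__(self) -> None:
        if not self.is_trained_class and self.truth_class == "":
            raise ValueError("untrained truth must carry NOVEL or an explicit label")
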