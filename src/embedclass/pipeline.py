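"""End-to-end slide classification.

Gate tiles on lesional probability, sample up to the budget, enforce the
minimum-tile rule, re-embed the reference map jointly with the slide's
tiles, discretize each tile by the kNN purity rule (with the a-priori
unoccupied-space guard), and render the graded chi-square verdict alongside
the probability baseline, the combined concordance call and the hybrid
score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._types import (
    OUTLIER,
    DecisionStatus,
    GateResult,
    GateStatus,
    SlideDecision,
    TileAssignment,
    TileRecord,
)
from .assignment import assign_tiles, tabulate, unoccupied_radius
from .config import PipelineConfig
from .decision import (
    combined_decision,
    decide,
    hybrid_scores,
    probability_diagnosis,
    tile_fractions,
)
from .refmap import embed_with_queries
from .tiling import check_min_tiles, gate_lesional, sample_tiles

__all__ = ["SlideReport", "classify_slide"]


@dataclass
class SlideReport:
    """Everything the pipeline concluded about one slide."""

    slide_id: str
    status: str
    n_tiles: int
    n_gated: int
    n_sampled: int
    class_names: list[str]
    decision: SlideDecision | None = None
    assignments: list[TileAssignment] = field(default_factory=list)
    contingency: dict[str, int] = field(default_factory=dict)
    outlier_fraction: float | None = None
    mean_probs: list[float] | None = None
    prob_top: str | None = None
    combined: str | None = None
    tile_frac: list[float] | None = None
    hybrid: list[float] | None = None
    review_tile_ids: list[str] = field(default_factory=list)

    @property
    def tsne_prediction(self) -> str:
        """Map-based call: the diagnosed class, or the abstention status."""
        if self.decision is not None and self.decision.status is DecisionStatus.DIAGNOSIS:
            return self.decision.classes[0]
        return self.status

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "status": self.status,
            "n_tiles": self.n_tiles,
            "n_gated": self.n_gated,
            "n_sampled": self.n_sampled,
            "class_names": list(self.class_names),
            "decision": self.decision.to_dict() if self.decision else None,
            "assignments": [
                {
                    "tile_id": a.tile_id,
                    "call": a.call,
                    "purity": a.purity,
                    "neighbor_class_counts": a.neighbor_class_counts,
                }
                for a in self.assignments
            ],
            "contingency": dict(sorted(self.contingency.items())),
            "outlier_fraction": self.outlier_fraction,
            "mean_probs": self.mean_probs,
            "prob_top": self.prob_top,
            "combined": self.combined,
            "tile_frac": self.tile_frac,
            "hybrid": self.hybrid,
            "review_tile_ids": list(self.review_tile_ids),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def classify_slide(
    tiles: Sequence[TileRecord],
    ref_features: np.ndarray,
    ref_labels: np.ndarray,
    config: PipelineConfig,
    class_names: Sequence[str],
    slide_id: str = "slide",
) -> SlideReport:
    """Run the full visual-classification workflow on one slide.

    Deterministic given the tiles, the reference set and the config (which
    carries every seed).
    """
    tiles = list(tiles)
    gated = gate_lesional(tiles, config.lesional_threshold)
    sampled = sample_tiles(gated, config.max_tiles_per_slide, config.seed)
    gate: GateResult = check_min_tiles(sampled, config.min_lesional_tiles)

    report = SlideReport(
        slide_id=slide_id,
        status=gate.status.value,
        n_tiles=len(tiles),
        n_gated=len(gated),
        n_sampled=len(sampled),
        class_names=list(class_names),
    )
    if gate.status is GateStatus.INSUFFICIENT_LESIONAL:
        report.review_tile_ids = [t.tile_id for t in gate.review_tiles]
        return report

    query_features = np.vstack([t.feature_vector for t in sampled])
    joint = embed_with_queries(ref_features, ref_labels, query_features, config.embed)

    guard = None
    if config.outlier_distance_factor is not None:
        guard = unoccupied_radius(
            joint.ref_coords, knn_k=config.knn_k, factor=config.outlier_distance_factor
        )
    assignments = assign_tiles(
        joint.query_coords,
        joint.ref_coords,
        joint.ref_labels,
        tile_ids=[t.tile_id for t in sampled],
        knn_k=config.knn_k,
        knn_purity=config.knn_purity,
        max_neighbor_distance=guard,
    )
    table = tabulate(assignments)
    decision = decide(table, alpha=config.alpha)

    probs = np.vstack([t.class_probs for t in sampled])
    mean_probs, prob_top = probability_diagnosis(probs, class_names)
    frac = tile_fractions(table, class_names)
    hybrid = hybrid_scores(frac, mean_probs, config.hybrid_weight)

    report.status = decision.status.value
    report.decision = decision
    report.assignments = assignments
    report.contingency = table
    report.outlier_fraction = table.get(OUTLIER, 0) / len(assignments)
    report.mean_probs = [float(v) for v in mean_probs]
    report.prob_top = prob_top
    report.combined = combined_decision(decision, prob_top)
    report.tile_frac = [float(v) for v in frac]
    report.hybrid = [float(v) for v in hybrid]
    return report
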