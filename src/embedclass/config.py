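"""Configuration objects for the synthetic fixture generator and the pipeline.

Defaults encode the study conditions of the workflow: 13 trained tissue
classes of which five are tumor ("lesional") types, 1024-px tiles at
0.504 um/px, a strict 85% lesional gate, a 15-tile minimum per slide, a
100-tile sampling budget, 25-NN / 85%-purity discretization and an iterative
chi-square at alpha = 0.01.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

#: Canonical class ordering: eight non-lesional tissue classes followed by
#: the five tumor classes. Probability-vector index i corresponds to
#: DEFAULT_CLASS_NAMES[i] for the life of a run.
DEFAULT_CLASS_NAMES: tuple[str, ...] = (
    "gray_matter",
    "white_matter",
    "cerebellum",
    "hemorrhage",
    "necrosis",
    "dura",
    "surgical_material",
    "blank",
    "glioma",
    "meningioma",
    "schwannoma",
    "metastasis",
    "lymphoma",
)

#: Indices of the five tumor classes within DEFAULT_CLASS_NAMES.
DEFAULT_LESION_IDS: tuple[int, ...] = (8, 9, 10, 11, 12)


@dataclass(frozen=True)
class FixtureConfig:
    """Geometry of the synthetic feature-space fixture.

    Class clusters are isotropic Gaussians whose means are placed (from the
    seed) so every pair is at least ``class_separation`` within-class
    standard deviations apart — well-separated clusters being the regime the
    discretization workflow assumes.
    """

    n_classes: int = 13
    feature_dim: int = 64
    class_separation: float = 10.0
    within_class_sd: float = 1.0
    tiles_per_class_range: tuple[int, int] = (350, 600)
    lesion_class_ids: tuple[int, ...] | None = None
    softmax_temperature: float = 1.0
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.tiles_per_class_range
        if not (1 <= lo <= hi):
            raise ValueError(
                f"tiles_per_class_range lower bound must satisfy 1 <= lo <= hi, got {self.tiles_per_class_range}"
            )
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.lesion_class_ids is None:
            # by default the trailing classes are the tumor types: five of
            # thirteen in the canonical layout, otherwise the last ~third
            n_lesion = 5 if self.n_classes == 13 else max(1, self.n_classes // 3)
            object.__setattr__(
                self,
                "lesion_class_ids",
                tuple(range(self.n_classes - n_lesion, self.n_classes)),
            )
        ids = set(self.lesion_class_ids)
        if not ids or not ids <= set(range(self.n_classes)):
            raise ValueError(
                f"lesion_class_ids must be a non-empty subset of 0..{self.n_classes - 1}"
            )
        if self.class_separation <= 0 or self.within_class_sd <= 0:
            raise ValueError("class_separation and within_class_sd must be positive")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")

    @property
    def labels(self) -> tuple[str, ...]:
        """Ordered class labels (generated ``class_00``.. if not supplied)."""
        if self.class_names is not None:
            return tuple(self.class_names)
        if self.n_classes == len(DEFAULT_CLASS_NAMES):
            return DEFAULT_CLASS_NAMES
        return tuple(f"class_{i:02d}" for i in range(self.n_classes))

    @property
    def lesion_labels(self) -> tuple[str, ...]:
        labels = self.labels
        return tuple(labels[i] for i in self.lesion_class_ids)


@dataclass(frozen=True)
class EmbedParams:
    """Parameters of the 2-D embedding used for the reference map."""

    method: str = "tsne"  # "tsne" | "pca"
    perplexity: float = 30.0
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("tsne", "pca"):
            raise ValueError(f"method must be 'tsne' or 'pca', got {self.method!r}")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.max_iter < 250:
            raise ValueError("max_iter must be at least 250")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and sizes of the slide classification pipeline.

    ``outlier_distance_factor`` scales the a-priori "unoccupied space" radius:
    a query tile whose k-th nearest reference neighbor on the 2-D map is
    farther than factor x (95th percentile of the reference points' own
    k-th-NN radius) is called an outlier regardless of neighborhood purity.
    Set to ``None`` to disable the guard and use the purity rule alone.
    """

    tile_size: int = 1024
    microns_per_pixel: float = 0.504
    lesional_threshold: float = 0.85
    min_lesional_tiles: int = 15
    max_tiles_per_slide: int = 100
    knn_k: int = 25
    knn_purity: float = 0.85
    alpha: float = 0.01
    seed: int = 0
    embed: EmbedParams = field(default_factory=EmbedParams)
    hybrid_weight: float = 0.5
    outlier_distance_factor: float | None = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.lesional_threshold < 1.0):
            raise ValueError("lesional_threshold must lie strictly in (0, 1)")
        if not (0.0 < self.knn_purity <= 1.0):
            raise ValueError("knn_purity must lie in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.min_lesional_tiles > self.max_tiles_per_slide:
            raise ValueError("min_lesional_tiles must not exceed max_tiles_per_slide")
        if self.tile_size < 1 or self.knn_k < 1 or self.max_tiles_per_slide < 1:
            raise ValueError("tile_size, knn_k and max_tiles_per_slide must be >= 1")
        if not (0.0 <= self.hybrid_weight <= 1.0):
            raise ValueError("hybrid_weight must lie in [0, 1]")
        if self.outlier_distance_factor is not None and self.outlier_distance_factor <= 0:
            raise ValueError("outlier_distance_factor must be positive or None")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        embed = payload.pop("embed", None)
        if embed is not None:
            payload["embed"] = EmbedParams(**embed)
        return cls(**payload)
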