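"""Two-dimensional reference maps of labeled training tiles.

The reference map is the planar (t-SNE or PCA) embedding of a labeled sample
of training-tile feature vectors. It is refined once by a wide
nearest-neighbor check that removes training points deviating from their own
class cluster, and it is regenerated jointly with each slide's query tiles so
new tiles can be read off the same plane.

t-SNE is stochastic but fully seed-determined here (fixed random_state, PCA
initialization, single-threaded gradient). PCA mode is deterministic with no
seed at all: queries are projected onto components learned from the
reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .config import EmbedParams

__all__ = ["ReferenceMap", "build_map", "refine_map", "embed_with_queries", "JointEmbedding"]


@dataclass
class ReferenceMap:
    """2-D embedded reference points with labels and provenance.

    ``points`` has columns ``tile_id, label, x, y``. ``provenance`` records
    per-class point counts before/after refinement.
    """

    points: pd.DataFrame
    method: str
    params: EmbedParams
    refined: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def coords(self) -> np.ndarray:
        return self.points[["x", "y"]].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.points["label"].to_numpy()

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "params": {
                "method": self.params.method,
                "perplexity": self.params.perplexity,
                "max_iter": self.params.max_iter,
                "seed": self.params.seed,
            },
            "refined": self.refined,
            "provenance": self.provenance,
            "points": [
                {"tile_id": r.tile_id, "label": r.label, "x": float(r.x), "y": float(r.y)}
                for r in self.points.itertuples(index=False)
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceMap":
        payload = json.loads(Path(path).read_text())
        return cls(
            points=pd.DataFrame(payload["points"], columns=["tile_id", "label", "x", "y"]),
            method=payload["method"],
            params=EmbedParams(**payload["params"]),
            refined=payload["refined"],
            provenance=payload["provenance"],
        )

    def plot(self, path: str | Path, query_coords: np.ndarray | None = None) -> None:
        """Scatter the class-colored reference map; queries as red diamonds."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 8))
        labels = sorted(set(self.points["label"]))
        cmap = matplotlib.colormaps["tab20"]
        for i, lab in enumerate(labels):
            sub = self.points[self.points["label"] == lab]
            ax.scatter(sub["x"], sub["y"], s=6, color=cmap(i % 20), label=lab)
        if query_coords is not None and len(query_coords):
            ax.scatter(
                query_coords[:, 0], query_coords[:, 1],
                marker="D", s=22, color="red", edgecolor="black", linewidth=0.3,
                label="query tiles", zorder=5,
            )
        ax.legend(fontsize=7, markerscale=2, loc="best")
        ax.set_xticks([]), ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class JointEmbedding:
    """Joint 2-D coordinates of reference and query tiles for one slide."""

    ref_coords: np.ndarray
    ref_labels: np.ndarray
    query_coords: np.ndarray


def _embed(features: np.ndarray, params: EmbedParams, n_ref: int | None = None) -> np.ndarray:
    if params.method == "pca":
        pca = PCA(n_components=2, svd_solver="full")
        if n_ref is None:
            return pca.fit_transform(features)
        pca.fit(features[:n_ref])
        return pca.transform(features)
    perplexity = min(params.perplexity, (features.shape[0] - 1) / 3.0)
    if perplexity < 2:
        raise ValueError(
            f"{features.shape[0]} points is too few for perplexity {params.perplexity}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=params.max_iter,
        init="pca",
        random_state=params.seed,
        n_jobs=1,
    )
    return np.asarray(tsne.fit_transform(np.asarray(features, dtype=float)))


def build_map(
    features: np.ndarray,
    labels: np.ndarray,
    tile_ids: np.ndarray | None = None,
    params: EmbedParams | None = None,
) -> ReferenceMap:
    """Embed the labeled reference tiles on a 2-D plane.

    One output point per input record, deterministic given the seed. PCA mode
    uses the top two principal components of the centered feature matrix.
    """
    params = params or EmbedParams()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree in length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two classes in the reference set")
    coords = _embed(features, params)
    if tile_ids is None:
        tile_ids = np.array([f"ref_{i:05d}" for i in range(features.shape[0])])
    points = pd.DataFrame(
        {"tile_id": tile_ids, "label": labels, "x": coords[:, 0], "y": coords[:, 1]}
    )
    counts = points["label"].value_counts().to_dict()
    return ReferenceMap(
        points=points,
        method=params.method,
        params=params,
        refined=False,
        provenance={"before": {str(k): int(v) for k, v in sorted(counts.items())}},
    )


def refine_map(
    ref_map: ReferenceMap,
    n_check_neighbors: int = 300,
    own_class_min: float = 0.5,
) -> ReferenceMap:
    """Drop reference points that deviate from their labeled cluster.

    Each point's own-class fraction among its ``n_check_neighbors`` nearest
    reference neighbors (2-D Euclidean, self excluded) is computed in a
    single pass; points below ``own_class_min`` are removed. Refinement that
    would empty a class raises instead.
    """
    n = len(ref_map.points)
    if n <= n_check_neighbors:
        raise ValueError(
            f"map has {n} points; refinement needs more than {n_check_neighbors}"
        )
    coords = ref_map.coords
    labels = ref_map.labels
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=n_check_neighbors + 1)
    neighbor_labels = labels[idx[:, 1:]]  # drop self
    own_frac = (neighbor_labels == labels[:, None]).mean(axis=1)
    keep = own_frac >= own_class_min
    kept = ref_map.points.loc[keep].reset_index(drop=True)
    emptied = sorted(set(labels.tolist()) - set(kept["label"].tolist()))
    if emptied:
        raise ValueError(f"refinement would remove every point of class(es): {emptied}")
    after = kept["label"].value_counts().to_dict()
    provenance = dict(ref_map.provenance)
    provenance["after"] = {str(k): int(v) for k, v in sorted(after.items())}
    provenance["removed"] = {
        str(k): int(provenance.get("before", {}).get(str(k), 0) - after.get(k, 0))
        for k in sorted(set(labels.tolist()))
    }
    return replace(ref_map, points=kept, refined=True, provenance=provenance)


def embed_with_queries(
    ref_features: np.ndarray,
    ref_labels: np.ndarray,
    query_features: np.ndarray,
    params: EmbedParams | None = None,
) -> JointEmbedding:
    """Re-embed reference and query tiles jointly for one slide.

    t-SNE mode regenerates the embedding from scratch on the stacked matrix
    (the per-slide protocol; the global structure is preserved in practice
    but coordinates are not comparable across slides). PCA mode learns the
    components from the reference alone and projects both sets, which is
    exactly reproducible.
    """
    params = params or EmbedParams()
    ref_features = np.asarray(ref_features, dtype=float)
    query_features = np.asarray(query_features, dtype=float)
    if query_features.ndim != 2 or query_features.shape[0] < 1:
        raise ValueError("need at least one query tile")
    if query_features.shape[1] != ref_features.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: reference {ref_features.shape[1]}, "
            f"query {query_features.shape[1]}"
        )
    stacked = np.vstack([ref_features, query_features])
    n_ref = ref_features.shape[0]
    coords = _embed(stacked, params, n_ref=n_ref if params.method == "pca" else None)
    return JointEmbedding(
        ref_coords=coords[:n_ref],
        ref_labels=np.asarray(ref_labels),
        query_coords=coords[n_ref:],
    )
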