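"""Synthetic feature-space fixtures.

Emulates what a fine-tuned CNN hands to the embedding workflow: a labeled
reference set of per-tile feature vectors forming well-separated class
clusters, per-slide tile mixtures (lesional tiles from one tumor class plus
contaminating non-lesional background), and novel "untrained" clusters placed
far from every trained class. Per-tile class probabilities are derived from
the same geometry by a squared-distance softmax, so the mock classifier is
calibrated against the clusters by construction.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from ._types import NOVEL, TileRecord
from .config import FixtureConfig

__all__ = [
    "PlacementError",
    "SyntheticSlide",
    "class_means",
    "make_reference_set",
    "make_slide",
    "make_novel_slide",
    "softmax_probs",
    "write_reference_csv",
    "read_reference_csv",
    "write_slide_dir",
    "read_slide_dir",
]


class PlacementError(RuntimeError):
    """Raised when cluster means cannot be placed at the required separation."""


@dataclass
class SyntheticSlide:
    """A synthetic slide: a tile mixture with known ground truth.

    ``class_names`` records the class ordering of the tiles' probability
    vectors (index i of every ``class_probs`` refers to ``class_names[i]``).
    """

    slide_id: str
    truth_class: str
    tiles: list[TileRecord] = field(default_factory=list)
    truth_is_lesional: bool = True
    truth_is_trained: bool = True
    class_names: tuple[str, ...] | None = None


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def class_means(config: FixtureConfig) -> np.ndarray:
    """Place the trained class means, deterministically from the seed.

    Means are drawn from an isotropic Gaussian of scale
    ``class_separation * within_class_sd`` and rejected until every pairwise
    distance is at least ``class_separation * within_class_sd``. In a
    reasonably high-dimensional space the first draw almost always succeeds;
    in low dimension, repeated failure raises :class:`PlacementError` naming
    the constraint.
    """
    rng = _rng(config.seed)
    min_dist = config.class_separation * config.within_class_sd
    scale = min_dist
    means: list[np.ndarray] = []
    for c in range(config.n_classes):
        for _ in range(1000):
            candidate = rng.normal(scale=scale, size=config.feature_dim)
            if all(np.linalg.norm(candidate - m) >= min_dist for m in means):
                means.append(candidate)
                break
        else:
            raise PlacementError(
                f"could not place mean for class {c}: feature_dim={config.feature_dim} "
                f"is too small to hold {config.n_classes} means with pairwise "
                f"separation >= {min_dist:g} (= class_separation x within_class_sd)"
            )
    out = np.asarray(means)
    assert pdist(out).min() >= min_dist
    return out


def softmax_probs(
    features: np.ndarray, means: np.ndarray, temperature: float = 1.0
) -> np.ndarray:
    """Mock classifier head: softmax of minus squared distance to each mean.

    Monotone in cluster membership — a tile at a class mean scores that class
    near 1 when the other means are far; a tile equidistant from all means
    scores uniformly.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    d2 = cdist(features, means, metric="sqeuclidean")
    logits = -d2 / float(temperature)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p


def make_reference_set(config: FixtureConfig) -> pd.DataFrame:
    """Generate the labeled reference tiles.

    Per class, a tile count is drawn uniformly from
    ``tiles_per_class_range`` (inclusive) and features from an isotropic
    Gaussian at the class mean. Returns a frame with columns
    ``tile_id, label, f0..f{D-1}``, fully determined by the seed.
    """
    means = class_means(config)
    rng = _rng(config.seed + 1)
    lo, hi = config.tiles_per_class_range
    labels = config.labels
    rows_id: list[str] = []
    rows_label: list[str] = []
    feats: list[np.ndarray] = []
    for c in range(config.n_classes):
        n_c = int(rng.integers(lo, hi + 1))
        f = means[c] + rng.normal(scale=config.within_class_sd, size=(n_c, config.feature_dim))
        feats.append(f)
        rows_id.extend(f"ref_c{c:02d}_{i:04d}" for i in range(n_c))
        rows_label.extend([labels[c]] * n_c)
    features = np.vstack(feats)
    frame = pd.DataFrame(features, columns=[f"f{j}" for j in range(config.feature_dim)])
    frame.insert(0, "label", rows_label)
    frame.insert(0, "tile_id", rows_id)
    return frame


def _tiles_from_features(
    features: np.ndarray,
    means: np.ndarray,
    config: FixtureConfig,
    prefix: str,
) -> list[TileRecord]:
    probs = softmax_probs(features, means, config.softmax_temperature)
    lesion_ids = list(config.lesion_class_ids)
    n = features.shape[0]
    ncol = max(1, math.ceil(math.sqrt(n)))
    tiles = []
    for i in range(n):
        p = probs[i]
        tiles.append(
            TileRecord(
                tile_id=f"{prefix}_{i:04d}",
                row=i // ncol,
                col=i % ncol,
                feature_vector=features[i],
                class_probs=p,
                p_lesional=float(min(1.0, p[lesion_ids].sum())),  # guard 1-ulp drift
            )
        )
    return tiles


def make_slide(
    config: FixtureConfig,
    truth_class: int,
    n_lesional: int,
    n_background: int,
    seed: int,
    slide_id: str | None = None,
) -> SyntheticSlide:
    """Generate one slide: lesional tiles from ``truth_class`` plus background.

    Background tiles are drawn from the non-lesional class clusters (one
    class chosen at random per tile), emulating the normal tissue, blood and
    artifact that surround a lesion on a real slide.
    """
    if not (0 <= truth_class < config.n_classes):
        raise ValueError(f"truth_class {truth_class} outside 0..{config.n_classes - 1}")
    if n_lesional < 0 or n_background < 0:
        raise ValueError("tile counts must be non-negative")
    if n_lesional == 0 and n_background == 0:
        raise ValueError("empty slide: n_lesional and n_background are both zero")
    means = class_means(config)
    rng = _rng(seed)
    sd = config.within_class_sd
    parts = []
    if n_lesional:
        parts.append(means[truth_class] + rng.normal(scale=sd, size=(n_lesional, config.feature_dim)))
    if n_background:
        bg_ids = [c for c in range(config.n_classes) if c not in config.lesion_class_ids]
        picks = rng.choice(bg_ids, size=n_background)
        parts.append(means[picks] + rng.normal(scale=sd, size=(n_background, config.feature_dim)))
    features = np.vstack(parts)
    sid = slide_id or f"slide_{truth_class:02d}_{seed}"
    label = config.labels[truth_class]
    return SyntheticSlide(
        slide_id=sid,
        truth_class=label,
        tiles=_tiles_from_features(features, means, config, sid),
        truth_is_lesional=truth_class in config.lesion_class_ids,
        truth_is_trained=True,
        class_names=config.labels,
    )


def make_novel_slide(
    config: FixtureConfig,
    n_tiles: int,
    seed: int,
    offset_sd: float = 10.0,
    slide_id: str | None = None,
    lesional_like: bool = True,
) -> SyntheticSlide:
    """Generate a slide from a cluster the classifier was never trained on.

    The novel mean is placed at least ``offset_sd x within_class_sd`` from
    every trained mean; probability vectors are still computed against the
    trained means (the mock classifier knows nothing of the novel class).
    With ``lesional_like`` (default) the placement additionally requires the
    nearest trained mean to be a lesion class, so the novel tumor reads as
    lesional to the gate — the open-set scenario of interest, since a novel
    cluster nearest to normal tissue would simply be gated out upstream.
    """
    if offset_sd <= 0:
        raise ValueError("offset_sd must be positive")
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    means = class_means(config)
    rng = _rng(seed)
    min_dist = offset_sd * config.within_class_sd
    scale = (config.class_separation + offset_sd) * config.within_class_sd
    lesion_ids = set(config.lesion_class_ids)
    novel_mean = None
    for _ in range(5000):
        candidate = rng.normal(scale=scale, size=config.feature_dim)
        d = np.linalg.norm(means - candidate, axis=1)
        if d.min() < min_dist:
            continue
        if lesional_like and int(d.argmin()) not in lesion_ids:
            continue
        novel_mean = candidate
        break
    if novel_mean is None:
        raise PlacementError(
            f"could not place a novel mean at distance >= {min_dist:g} from all "
            f"{config.n_classes} trained means in {config.feature_dim} dimensions"
        )
    features = novel_mean + rng.normal(scale=config.within_class_sd, size=(n_tiles, config.feature_dim))
    sid = slide_id or f"novel_{seed}"
    return SyntheticSlide(
        slide_id=sid,
        truth_class=NOVEL,
        tiles=_tiles_from_features(features, means, config, sid),
        truth_is_lesional=True,
        truth_is_trained=False,
        class_names=config.labels,
    )


# ---------------------------------------------------------------------------
# plain-text IO

def write_reference_csv(reference: pd.DataFrame, path: str | Path) -> None:
    reference.to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_slide_dir(slide: SyntheticSlide, out_dir: str | Path) -> Path:
    """Write one slide as ``tiles.csv`` plus ``slide.json`` truth metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = len(slide.tiles[0].class_probs)
    d = len(slide.tiles[0].feature_vector)
    rows = []
    for t in slide.tiles:
        row = {"tile_id": t.tile_id, "row": t.row, "col": t.col, "p_lesional": t.p_lesional}
        row.update({f"p_c{i}": t.class_probs[i] for i in range(k)})
        row.update({f"f{j}": t.feature_vector[j] for j in range(d)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "tiles.csv", index=False)
    (out / "slide.json").write_text(
        json.dumps(
            {
                "slide_id": slide.slide_id,
                "truth_class": slide.truth_class,
                "truth_is_lesional": slide.truth_is_lesional,
                "truth_is_trained": slide.truth_is_trained,
                "class_names": list(slide.class_names) if slide.class_names else None,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return out


def read_slide_dir(slide_dir: str | Path) -> SyntheticSlide:
    p = Path(slide_dir)
    meta = json.loads((p / "slide.json").read_text())
    frame = pd.read_csv(p / "tiles.csv")
    pcols = sorted(
        (c for c in frame.columns if c.startswith("p_c")), key=lambda c: int(c[3:])
    )
    fcols = sorted(
        (c for c in frame.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    tiles = [
        TileRecord(
            tile_id=str(r["tile_id"]),
            row=int(r["row"]),
            col=int(r["col"]),
            feature_vector=r[fcols].to_numpy(dtype=float),
            class_probs=r[pcols].to_numpy(dtype=float),
            p_lesional=float(r["p_lesional"]),
        )
        for _, r in frame.iterrows()
    ]
    return SyntheticSlide(
        slide_id=meta["slide_id"],
        truth_class=meta["truth_class"],
        tiles=tiles,
        truth_is_lesional=bool(meta["truth_is_lesional"]),
        truth_is_trained=bool(meta["truth_is_trained"]),
        class_names=tuple(meta["class_names"]) if meta.get("class_names") else None,
    )
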