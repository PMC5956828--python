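"""Embedding-provider contract.

The pipeline is agnostic about where per-tile feature vectors and class
probabilities come from: a trained network, a precomputed table, or the mock
provider shipped here. Any provider must be deterministic (same tile, same
outputs) and expose a fixed class ordering — probability-vector index ``i``
always refers to ``class_names[i]``.

A trained-network adapter can be wired in by implementing
:class:`EmbeddingProvider`; nothing else in the pipeline changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from ._types import TileRecord
from .config import FixtureConfig
from .fixtures import class_means, softmax_probs

#: Probability vectors must sum to 1 within this tolerance; slight float
#: drift is renormalized, anything worse is rejected as a provider bug.
PROB_SUM_TOL = 1e-6


class ProviderError(ValueError):
    """A provider returned malformed output for a tile."""


def validate_probs(probs: np.ndarray, tile_id: str = "?") -> np.ndarray:
    """Check and renormalize a class-probability vector.

    Accepts vectors whose sum deviates from 1 by at most :data:`PROB_SUM_TOL`
    (renormalizing the drift away); larger deviations raise
    :class:`ProviderError` naming the tile.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0:
        raise ProviderError(f"tile {tile_id}: probability vector has bad shape {probs.shape}")
    if np.any(probs < 0):
        raise ProviderError(f"tile {tile_id}: negative probability")
    s = float(probs.sum())
    if abs(s - 1.0) > PROB_SUM_TOL:
        raise ProviderError(f"tile {tile_id}: probabilities sum to {s!r}, expected 1 within {PROB_SUM_TOL}")
    return probs / s


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract supplying features and probabilities for tiles."""

    n_classes: int
    feature_dim: int
    class_names: tuple[str, ...]

    def embed(self, tile: TileRecord) -> np.ndarray: ...

    def class_probs(self, tile: TileRecord) -> np.ndarray: ...

    def lesional_prob(self, tile: TileRecord) -> float: ...


@dataclass
class MockProvider:
    """Provider backed by the synthetic fixture geometry.

    ``embed`` passes the tile's stored feature vector through unchanged;
    probabilities are recomputed from the fixture's class means by the same
    squared-distance softmax the generator uses, and the lesional probability
    is the summed probability mass of the lesion classes (the grouped-lesion
    reading of the class list).
    """

    config: FixtureConfig

    def __post_init__(self) -> None:
        self._means = class_means(self.config)
        self.n_classes = self.config.n_classes
        self.feature_dim = self.config.feature_dim
        self.class_names = self.config.labels

    def embed(self, tile: TileRecord) -> np.ndarray:
        vec = np.asarray(tile.feature_vector, dtype=float)
        if vec.shape != (self.feature_dim,):
            raise ProviderError(
                f"tile {tile.tile_id}: feature vector shape {vec.shape}, expected ({self.feature_dim},)"
            )
        return vec

    def class_probs(self, tile: TileRecord) -> np.ndarray:
        p = softmax_probs(self.embed(tile), self._means, self.config.softmax_temperature)[0]
        return validate_probs(p, tile.tile_id)

    def lesional_prob(self, tile: TileRecord) -> float:
        p = self.class_probs(tile)
        return float(p[list(self.config.lesion_class_ids)].sum())


@dataclass
class PrecomputedProvider:
    """Provider that trusts the values already stored on each tile record.

    This is the path for pipelines fed from a ``tiles.csv`` of precomputed
    network outputs — no image decoding, no recomputation.
    """

    n_classes: int
    feature_dim: int
    class_names: tuple[str, ...]

    def embed(self, tile: TileRecord) -> np.ndarray:
        vec = np.asarray(tile.feature_vector, dtype=float)
        if vec.shape != (self.feature_dim,):
            raise ProviderError(
                f"tile {tile.tile_id}: feature vector shape {vec.shape}, expected ({self.feature_dim},)"
            )
        return vec

    def class_probs(self, tile: TileRecord) -> np.ndarray:
        return validate_probs(tile.class_probs, tile.tile_id)

    def lesional_prob(self, tile: TileRecord) -> float:
        p = float(tile.p_lesional)
        if not (0.0 <= p <= 1.0):
            raise ProviderError(f"tile {tile.tile_id}: lesional probability {p!r} outside [0, 1]")
        return p
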