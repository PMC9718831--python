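"""Latent-space projection and nearest-neighbour fitness subtyping.

After training, every participant maps to a 128-dimensional point (the
dense model's penultimate-layer activations).  This module projects
that cloud to 2-D with t-SNE for visualization and compares exact
Euclidean nearest-neighbour structure between the model's input
("original") space and the learned latent space — tighter neighbour
totals in the latent space indicate better semantic clustering of
fitness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE


@dataclass
class EmbeddingSpace:
    """Per-participant vectors in one comparison space."""

    kind: str  # "original_scaled" | "latent" | free-form
    ids: list[str]
    vectors: np.ndarray  # (n, d)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("participant ids must be unique")
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("one vector per id required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding vectors must be finite")
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @classmethod
    def from_frame(cls, kind: str, frame: pd.DataFrame) -> "EmbeddingSpace":
        return cls(kind=kind, ids=list(frame.index.astype(str)),
                   vectors=frame.to_numpy(float))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class NeighborResult:
    query_id: str
    k: int
    neighbor_ids: list[str]
    distances: list[float]  # non-decreasing

    @property
    def total_distance(self) -> float:
        return float(sum(self.distances))


def knn_query(space: EmbeddingSpace, query_id: str, k: int = 5) -> NeighborResult:
    """Exact Euclidean k-nearest neighbours of one participant.

    The query is never its own neighbour; distance ties are broken by
    participant id so results are storage-order invariant.
    """
    if query_id not in space._index:
        raise ValueError(f"unknown participant id {query_id!r}")
    if not 1 <= k < len(space):
        raise ValueError("k must be in [1, population size)")
    qi = space._index[query_id]
    diffs = space.vectors - space.vectors[qi]
    dists = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    order = sorted((i for i in range(len(space)) if i != qi),
                   key=lambda i: (dists[i], space.ids[i]))
    chosen = order[:k]
    return NeighborResult(
        query_id=query_id, k=k,
        neighbor_ids=[space.ids[i] for i in chosen],
        distances=[float(dists[i]) for i in chosen],
    )


def project_tsne(space: EmbeddingSpace, perplexity: float = 50.0,
                 seed: int = 0) -> pd.DataFrame:
    """Seeded 2-D t-SNE projection of an embedding space.

    Requires population > 3 * perplexity (the standard validity rule of
    the algorithm).  The outcome variable plays no role here; colour
    any resulting scatter by VO2max downstream.
    """
    n = len(space)
    if n <= 3 * perplexity:
        raise ValueError(
            f"population {n} too small for perplexity {perplexity}; "
            f"t-SNE needs population > 3 * perplexity")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    coords = tsne.fit_transform(space.vectors)
    return pd.DataFrame(coords, index=pd.Index(space.ids, name="participant_id"),
                        columns=["tsne1", "tsne2"])


def compare_spaces(original: EmbeddingSpace, latent: EmbeddingSpace,
                   query_ids: Sequence[str], k: int = 5) -> pd.DataFrame:
    """Paired neighbour-distance totals per query in both spaces.

    Returns one row per query with ``total_original`` and
    ``total_latent``; the frame's ``attrs["fraction_latent_smaller"]``
    records how often the latent total is strictly smaller (a logged
    diagnostic, not an enforced claim).
    """
    if set(original.ids) != set(latent.ids):
        raise ValueError("both spaces must contain the same participant ids")
    rows = []
    for pid in query_ids:
        t_orig = knn_query(original, pid, k).total_distance
        t_lat = knn_query(latent, pid, k).total_distance
        rows.append({"participant_id": pid, "total_original": t_orig,
                     "total_latent": t_lat})
    out = pd.DataFrame(rows).set_index("participant_id")
    out.attrs["fraction_latent_smaller"] = float(
        (out["total_latent"] < out["total_original"]).mean())
    return out
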