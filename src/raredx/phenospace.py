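"""Phenotype-space construction: pairwise similarity of term-annotated
entities (patients and reference diseases), conversion to distances and a
low-dimensional UMAP embedding.

Patients and reference diseases are treated uniformly as entities carrying
a term set; the pairwise symmetric best-match-average Resnik similarity is
converted to a dissimilarity and embedded in four dimensions with UMAP on
the precomputed distance matrix.  Only the first two dimensions are
normally plotted.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyIndex, patient_similarity

__all__ = [
    "EmbeddingResult",
    "similarity_matrix",
    "to_distance",
    "embed",
    "export_coordinates",
    "plot_embedding",
]

DEFAULT_N_NEIGHBORS = 15
DEFAULT_MIN_DIST = 0.1


@dataclass
class EmbeddingResult:
    """UMAP coordinates plus the provenance needed to reproduce them."""

    coordinates: pd.DataFrame  # one row per entity, columns dim1..dimK
    seed: int
    n_neighbors: int
    min_dist: float
    distance_hash: str  # sha256 of the distance matrix bytes

    @property
    def entity_ids(self) -> list[str]:
        return list(self.coordinates.index)


def similarity_matrix(
    index: OntologyIndex,
    entities: Mapping[str, set] | Sequence[tuple[str, set]],
) -> tuple[list[str], np.ndarray]:
    """Symmetric pairwise best-match-average similarity matrix.

    Entities with an empty term set are dropped with a warning.  The
    diagonal holds each entity's self-similarity, which is row-wise
    maximal because every term best-matches itself.
    """
    items = list(entities.items()) if isinstance(entities, Mapping) else list(entities)
    kept = []
    for eid, terms in items:
        if not terms:
            warnings.warn(f"entity {eid!r} has no terms; dropped", stacklevel=2)
            continue
        kept.append((eid, set(terms)))
    if len(kept) < 2:
        raise ValueError("need at least two entities with non-empty term sets")
    ids = [eid for eid, _ in kept]
    n = len(kept)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = patient_similarity(index, kept[i][1], kept[j][1])
            sim[i, j] = sim[j, i] = s
    return ids, sim


def to_distance(sim: np.ndarray, method: str = "shift") -> np.ndarray:
    """Convert a similarity matrix to a dissimilarity matrix.

    ``shift`` (default): D = max(S) - S; ``inverse``: D = 1 / (1 + S).
    The diagonal is forced to zero so the result is a valid dissimilarity.
    """
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if method == "shift":
        dist = sim.max() - sim
    elif method == "inverse":
        dist = 1.0 / (1.0 + sim)
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(dist, 0.0)
    return dist


def embed(
    sim: np.ndarray,
    entity_ids: Sequence[str] | None = None,
    dims: int = 4,
    seed: int = 1,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    distance_method: str = "shift",
) -> EmbeddingResult:
    """Embed entities in ``dims`` dimensions with UMAP on precomputed
    distances derived from the similarity matrix.

    Deterministic for a fixed seed (UMAP is run single-threaded with a
    fixed random state).  ``n_neighbors`` is clamped to n - 1 for small
    inputs.
    """
    if dims < 2:
        raise ValueError("dims must be >= 2")
    dist = to_distance(np.asarray(sim, dtype=float), method=distance_method)
    n = dist.shape[0]
    if entity_ids is None:
        entity_ids = [f"entity_{i}" for i in range(n)]
    if len(entity_ids) != n:
        raise ValueError("entity_ids length does not match matrix size")
    k = min(n_neighbors, n - 1)

    import umap  # deferred: numba compilation is slow at import time

    def _fit(init: str) -> np.ndarray:
        reducer = umap.UMAP(
            n_components=dims,
            metric="precomputed",
            n_neighbors=k,
            min_dist=min_dist,
            random_state=seed,
            init=init,
        )
        return reducer.fit_transform(dist)

    # spectral initialization needs dims + 1 eigenvectors < n, and its
    # failure fallback inside umap is not seed-reproducible; detect the
    # failure and refit with the (seeded, deterministic) random init
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if n > dims + 2:
            coords = _fit("spectral")
            if any("Spectral initialisation failed" in str(w.message)
                   for w in caught):
                coords = _fit("random")
        else:
            coords = _fit("random")
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    frame = pd.DataFrame(
        coords,
        index=pd.Index(entity_ids, name="entity_id"),
        columns=[f"dim{i + 1}" for i in range(dims)],
    )
    digest = hashlib.sha256(np.ascontiguousarray(dist).tobytes()).hexdigest()
    return EmbeddingResult(
        coordinates=frame,
        seed=seed,
        n_neighbors=k,
        min_dist=min_dist,
        distance_hash=digest,
    )


def export_coordinates(
    result: EmbeddingResult, path, labels: Mapping[str, str] | None = None
) -> None:
    """Write coordinates as TSV (entity_id, dim1..dimK[, label])."""
    out = result.coordinates.copy()
    if labels is not None:
        out["label"] = [labels.get(e, "") for e in out.index]
    out.to_csv(path, sep="\t")


def plot_embedding(
    result: EmbeddingResult,
    path,
    labels: Mapping[str, str] | None = None,
) -> None:
    """Scatter plot of the first two embedding dimensions, colored by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.coordinates
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.scatter(frame["dim1"], frame["dim2"], s=8)
    else:
        series = pd.Series({e: labels.get(e, "unlabeled") for e in frame.index})
        for lab, idx in series.groupby(series).groups.items():
            sub = frame.loc[idx]
            ax.scatter(sub["dim1"], sub["dim2"], s=8, label=str(lab))
        ax.legend(fontsize=7, markerscale=1.5)
    ax.set_xlabel("dim1")
    ax.set_ylabel("dim2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
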