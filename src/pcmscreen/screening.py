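"""Virtual screening: affinity filter, novelty band, clustering, representatives.

The pipeline order is: stream the library through the model keeping
predicted actives (pChEMBL >= threshold), drop compounds outside the
novelty band (Tanimoto to the nearest training compound must be strictly
between the low and high bounds), cluster survivors by fingerprint
Jaccard distance with a minimum cluster size, and flag the top-predicted
member of every non-noise cluster as its representative.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.manifold import TSNE

from .curation import standardize_compound
from .descriptors import ecfp_fingerprint

DEFAULT_SEED = 12345
#: Predicted pChEMBL cutoff: 100 nM, i.e. 7.00 log units. Compounds at or
#: above the threshold are retained.
AFFINITY_THRESHOLD = 7.0
#: Novelty band: keep hits with low < Tanimoto-to-training < high.
NOVELTY_LOW, NOVELTY_HIGH = 0.50, 0.90
MIN_CLUSTER_SIZE = 19


@dataclass
class ScreeningHit:
    smiles: str
    compound_id: str
    predicted_pchembl: float
    nearest_training_similarity: float | None = None
    cluster_label: int | None = None
    is_representative: bool = False


@dataclass
class ScreenStats:
    n_scored: int = 0
    n_retained: int = 0
    n_unparseable: int = 0


def read_smiles(source: str | Path | Iterable[str]) -> Iterator[tuple[str, str]]:
    """Yield (smiles, id) from a SMILES file (optionally gzipped) or iterable.

    Lines hold a SMILES and an optional whitespace-separated id.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            yield from _parse_lines(handle)
    else:
        yield from _parse_lines(source)


def _parse_lines(lines: Iterable[str]) -> Iterator[tuple[str, str]]:
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        yield parts[0], (parts[1] if len(parts) > 1 else f"mol{i}")


def screen_library(
    model,
    library: str | Path | Iterable[str],
    featurize: Callable[[Sequence[str]], np.ndarray],
    threshold: float = AFFINITY_THRESHOLD,
    batch_size: int = 1000,
    standardize: bool = True,
) -> tuple[list[ScreeningHit], ScreenStats]:
    """Stream a SMILES library through the model, keeping predicted actives.

    Memory stays bounded by ``batch_size`` plus the retained hit list:
    compounds predicted below ``threshold`` are discarded per batch.
    ``featurize`` maps a list of standardized SMILES to the model's
    feature rows (compound blocks + the fixed seed-target protein blocks).
    """
    stats = ScreenStats()
    hits: list[ScreeningHit] = []
    batch: list[tuple[str, str]] = []

    def flush() -> None:
        if not batch:
            return
        smiles = [s for s, _ in batch]
        preds = np.asarray(model.predict(featurize(smiles))).ravel()
        stats.n_scored += len(batch)
        for (smi, cid), pred in zip(batch, preds):
            if pred >= threshold:
                hits.append(ScreeningHit(smiles=smi, compound_id=cid, predicted_pchembl=float(pred)))
        batch.clear()

    for smi, cid in read_smiles(library):
        if standardize:
            try:
                smi = standardize_compound(smi)
            except ValueError:
                stats.n_unparseable += 1
                continue
        batch.append((smi, cid))
        if len(batch) >= batch_size:
            flush()
    flush()
    stats.n_retained = len(hits)
    if stats.n_scored == 0:
        warnings.warn("screening library was empty", stacklevel=2)
    return hits, stats


def _fingerprints(smiles: Sequence[str], radius: int, n_bits: int) -> np.ndarray:
    return np.stack([ecfp_fingerprint(s, radius, n_bits) for s in smiles]).astype(bool)


def nearest_training_similarity(
    fps: np.ndarray, training_fps: np.ndarray
) -> np.ndarray:
    """Max Tanimoto similarity of each row in ``fps`` to the training set."""
    fps = np.asarray(fps, dtype=bool)
    train = np.asarray(training_fps, dtype=bool)
    if train.size == 0:
        raise ValueError("empty training fingerprint set")
    inter = fps.astype(np.int32) @ train.astype(np.int32).T
    union = fps.sum(axis=1)[:, None] + train.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim.max(axis=1)


def novelty_filter(
    hits: Sequence[ScreeningHit],
    training_fps: np.ndarray,
    low: float = NOVELTY_LOW,
    high: float = NOVELTY_HIGH,
    radius: int = 3,
    n_bits: int = 1024,
    fps: np.ndarray | None = None,
) -> list[ScreeningHit]:
    """Keep hits inside the open novelty band low < similarity < high.

    A hit with 90% or higher identity to the training set is redundant; one
    with 50% or lower identity is outside the model's applicability domain.
    Both boundaries are removed. Every surviving hit is annotated with its
    nearest-training-compound Tanimoto similarity. ``fps`` may supply
    precomputed hit fingerprints (same parameters as the training set's).
    """
    if not hits:
        return []
    if fps is None:
        fps = _fingerprints([h.smiles for h in hits], radius, n_bits)
    sims = nearest_training_similarity(fps, training_fps)
    kept = []
    for hit, sim in zip(hits, sims):
        hit.nearest_training_similarity = float(sim)
        if low < sim < high:
            kept.append(hit)
    return kept


def cluster_hits(
    hits: Sequence[ScreeningHit],
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    radius: int = 3,
    n_bits: int = 1024,
) -> list[ScreeningHit]:
    """Density-cluster hits on fingerprint Jaccard distance (HDBSCAN).

    Clustering runs on the fingerprints directly, never on a 2-D
    embedding. Points in no dense region get the noise label -1; every
    non-noise cluster has at least ``min_cluster_size`` members.
    """
    if not hits:
        raise ValueError("no hits to cluster")
    if len(hits) < min_cluster_size:
        for hit in hits:
            hit.cluster_label = -1
        return list(hits)
    fps = _fingerprints([h.smiles for h in hits], radius, n_bits)
    inter = fps.astype(np.int32) @ fps.astype(np.int32).T
    counts = fps.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    if dist.max() == 0.0:
        # degenerate: all hits identical — HDBSCAN never selects the root
        labels = np.zeros(len(hits), dtype=int)
    else:
        labels = HDBSCAN(min_cluster_size=min_cluster_size, metric="precomputed", copy=True).fit_predict(dist)
    for hit, label in zip(hits, labels):
        hit.cluster_label = int(label)
    return list(hits)


def select_representatives(hits: Sequence[ScreeningHit]) -> list[ScreeningHit]:
    """Flag the top-predicted hit of every non-noise cluster.

    Ties break toward the higher nearest-training similarity, then the
    lexicographically smallest canonical SMILES. Noise points are never
    selected.
    """
    if any(h.cluster_label is None for h in hits):
        raise ValueError("cluster labels must be assigned first")
    for hit in hits:
        hit.is_representative = False
    clusters: dict[int, list[ScreeningHit]] = {}
    for hit in hits:
        if hit.cluster_label != -1:
            clusters.setdefault(hit.cluster_label, []).append(hit)
    if not clusters:
        warnings.warn("all hits are noise; no representatives selected", stacklevel=2)
        return []
    reps = []
    for label in sorted(clusters):
        best = min(
            clusters[label],
            key=lambda h: (
                -h.predicted_pchembl,
                -(h.nearest_training_similarity or 0.0),
                h.smiles,
            ),
        )
        best.is_representative = True
        reps.append(best)
    return reps


def embed_2d(
    hits: Sequence[ScreeningHit],
    seed: int = DEFAULT_SEED,
    perplexity: float = 30.0,
    radius: int = 3,
    n_bits: int = 1024,
) -> np.ndarray:
    """t-SNE layout of hit fingerprints for reporting (never for clustering)."""
    if len(hits) < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} points for perplexity {perplexity}"
        )
    fps = _fingerprints([h.smiles for h in hits], radius, n_bits).astype(float)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(fps)
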