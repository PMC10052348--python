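"""Data-driven selection of training targets for a PCM model.

The protein of interest (the seed) rarely has enough ligand data on its
own. Candidate training sets are built by pulling in related proteins
two ways: (1) connected components of a sequence-similarity network at
descending alignment-score thresholds, and (2) nested clades around the
seed in a neighbor-joining tree. Each candidate "layer" is scored with a
fixed out-of-the-box random forest under cross-validation, and the
largest layer whose score is within tolerance of the best is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_predict

from .curation import ActivityRecord
from .descriptors import (
    acc_transform,
    assemble_features,
    ecfp_fingerprint,
    physchem_block,
    residue_scale_encoding,
)
from .modeling import compute_metrics

DEFAULT_SEED = 12345
#: Alignment-score thresholds used for the similarity-network sweep; raw
#: local-alignment scores are database-specific, so these are defaults, not
#: universal constants.
DEFAULT_THRESHOLDS = (850, 650, 550, 350, 100)

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


@dataclass(frozen=True)
class SimilarityMatrix:
    ids: tuple[str, ...]
    scores: np.ndarray  # symmetric, nonnegative

    def __post_init__(self) -> None:
        s = self.scores
        if s.shape != (len(self.ids), len(self.ids)):
            raise ValueError("score matrix shape does not match ids")
        if not np.allclose(s, s.T):
            raise ValueError("score matrix must be symmetric")


@dataclass
class LayerDataset:
    """A candidate training set: a protein set around the seed + its records."""

    label: str
    proteins: frozenset[str]
    records: list[ActivityRecord] = field(default_factory=list)
    cv_r2: float | None = None
    cv_rmse: float | None = None
    evaluable: bool = True

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FeatureConfig:
    """Descriptor configuration used when scoring candidate layers."""

    ecfp_bits: int = 1024
    ecfp_radius: int = 3
    physchem: bool = True
    protein_scale: bool = True
    acc_max_lag: int = 3


def _local_score(a: str, b: str) -> int:
    sa, sb = bseq.ProteinSequence(a), bseq.ProteinSequence(b)
    aln = balign.align_optimal(sa, sb, _BLOSUM62, gap_penalty=(-11, -1), local=True, max_number=1)[0]
    return int(aln.score)


def all_vs_all_scores(sequences: Mapping[str, str]) -> SimilarityMatrix:
    """All-versus-all Smith-Waterman scores (BLOSUM62, gap 11/1).

    Scores are symmetrized by taking the max of the two alignment orders;
    the diagonal holds each sequence's self-alignment score.
    """
    ids = tuple(sequences)
    if not ids:
        raise ValueError("no sequences")
    for pid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {pid!r}")
    n = len(ids)
    scores = np.zeros((n, n), dtype=float)
    for i in range(n):
        scores[i, i] = _local_score(sequences[ids[i]], sequences[ids[i]])
        for j in range(i + 1, n):
            s = max(
                _local_score(sequences[ids[i]], sequences[ids[j]]),
                _local_score(sequences[ids[j]], sequences[ids[i]]),
            )
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(ids=ids, scores=scores)


def build_network(matrix: SimilarityMatrix, threshold: float) -> nx.Graph:
    """Similarity network: undirected edge iff score >= threshold."""
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.scores[i, j] >= threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j], weight=float(matrix.scores[i, j]))
    return g


def seed_component(network: nx.Graph, seed: str) -> frozenset[str]:
    """Connected component of the network containing the seed protein."""
    if seed not in network:
        raise KeyError(f"seed {seed!r} not in network")
    return frozenset(nx.node_connected_component(network, seed))


def threshold_sweep(
    matrix: SimilarityMatrix,
    seed: str,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[tuple[float, frozenset[str]]]:
    """Seed component at each threshold; components grow as thresholds fall."""
    ts = list(thresholds)
    if any(b >= a for a, b in zip(ts, ts[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    return [(t, seed_component(build_network(matrix, t), seed)) for t in ts]


def _nj_tree_graph(sequences: Mapping[str, str]) -> tuple[nx.Graph, dict[str, object]]:
    """Neighbor-joining topology as an undirected graph over unique node ids."""
    ids = list(sequences)
    dist = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i):
            sa = bseq.ProteinSequence(sequences[ids[i]])
            sb = bseq.ProteinSequence(sequences[ids[j]])
            aln = balign.align_optimal(sa, sb, _BLOSUM62, gap_penalty=(-11, -1), max_number=1)[0]
            dist[i, j] = dist[j, i] = 1.0 - balign.get_sequence_identity(aln)
    dm = DistanceMatrix(names=ids, matrix=[list(dist[i, : i + 1]) for i in range(len(ids))])
    tree = DistanceTreeConstructor().nj(dm)

    g = nx.Graph()
    counter = [0]

    def node_id(clade):
        if clade.is_terminal():
            return ("leaf", clade.name)
        counter[0] += 1
        return ("internal", counter[0])

    def walk(clade, my_id):
        for child in clade.clades:
            cid = node_id(child)
            g.add_edge(my_id, cid)
            walk(child, cid)

    root_id = node_id(tree.root)
    g.add_node(root_id)
    walk(tree.root, root_id)
    return g, {pid: ("leaf", pid) for pid in ids}


def build_phylo_layers(sequences: Mapping[str, str], seed: str) -> list[frozenset[str]]:
    """Nested protein layers around the seed from a neighbor-joining tree.

    Pairwise fractional-identity distances (global alignment) feed a
    neighbor-joining tree; layer k collects the seed plus every leaf whose
    path from the seed leaf crosses at most k internal nodes in the
    unrooted topology. Consecutive identical layers are merged, so the
    result is a strictly growing chain ending at the full leaf set.
    """
    if seed not in sequences:
        raise KeyError(f"seed {seed!r} not among sequences")
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to build a tree")
    if len(sequences) == 2:
        return [frozenset({seed}), frozenset(sequences)]

    g, leaf_ids = _nj_tree_graph(sequences)
    hops = nx.single_source_shortest_path_length(g, leaf_ids[seed])
    # internal nodes crossed = path length minus the two leaf endpoints
    depth = {pid: hops[leaf_ids[pid]] - 1 for pid in sequences if pid != seed}
    layers: list[frozenset[str]] = [frozenset({seed})]
    for k in sorted(set(depth.values())):
        layer = frozenset({seed} | {pid for pid, d in depth.items() if d <= k})
        if layer != layers[-1]:
            layers.append(layer)
    return layers


def dedupe_layers(layers: Sequence[LayerDataset]) -> list[LayerDataset]:
    """Drop layers whose protein set duplicates an earlier layer."""
    seen: set[frozenset[str]] = set()
    out = []
    for layer in layers:
        if layer.proteins not in seen:
            seen.add(layer.proteins)
            out.append(layer)
    return out


def make_layer_datasets(
    layers: Sequence[tuple[str, frozenset[str]]],
    records: Sequence[ActivityRecord],
) -> list[LayerDataset]:
    """Restrict the curated records to each layer's protein set."""
    return [
        LayerDataset(label=label, proteins=proteins,
                     records=[r for r in records if r.target_id in proteins])
        for label, proteins in layers
    ]


def layer_feature_matrix(
    records: Sequence[ActivityRecord],
    sequences: Mapping[str, str],
    config: FeatureConfig = FeatureConfig(),
):
    """PCM design matrix + label vector for a set of activity records."""
    smiles = sorted({r.standardized_smiles for r in records})
    proteins = sorted({r.target_id for r in records})
    compound_blocks: dict[str, dict[str, np.ndarray]] = {
        f"ecfp{2 * config.ecfp_radius}_{config.ecfp_bits}": {
            s: ecfp_fingerprint(s, config.ecfp_radius, config.ecfp_bits) for s in smiles
        }
    }
    if config.physchem:
        compound_blocks["physchem"] = {s: physchem_block(s) for s in smiles}
    protein_blocks: dict[str, dict[str, np.ndarray]] = {}
    if config.protein_scale and proteins:
        width = max(len(sequences[p]) for p in proteins)
        aligned = [sequences[p].ljust(width, "-") for p in proteins]
        mats = residue_scale_encoding(aligned)
        protein_blocks["zscale_acc"] = {
            p: acc_transform(m, config.acc_max_lag) for p, m in zip(proteins, mats)
        }
    rows = [(r.standardized_smiles, r.target_id) for r in records]
    features = assemble_features(rows, compound_blocks, protein_blocks)
    labels = np.array([r.pchembl for r in records], dtype=float)
    return features, labels


def evaluate_layer(
    layer: LayerDataset,
    sequences: Mapping[str, str],
    config: FeatureConfig = FeatureConfig(),
    folds: int = 10,
    min_records: int = 20,
    seed: int = DEFAULT_SEED,
) -> LayerDataset:
    """Score a candidate layer with a fixed out-of-the-box random forest.

    The forest uses 100 trees, sqrt(D) features per split, minimum node
    size 1 and no depth limit; R2 and RMSE are computed on pooled
    out-of-fold predictions from seeded k-fold cross-validation. Layers
    below ``min_records`` are marked unevaluable rather than failing.
    """
    if layer.n_records < min_records:
        return replace(layer, cv_r2=None, cv_rmse=None, evaluable=False)
    features, labels = layer_feature_matrix(layer.records, sequences, config)
    model = RandomForestRegressor(
        n_estimators=100, max_features="sqrt", min_samples_leaf=1,
        max_depth=None, random_state=seed, n_jobs=1,
    )
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(model, features.values, labels, cv=cv)
    r2, rmse = compute_metrics(labels, pred)
    return replace(layer, cv_r2=r2, cv_rmse=rmse, evaluable=True)


def select_dataset(layers: Sequence[LayerDataset], r2_tolerance: float = 0.01) -> LayerDataset:
    """Pick the largest layer whose CV R2 is within tolerance of the best.

    Among layers with cv_r2 >= max(cv_r2) - r2_tolerance the one with the
    most records wins; ties break toward the earlier layer in the list.
    """
    evaluable = [l for l in layers if l.evaluable and l.cv_r2 is not None]
    if not evaluable:
        raise ValueError("no evaluable layers")
    best = max(l.cv_r2 for l in evaluable)
    candidates = [l for l in evaluable if l.cv_r2 >= best - r2_tolerance]
    order = {id(l): i for i, l in enumerate(layers)}
    return max(candidates, key=lambda l: (l.n_records, -order[id(l)]))
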