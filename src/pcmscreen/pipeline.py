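"""End-to-end glue: train a stacked model on a curated world and screen a deck."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import ActivityRecord, curate_dataset
from .descriptors import ecfp_fingerprint
from .modeling import ModelSpec, StackedModel, train_stacked
from .screening import (
    cluster_hits,
    novelty_filter,
    screen_library,
    select_representatives,
)
from .targets import FeatureConfig, layer_feature_matrix


def train_world_model(
    records: Sequence[ActivityRecord],
    sequences: Mapping[str, str],
    config: FeatureConfig = FeatureConfig(ecfp_bits=256),
    k: int = 5,
    seed: int = 12345,
) -> tuple[StackedModel, FeatureConfig]:
    """Stacked (RF + GB) -> PLS model over the standard feature blocks."""
    features, labels = layer_feature_matrix(records, sequences, config)
    base = [
        ModelSpec("random_forest", {"n_estimators": 100, "max_features": "sqrt"}),
        ModelSpec("gradient_boosting", {"n_estimators": 100, "max_depth": 5}),
    ]
    meta = ModelSpec("partial_least_squares", {"n_components": 2})
    model = train_stacked(base, meta, features.values, labels, k=k, seed=seed)
    return model, config


def make_featurizer(
    sequences: Mapping[str, str],
    seed_protein: str,
    config: FeatureConfig,
):
    """Compound SMILES -> PCM feature rows paired with the fixed seed target."""

    def featurize(smiles: Sequence[str]) -> np.ndarray:
        records = [
            ActivityRecord(standardized_smiles=s, target_id=seed_protein, pchembl=0.0)
            for s in smiles
        ]
        features, _ = layer_feature_matrix(records, sequences, config)
        return features.values

    return featurize


def screen_with_world(
    fixtures_dir: str | Path,
    library: str | Path,
    threshold: float = 7.0,
    min_cluster_size: int = 19,
    seed: int = 12345,
    seed_protein: str = "P_seed",
) -> pd.DataFrame:
    """Full screen from a make-fixtures directory: curate, train, filter, cluster."""
    fixtures = Path(fixtures_dir)
    from Bio import SeqIO

    sequences = {r.id: str(r.seq) for r in SeqIO.parse(fixtures / "targets.fa", "fasta")}
    records, _ = curate_dataset(pd.read_csv(fixtures / "activities.csv"), sequences)
    model, config = train_world_model(records, sequences, seed=seed)
    featurize = make_featurizer(sequences, seed_protein, config)
    hits, _stats = screen_library(model, library, featurize, threshold=threshold)
    training_fps = np.stack(
        [ecfp_fingerprint(s) for s in sorted({r.standardized_smiles for r in records})]
    )
    kept = novelty_filter(hits, training_fps)
    if kept:
        cluster_hits(kept, min_cluster_size=min_cluster_size)
        select_representatives(kept)
    return pd.DataFrame(
        {
            "smiles": [h.smiles for h in kept],
            "compound_id": [h.compound_id for h in kept],
            "predicted_pchembl": [h.predicted_pchembl for h in kept],
            "nearest_training_similarity": [h.nearest_training_similarity for h in kept],
            "cluster": [h.cluster_label for h in kept],
            "representative": [h.is_representative for h in kept],
        }
    )
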