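"""Similarity networks, phylogenetic layers, layer scoring, dataset selection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pcmscreen.curation import ActivityRecord
from pcmscreen.synthetic import generate_protein_family, make_seed_sequence
from pcmscreen.targets import (
    FeatureConfig,
    LayerDataset,
    SimilarityMatrix,
    all_vs_all_scores,
    build_network,
    build_phylo_layers,
    dedupe_layers,
    evaluate_layer,
    select_dataset,
    seed_component,
    threshold_sweep,
)

SEQS = {
    "seed": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
    "near": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVA",
    "far": "GWNDPLYTRENDWQAGGHHCCPMMVVLLIIFFA",
}


class TestAllVsAll:
    def test_symmetric_with_dominant_diagonal(self):
        m = all_vs_all_scores(SEQS)
        assert np.allclose(m.scores, m.scores.T)
        for i in range(3):
            assert m.scores[i, i] >= m.scores[i].max()

    def test_identical_sequences_score_as_self(self):
        m = all_vs_all_scores({"a": SEQS["seed"], "b": SEQS["seed"]})
        assert m.scores[0, 1] == m.scores[0, 0]

    def test_unrelated_sequences_score_low(self):
        m = all_vs_all_scores(SEQS)
        ids = list(m.ids)
        related = m.scores[ids.index("seed"), ids.index("near")]
        unrelated = m.scores[ids.index("seed"), ids.index("far")]
        assert unrelated < related < m.scores[ids.index("seed"), ids.index("seed")]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            all_vs_all_scores({"a": ""})


def _matrix(ids, score_map, diag=100.0):
    n = len(ids)
    scores = np.zeros((n, n))
    np.fill_diagonal(scores, diag)
    for (a, b), s in score_map.items():
        scores[ids.index(a), ids.index(b)] = scores[ids.index(b), ids.index(a)] = s
    return SimilarityMatrix(ids=tuple(ids), scores=scores)


class TestNetwork:
    def setup_method(self):
        self.m = _matrix(["s", "a", "b"], {("s", "a"): 50, ("a", "b"): 30, ("s", "b"): 10})

    def test_threshold_extremes(self):
        assert build_network(self.m, 60).number_of_edges() == 0
        assert build_network(self.m, 0).number_of_edges() == 3

    def test_edge_monotonicity(self):
        for t1, t2 in [(0, 20), (20, 40), (40, 60)]:
            e1 = set(map(frozenset, build_network(self.m, t1).edges))
            e2 = set(map(frozenset, build_network(self.m, t2).edges))
            assert e2 <= e1

    def test_seed_component_examples(self):
        g = build_network(self.m, 45)  # only s-a survives
        assert seed_component(g, "s") == {"s", "a"}
        g = build_network(self.m, 25)  # path s-a-b
        assert seed_component(g, "s") == {"s", "a", "b"}
        with pytest.raises(KeyError):
            seed_component(g, "missing")

    def test_sweep_nested(self):
        sweep = threshold_sweep(self.m, "s", [45, 25, 5])
        sets = [s for _, s in sweep]
        assert sets[0] <= sets[1] <= sets[2]
        assert all("s" in s for s in sets)
        with pytest.raises(ValueError):
            threshold_sweep(self.m, "s", [25, 45])


class TestSeedComponentOracle:
    def test_matches_reachability_on_small_graphs(self, rng):
        """DFS-reachability oracle agreement on random graphs up to 8 nodes."""
        for _ in range(60):
            n = int(rng.integers(2, 9))
            ids = [f"n{i}" for i in range(n)]
            scores = np.zeros((n, n))
            np.fill_diagonal(scores, 10)
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.3:
                    scores[i, j] = scores[j, i] = 5
            m = SimilarityMatrix(tuple(ids), scores)
            g = build_network(m, 1)
            seed = ids[int(rng.integers(n))]
            # brute force: iterative DFS over the edge list
            stack, seen = [seed], {seed}
            while stack:
                u = stack.pop()
                for v in g.neighbors(u):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            assert seed_component(g, seed) == seen


class TestPhyloLayers:
    def test_ladder_family_gives_nested_chain(self):
        # mutation count increases leaf by leaf -> ladder-like tree
        base = make_seed_sequence(80, seed=5)
        seqs, _ = generate_protein_family(
            base, tier_sizes=(1, 1, 1, 1), tier_rates=(0.05, 0.15, 0.3, 0.5), seed=5
        )
        layers = build_phylo_layers(seqs, "P_seed")
        assert layers[0] == {"P_seed"}
        assert layers[-1] == set(seqs)
        for a, b in zip(layers, layers[1:]):
            assert a < b

    def test_star_family_one_nontrivial_layer(self):
        # all leaves equidistant mutants -> single internal structure
        base = make_seed_sequence(60, seed=9)
        seqs = {"P_seed": base}
        rng = np.random.default_rng(9)
        from pcmscreen.descriptors import AMINO_ACIDS

        for i in range(4):  # independent single-point mutants of the seed
            pos = int(rng.integers(len(base)))
            repl = rng.choice([a for a in AMINO_ACIDS if a != base[pos]])
            seqs[f"m{i}"] = base[:pos] + repl + base[pos + 1 :]
        layers = build_phylo_layers(seqs, "P_seed")
        assert layers[0] == {"P_seed"}
        assert layers[-1] == set(seqs)

    def test_two_sequences(self):
        layers = build_phylo_layers({"s": SEQS["seed"], "n": SEQS["near"]}, "s")
        assert layers == [frozenset({"s"}), frozenset({"s", "n"})]

    def test_seed_must_be_present(self):
        with pytest.raises(KeyError):
            build_phylo_layers(SEQS, "nope")

    def test_world_layers_recover_tiers(self, small_world):
        """The nested chain contains the exact planted mid-family layer."""
        layers = build_phylo_layers(small_world.sequences, "P_seed")
        mid = frozenset(p for p, t in small_world.tiers.items() if t <= 2)
        assert mid in layers
        assert layers[-1] == set(small_world.sequences)


def _linear_layer(n=120, seed=0, shuffle_labels=False):
    """Records whose labels are a linear readout of fingerprint bits."""
    from pcmscreen.synthetic import generate_compound_library
    from pcmscreen.descriptors import ecfp_fingerprint

    rng = np.random.default_rng(seed)
    compounds = sorted(set(generate_compound_library(600, seed=seed)))[:n]
    # sparse readout: a handful of informative bits, tree-recoverable
    w = np.zeros(128)
    w[rng.choice(128, size=6, replace=False)] = rng.normal(size=6)
    labels = []
    for s in compounds:
        bits = ecfp_fingerprint(s, radius=2, n_bits=128).astype(float)
        labels.append(6.0 + float(w @ bits))
    labels = np.array(labels)
    if shuffle_labels:
        rng.shuffle(labels)
    records = [
        ActivityRecord(standardized_smiles=s, target_id="P", pchembl=float(v))
        for s, v in zip(compounds, labels)
    ]
    return LayerDataset(label="L", proteins=frozenset({"P"}), records=records)


class TestEvaluateLayer:
    CFG = FeatureConfig(ecfp_bits=128, ecfp_radius=2, physchem=False, protein_scale=False)

    def test_noiseless_linear_signal_recovered(self):
        layer = evaluate_layer(_linear_layer(), sequences={}, config=self.CFG)
        assert layer.cv_r2 >= 0.9

    def test_pure_noise_scores_near_zero(self):
        layer = evaluate_layer(_linear_layer(shuffle_labels=True), sequences={}, config=self.CFG)
        assert layer.cv_r2 <= 0.1

    def test_small_layer_marked_unevaluable(self):
        small = _linear_layer(n=10)
        out = evaluate_layer(small, sequences={}, config=self.CFG)
        assert not out.evaluable and out.cv_r2 is None


class TestSelectDataset:
    def _layer(self, label, r2, n):
        records = [
            ActivityRecord(standardized_smiles=f"C{'C' * i}", target_id="P", pchembl=6.0)
            for i in range(n)
        ]
        return LayerDataset(label=label, proteins=frozenset({"P"}), records=records,
                            cv_r2=r2, cv_rmse=0.5)

    def test_dominant_layer_wins(self):
        layers = [self._layer("a", 0.9, 10), self._layer("b", 0.5, 100)]
        assert select_dataset(layers, r2_tolerance=0.01).label == "a"

    def test_comparable_scores_prefer_more_data(self):
        # 0.72 vs 0.71 at tolerance 0.01: the 20k-record layer is chosen
        layers = [self._layer("small", 0.72, 50), self._layer("large", 0.71, 200)]
        assert select_dataset(layers, r2_tolerance=0.01).label == "large"

    def test_zero_tolerance_is_strict_argmax(self):
        layers = [self._layer("a", 0.72, 50), self._layer("b", 0.71, 200)]
        assert select_dataset(layers, r2_tolerance=0.0).label == "a"

    def test_no_evaluable_layers(self):
        layer = self._layer("a", None, 5)
        layer.evaluable = False
        with pytest.raises(ValueError):
            select_dataset([layer])


def test_dedupe_layers_keeps_first():
    a = LayerDataset("SN850", frozenset({"s", "x"}))
    b = LayerDataset("layer2", frozenset({"s", "x"}))
    c = LayerDataset("layer3", frozenset({"s", "x", "y"}))
    assert [l.label for l in dedupe_layers([a, b, c])] == ["SN850", "layer3"]
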