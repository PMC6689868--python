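import numpy as np
import pytest

from hergml.chemio import Call, MoleculeRecord, mol_from_record
from hergml.features import enumerate_atom_pairs
from hergml.sohn import (
    Hypothesis,
    SohnConfig,
    SohnModel,
    applicable_hypotheses,
    build_network,
    local_knn_predict,
    select_hypotheses,
    sohn_confidence,
)
from hergml.synthetic import (
    SimulationConfig,
    generate_dataset,
    motif_signature_features,
    with_seed,
)
from tests.conftest import SINGLE_MOTIF


def rec(rid, smiles, call):
    return MoleculeRecord(id=rid, smiles=smiles, call=call)


AMINE_ACTIVES = [
    rec(f"a{i}", s, Call.ACTIVE)
    for i, s in enumerate(
        ["c1ccccc1CCN(C)C", "Cc1ccccc1CCN(C)C", "CCc1ccccc1CCN(C)C", "c1ccncc1CCN(C)C"]
    )
]
PLAIN_INACTIVES = [
    rec(f"i{i}", s, Call.INACTIVE)
    for i, s in enumerate(["c1ccccc1CC", "Cc1ccccc1C", "CCc1ccccc1", "c1ccncc1CC"])
]


class TestHypothesisSelection:
    def test_perfectly_separating_feature_selected_at_root(self):
        hyps = select_hypotheses(AMINE_ACTIVES + PLAIN_INACTIVES, min_support=3)
        assert hyps
        root = min(hyps, key=lambda h: h.depth)
        assert root.depth == 0
        signature = {f.code for f in motif_signature_features(SINGLE_MOTIF)}
        assert set(root.feature_codes) & signature
        assert root.support == frozenset(range(4)) or len(root.support) == 4

    def test_single_class_dataset_yields_no_hypotheses(self):
        actives = [rec(r.id, r.smiles, Call.ACTIVE) for r in AMINE_ACTIVES + PLAIN_INACTIVES]
        assert select_hypotheses(actives, min_support=2) == []

    def test_min_support_above_n_yields_no_hypotheses(self):
        records = AMINE_ACTIVES + PLAIN_INACTIVES
        assert select_hypotheses(records, min_support=len(records) + 1) == []

    def test_supports_contain_only_records_with_the_feature(self):
        records = AMINE_ACTIVES + PLAIN_INACTIVES
        model = SohnModel(SohnConfig(min_support=3, k=3)).fit(records)
        for hyp in model.hypotheses:
            for idx in hyp.support:
                present = {f.code for f in enumerate_atom_pairs(mol_from_record(model.records[idx]))}
                assert set(hyp.feature_codes) & present

    def test_root_split_matches_exhaustive_information_gain_scan(self):
        """The recursive partitioner's root feature equals the argmax of an
        independent exhaustive gain scan on small generated datasets."""
        from tests.oracles import oracle_root_split

        for seed in range(3):
            cfg = SimulationConfig(n_public=10, n_private_train=40, n_private_test=10)
            records = generate_dataset(with_seed(cfg, seed)).private_train
            model = SohnModel(SohnConfig(min_support=5, k=3, seed=seed)).fit(records)
            gmax, argmax_codes = oracle_root_split(model.records, 5)
            roots = [h for h in model.hypotheses if h.depth == 0]
            if gmax is None:
                assert not roots
                continue
            (root,) = roots
            assert root.gain == pytest.approx(gmax, abs=1e-9)
            assert set(root.feature_codes) & argmax_codes


class TestNetwork:
    def h(self, codes, support, gain=0.5):
        return Hypothesis(feature_codes=tuple(codes), support=frozenset(support), gain=gain)

    def test_disjoint_supports_give_two_roots(self):
        net = build_network([self.h(["X"], {0, 1}), self.h(["Y"], {2, 3})])
        assert len(net.nodes) == 2
        assert net.children == {}

    def test_strict_inclusion_gives_edge(self):
        net = build_network([self.h(["X"], {0, 1, 2}), self.h(["Y"], {0, 1})])
        parent = next(i for i, n in enumerate(net.nodes) if n.feature_codes == ("X",))
        child = next(i for i, n in enumerate(net.nodes) if n.feature_codes == ("Y",))
        assert net.children == {parent: (child,)}
        net.validate()

    def test_chain_has_no_transitive_shortcut(self):
        net = build_network(
            [self.h(["X"], {0, 1, 2, 3}), self.h(["Y"], {0, 1, 2}), self.h(["Z"], {0, 1})]
        )
        edges = {(i, j) for i, kids in net.children.items() for j in kids}
        assert len(edges) == 2  # X->Y and Y->Z only

    def test_equal_supports_merge_into_one_node(self):
        net = build_network([self.h(["X"], {0, 1}, 0.4), self.h(["Y"], {0, 1}, 0.6)])
        (node,) = net.nodes
        assert node.feature_codes == ("X", "Y")
        assert node.gain == 0.6

    def test_matches_networkx_transitive_reduction(self):
        networkx = pytest.importorskip("networkx")
        rng = np.random.default_rng(7)
        for _ in range(20):
            supports = {
                frozenset(np.flatnonzero(rng.random(8) < 0.5).tolist()) for _ in range(6)
            }
            supports = [s for s in supports if s]
            hyps = [self.h([f"F{i}"], s) for i, s in enumerate(supports)]
            net = build_network(hyps)
            dag = networkx.DiGraph()
            dag.add_nodes_from(range(len(net.nodes)))
            for i, a in enumerate(net.nodes):
                for j, b in enumerate(net.nodes):
                    if b.support < a.support:
                        dag.add_edge(i, j)
            expected = set(networkx.transitive_reduction(dag).edges())
            got = {(i, j) for i, kids in net.children.items() for j in kids}
            assert got == expected


class TestApplicability:
    def network(self):
        return build_network(
            [
                Hypothesis(("X",), frozenset({0, 1, 2}), 0.5),
                Hypothesis(("Y",), frozenset({0, 1}), 0.6),
                Hypothesis(("Z",), frozenset({4, 5}), 0.4),
            ]
        )

    def test_query_without_features_matches_nothing(self):
        assert applicable_hypotheses(self.network(), {"Q"}) == []

    def test_child_shadows_matching_parent(self):
        hits = applicable_hypotheses(self.network(), {"X", "Y"})
        assert [h.feature_codes for h in hits] == [("Y",)]

    def test_incomparable_nodes_both_apply(self):
        hits = applicable_hypotheses(self.network(), {"X", "Z"})
        assert {h.feature_codes for h in hits} == {("X",), ("Z",)}


class TestConfidence:
    def test_exact_match_override(self):
        assert sohn_confidence([1.0, 0.2], [Call.ACTIVE, Call.INACTIVE], Call.ACTIVE) == 1.0

    def test_unanimity_override(self):
        assert sohn_confidence([0.4, 0.4], [Call.ACTIVE, Call.ACTIVE], Call.ACTIVE) == 1.0

    def test_interior_value_is_mean_similarity_times_agreement(self):
        value = sohn_confidence(
            [0.8, 0.8, 0.8], [Call.ACTIVE, Call.ACTIVE, Call.INACTIVE], Call.ACTIVE
        )
        assert value == pytest.approx(0.8 * 2 / 3)

    def test_monotone_in_similarity_and_agreement(self):
        low = sohn_confidence([0.3, 0.3, 0.3], [Call.ACTIVE] * 2 + [Call.INACTIVE], Call.ACTIVE)
        higher_sim = sohn_confidence(
            [0.5, 0.5, 0.5], [Call.ACTIVE] * 2 + [Call.INACTIVE], Call.ACTIVE
        )
        assert higher_sim >= low


class TestPrediction:
    def fit(self, records, **kwargs):
        defaults = dict(min_support=3, k=3, max_depth=4, seed=0)
        defaults.update(kwargs)
        return SohnModel(SohnConfig(**defaults)).fit(records)

    def test_exact_training_match_has_confidence_one(self):
        model = self.fit(AMINE_ACTIVES + PLAIN_INACTIVES)
        pred = model.predict_record(AMINE_ACTIVES[0])
        assert pred.call is Call.ACTIVE
        assert pred.confidence == 1.0

    def test_local_knn_functional_surface(self):
        model = self.fit(AMINE_ACTIVES + PLAIN_INACTIVES)
        root = min(model.hypotheses, key=lambda h: h.depth)
        call, conf = local_knn_predict(
            root, mol_from_record(AMINE_ACTIVES[1]), k=3, train=model.records
        )
        assert call is Call.ACTIVE
        assert conf == 1.0

    def test_conflicting_unanimous_hypotheses_resolve_to_active(self):
        # active iff the amine motif is present; a second, disjoint motif
        # (phenylthioether) marks a unanimously inactive support
        thio_inactives = [
            rec(f"t{i}", s, Call.INACTIVE)
            for i, s in enumerate(["CCSC1CCCCC1", "CCSC1CCCC1", "CCSC1CCCCCC1", "CCSC1CCNCC1"])
        ]
        model = self.fit(AMINE_ACTIVES + PLAIN_INACTIVES + thio_inactives)
        query = rec("q", "CCSC1CCC(CCN(C)C)CC1", None)
        pred = model.predict_record(query)
        assert pred.call is Call.ACTIVE

    def test_out_of_domain_falls_back_to_global_knn_with_flag(self):
        model = self.fit(AMINE_ACTIVES + PLAIN_INACTIVES)
        pred = model.predict_record(rec("q", "FC(F)(F)F", None))
        assert "out_of_domain" in pred.provenance
        assert 0.0 <= pred.confidence <= 1.0

    def test_training_is_order_invariant_and_deterministic(self):
        records = AMINE_ACTIVES + PLAIN_INACTIVES
        probe = [rec("p1", "c1ccccc1CCCN(C)C", None), rec("p2", "CCCCO", None)]
        model_a = self.fit(records)
        model_b = self.fit(records[::-1])
        assert [h.feature_codes for h in model_a.hypotheses] == [
            h.feature_codes for h in model_b.hypotheses
        ]
        preds_a = [(p.call, p.confidence) for p in model_a.predict(probe)]
        preds_b = [(p.call, p.confidence) for p in model_b.predict(probe)]
        assert preds_a == preds_b

    def test_untrained_model_raises_state_error(self):
        with pytest.raises(RuntimeError):
            SohnModel().predict_record(rec("q", "CCO", None))

    def test_network_invariant_holds_after_fit(self, small_dataset):
        model = SohnModel(SohnConfig(seed=0)).fit(small_dataset.private_train)
        model.network.validate()
        for i, kids in model.network.children.items():
            for j in kids:
                assert model.network.nodes[j].support < model.network.nodes[i].support

    def test_persistence_round_trip(self, tmp_path, small_dataset):
        model = SohnModel(SohnConfig(seed=1)).fit(small_dataset.private_train[:60])
        path = tmp_path / "sohn.joblib"
        model.save(path)
        loaded = SohnModel.load(path)
        probe = small_dataset.private_test[:10]
        assert [(p.call, p.confidence) for p in model.predict(probe)] == [
            (p.call, p.confidence) for p in loaded.predict(probe)
        ]
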