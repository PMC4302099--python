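from __future__ import annotations

import numpy as np
import pytest
import sklearn.metrics

from conftest import sk
from oracles import auc_by_rank_statistic, random_network
from phenogo.evaluate import (
    Prediction,
    apply_rules,
    load_obo,
    ppv_by_cutoff,
    read_labels_tsv,
    read_predictions,
    roc_for_simple_rules,
    roc_from_scores,
    rule_fires,
    term_depth,
    write_predictions,
)
from phenogo.mining import RuleKind, make_rule
from phenogo.network import AnnotationNetwork, StudyKey, permute_go_columns


def _test_net(mp_index, gene_of=None, universe=None):
    return AnnotationNetwork.from_sets(
        mp_index, {}, universe=universe, gene_of=gene_of, mode="test"
    )


PLUS_RULE = make_rule(
    RuleKind.PLUS, ("MP:0002766", "MP:0004252"), "GO:0007368", support=5, rule_id="plus-21"
)
MINUS_RULE = make_rule(
    RuleKind.MINUS, ("MP:0000001", "MP:0000002"), "GO:0000001", support=3, rule_id="minus-0"
)


def _scored(rule, p):
    from dataclasses import replace

    return replace(rule, p_value=p, log10_p=float(np.log10(p)))


class TestRuleFiring:
    def test_heart_looping_example(self):
        # the worked prediction: both looping/situs-inversus phenotypes
        # present fires the determination-of-left/right-symmetry rule
        terms = frozenset({"MP:0004252", "MP:0002766"})
        assert rule_fires(PLUS_RULE, terms)
        assert not rule_fires(PLUS_RULE, frozenset({"MP:0004252"}))

    def test_minus_rule_fires_only_without_negated_term(self):
        assert rule_fires(MINUS_RULE, frozenset({"MP:0000001"}))
        assert not rule_fires(MINUS_RULE, frozenset({"MP:0000001", "MP:0000002"}))

    def test_disjunctive_semantics(self):
        pp = make_rule(
            RuleKind.PLUS_PLUS, ("MP:0000001", "MP:0000002", "MP:0000003"), "GO:0000001"
        )
        mm = make_rule(
            RuleKind.MINUS_MINUS, ("MP:0000001", "MP:0000002", "MP:0000003"), "GO:0000001"
        )
        assert rule_fires(pp, frozenset({"MP:0000001", "MP:0000003"}))
        assert not rule_fires(pp, frozenset({"MP:0000001"}))
        assert rule_fires(mm, frozenset({"MP:0000001"}))
        assert not rule_fires(mm, frozenset({"MP:0000001", "MP:0000002"}))


class TestApplyRules:
    def test_predictions_carry_provenance(self):
        net = _test_net(
            {"MP:0004252": {sk(1)}, "MP:0002766": {sk(1)}},
            gene_of={sk(1): {"MGI:106676"}},
        )
        (pred,) = apply_rules([_scored(PLUS_RULE, 1e-23)], net)
        assert pred.go_term == "GO:0007368"
        assert pred.gene == "MGI:106676"
        assert pred.rule_ids == ("plus-21",)
        assert set(pred.evidence_terms) == {"MP:0002766", "MP:0004252"}
        assert pred.prediction_id == "P000000"

    def test_duplicate_go_predictions_collapse_to_min_p(self):
        other = make_rule(
            RuleKind.MINUS, ("MP:0004252", "MP:0009999"), "GO:0007368", rule_id="minus-7"
        )
        net = _test_net({"MP:0004252": {sk(1)}, "MP:0002766": {sk(1)}})
        (pred,) = apply_rules([_scored(PLUS_RULE, 1e-23), _scored(other, 1e-4)], net)
        assert pred.p_value == 1e-23
        assert pred.rule_ids == ("minus-7", "plus-21")

    def test_ambiguous_genes_emit_one_prediction_each(self):
        net = _test_net(
            {"MP:0004252": {sk(1)}, "MP:0002766": {sk(1)}},
            gene_of={sk(1): {"MGI:1", "MGI:2"}},
        )
        preds = apply_rules([_scored(PLUS_RULE, 1e-23)], net)
        assert [p.gene for p in preds] == ["MGI:1", "MGI:2"]
        assert all(p.ambiguous_gene for p in preds)

    def test_requires_test_mode(self, toy_network):
        with pytest.raises(ValueError, match="test mode"):
            apply_rules([_scored(PLUS_RULE, 1e-23)], toy_network)

    def test_every_prediction_antecedent_reverifies(self):
        net = _test_net(
            {
                "MP:0004252": {sk(1), sk(2)},
                "MP:0002766": {sk(1)},
                "MP:0000001": {sk(2), sk(3)},
                "MP:0000002": {sk(3)},
            }
        )
        preds = apply_rules([_scored(PLUS_RULE, 1e-23), _scored(MINUS_RULE, 1e-5)], net)
        from phenogo.network import study_terms

        mp_of = study_terms(net, "mp")
        assert preds
        for pred in preds:
            fired = [
                r
                for r in (PLUS_RULE, MINUS_RULE)
                if r.go_term == pred.go_term and rule_fires(r, mp_of[pred.study])
            ]
            assert fired


class TestRocFromScores:
    def test_perfect_separation(self):
        roc = roc_from_scores([0.1, 0.2, 0.3, 0.4], [True, True, False, False])
        assert roc.auc == 1.0
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)

    def test_interleaved_hand_example(self):
        roc = roc_from_scores([0.1, 0.2, 0.3, 0.4], [True, False, True, False])
        assert roc.auc == 0.75

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(0)
        roc = roc_from_scores(rng.random(200), rng.random(200) < 0.3)
        fpr = [p[0] for p in roc.points]
        tpr = [p[1] for p in roc.points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_ties_processed_as_one_threshold_step(self):
        # one positive and one negative at the same score: half a win
        roc = roc_from_scores([0.5, 0.5], [True, False])
        assert roc.auc == 0.5

    def test_matches_sklearn_and_rank_statistic(self):
        rng = np.random.default_rng(42)
        scores = np.round(rng.random(500), 2)  # coarse grid forces ties
        labels = rng.random(500) < 0.4
        roc = roc_from_scores(scores, labels)
        assert roc.auc == pytest.approx(sklearn.metrics.roc_auc_score(labels, -scores))
        assert roc.auc == pytest.approx(auc_by_rank_statistic(scores, labels))

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            roc_from_scores([0.1, 0.2], [True, True])


class TestRocForSimpleRules:
    def test_planted_separation_gives_high_auc(self):
        # MP1 perfectly tracks GO1 across many studies; MP2 is noise
        keys = [sk(i) for i in range(12)]
        net = AnnotationNetwork.from_sets(
            {
                "MP:0000001": set(keys[:6]),
                "MP:0000002": {keys[0], keys[7], keys[8]},
            },
            {"GO:0000001": set(keys[:6]), "GO:0000002": set(keys[6:])},
            universe=keys,
        )
        roc = roc_for_simple_rules(net, direction="mp_to_go")
        assert roc.auc > 0.8

    def test_both_directions_computable(self):
        net = random_network(np.random.default_rng(1), max_studies=15)
        a = roc_for_simple_rules(net, direction="mp_to_go")
        b = roc_for_simple_rules(net, direction="go_to_mp")
        assert 0 <= a.auc <= 1 and 0 <= b.auc <= 1

    def test_invariant_to_studykey_relabeling(self):
        net = random_network(np.random.default_rng(7), max_studies=12)
        relabel = {
            k: StudyKey(pmid=f"z{i}", allele_id="b") for i, k in enumerate(net.universe)
        }
        renamed = AnnotationNetwork.from_sets(
            {t: {relabel[k] for k in v} for t, v in net.mp_index.items()},
            {t: {relabel[k] for k in v} for t, v in net.go_index.items()},
            universe=list(relabel.values()),
        )
        assert roc_for_simple_rules(net).auc == pytest.approx(
            roc_for_simple_rules(renamed).auc
        )

    def test_permuting_go_columns_destroys_signal(self):
        keys = [sk(i) for i in range(30)]
        net = AnnotationNetwork.from_sets(
            {
                "MP:0000001": set(keys[:10]),
                "MP:0000002": set(keys[10:20]),
                "MP:0000003": set(keys[20:]),
            },
            {
                "GO:0000001": set(keys[:10]),
                "GO:0000002": set(keys[10:20]),
                "GO:0000003": set(keys[20:]),
            },
            universe=keys,
        )
        original = roc_for_simple_rules(net).auc
        rng = np.random.default_rng(2)
        permuted = roc_for_simple_rules(permute_go_columns(net, rng)).auc
        assert original == 1.0
        assert permuted < original


class TestPpv:
    def _preds(self, n=20):
        return [
            Prediction(
                study=sk(i),
                gene="",
                go_term="GO:0000001",
                rule_ids=("plus-0",),
                p_value=10.0 ** -(n - i),
                log10_p=-(n - i),
                evidence_terms=(),
                prediction_id=f"P{i:06d}",
            )
            for i in range(n)
        ]

    def test_sixteen_of_twenty_reviewed(self):
        preds = self._preds(20)
        labels = {p.prediction_id: i < 16 for i, p in enumerate(preds)}
        ((_, ppv),) = ppv_by_cutoff(preds, labels, [1.0])
        assert ppv == pytest.approx(0.80)

    def test_all_true_gives_one_at_any_achievable_cutoff(self):
        preds = self._preds(5)
        labels = {p.prediction_id: True for p in preds}
        for _, ppv in ppv_by_cutoff(preds, labels, [1e-5, 1e-2, 1.0]):
            assert ppv == 1.0

    def test_empty_cutoff_reports_missing(self):
        preds = self._preds(3)
        labels = {p.prediction_id: True for p in preds}
        ((_, ppv),) = ppv_by_cutoff(preds, labels, [1e-30])
        assert ppv is None

    def test_unlabeled_prediction_is_an_error(self):
        preds = self._preds(2)
        with pytest.raises(KeyError):
            ppv_by_cutoff(preds, {}, [1.0])


class TestTermDepth:
    def test_diamond_depths(self, tiny_obo):
        dag = load_obo(tiny_obo)
        assert term_depth(dag, "GO:0000001") == 0
        assert term_depth(dag, "GO:0000002") == 1
        assert term_depth(dag, "GO:0000004") == 1  # direct root edge wins under BFS
        assert term_depth(dag, "GO:0000004", method="longest") == 2

    def test_absent_term_raises(self, tiny_obo):
        with pytest.raises(KeyError):
            term_depth(load_obo(tiny_obo), "GO:9999999")


class TestPredictionsRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        net = _test_net(
            {"MP:0004252": {sk(1)}, "MP:0002766": {sk(1)}},
            gene_of={sk(1): {"MGI:106676"}},
        )
        preds = apply_rules([_scored(PLUS_RULE, 1e-23)], net)
        path = tmp_path / "predictions.tsv"
        write_predictions(preds, path, header_lines=["round trip"])
        assert read_predictions(path) == preds

    def test_labels_tsv_parsing(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("prediction_id\tvalid\nP000000\tyes\nP000001\tno\n")
        assert read_labels_tsv(path) == {"P000000": True, "P000001": False}
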