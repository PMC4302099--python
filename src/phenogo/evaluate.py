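"""Applying rules to MP-only corpora and evaluating the results.

``apply_rules`` turns mined rules plus a test-mode network into GO
annotation suggestions.  ``roc_for_simple_rules`` validates the
p-value as a confidence score by ranking every (study, antecedent,
consequent) instance and sweeping thresholds (computed by
resubstitution on the training network, in either prediction
direction).  ``ppv_by_cutoff`` replays a reviewed prediction set at a
grid of p-value cutoffs.  ``term_depth`` gives the is_a depth of a
term in an OBO ontology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

from .mining import Rule, RuleKind
from .network import AnnotationNetwork, StudyKey, study_terms
from .stats import binomial_tail, log10_fraction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Prediction:
    """One suggested (study, gene, GO term) annotation with rule provenance."""

    study: StudyKey
    gene: str
    go_term: str
    rule_ids: tuple[str, ...]
    p_value: float
    log10_p: float
    evidence_terms: tuple[str, ...]
    ambiguous_gene: bool = False
    prediction_id: str = field(default="", compare=False)


@dataclass(frozen=True)
class RocResult:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), from (0,0) to (1,1)
    auc: float
    direction: str


def rule_fires(rule: Rule, mp_terms: frozenset[str]) -> bool:
    """Does the rule's antecedent hold for a study annotated to ``mp_terms``?"""
    if not set(rule.mp_positive) <= mp_terms:
        return False
    if set(rule.mp_negative) & mp_terms:
        return False
    if rule.kind is RuleKind.PLUS_PLUS:
        return bool(set(rule.mp_disjunctive) & mp_terms)
    if rule.kind is RuleKind.MINUS_MINUS:
        return not set(rule.mp_disjunctive) & mp_terms
    return True


def apply_rules(rules: Sequence[Rule], test_network: AnnotationNetwork) -> list[Prediction]:
    """Fire every rule against every MP-only StudyKey.

    Multiple rules predicting the same (study, GO term) collapse to one
    Prediction carrying the minimum p-value and all contributing rule
    ids.  Studies mapping to several genes emit one Prediction per
    gene, flagged ambiguous.
    """
    if test_network.mode != "test":
        raise ValueError("apply_rules expects a network built in test mode")
    mp_of = study_terms(test_network, "mp")
    best: dict[tuple[StudyKey, str], Rule] = {}
    contributors: dict[tuple[StudyKey, str], list[str]] = {}
    for key in test_network.universe:
        terms = mp_of[key]
        for rule in rules:
            if not rule_fires(rule, terms):
                continue
            slot = (key, rule.go_term)
            contributors.setdefault(slot, []).append(rule.rule_id)
            prev = best.get(slot)
            if prev is None or (rule.p_value, rule.rule_id) < (prev.p_value, prev.rule_id):
                best[slot] = rule

    predictions: list[Prediction] = []
    for slot in sorted(best, key=lambda s: (s[0], s[1])):
        key, go_term = slot
        rule = best[slot]
        terms = mp_of[key]
        evidence = tuple(
            t for t in rule.mp_positive + rule.mp_disjunctive if t in terms
        )
        genes = sorted(test_network.gene_of.get(key, frozenset()))
        ambiguous = len(genes) > 1
        for gene in genes or [""]:
            predictions.append(
                Prediction(
                    study=key,
                    gene=gene,
                    go_term=go_term,
                    rule_ids=tuple(sorted(set(contributors[slot]))),
                    p_value=rule.p_value,
                    log10_p=rule.log10_p,
                    evidence_terms=evidence,
                    ambiguous_gene=ambiguous,
                )
            )
    return [
        replace(pred, prediction_id=f"P{i:06d}") for i, pred in enumerate(predictions)
    ]


# ---------------------------------------------------------------------------
# ROC

def roc_from_scores(scores: Sequence[float], labels: Sequence[bool], direction: str = "") -> RocResult:
    """ROC over ranked instances where a *lower* score means a stronger call.

    Thresholds sweep the distinct score values (ties move as one step);
    AUC by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = int(labels.sum())
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("AUC undefined: labels are all-positive or all-negative")
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # step boundaries where the score value changes
    boundary = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([boundary, [s_sorted.size - 1]])
    tp = np.cumsum(l_sorted)[idx]
    fp = (idx + 1) - tp
    tpr = np.concatenate([[0.0], tp / pos, [1.0]])
    fpr = np.concatenate([[0.0], fp / neg, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    return RocResult(points=points, auc=auc, direction=direction)


def roc_for_simple_rules(network: AnnotationNetwork, direction: str = "mp_to_go") -> RocResult:
    """Resubstitution ROC of the simple-rule p-value on a training network.

    One instance per (StudyKey, antecedent term, consequent term) with
    the antecedent annotated; positive iff the consequent is annotated
    to the same StudyKey; scored by the pair's binomial-tail p-value
    (as log10 — a monotone transform that avoids underflow ties).
    In the reverse direction GO terms predict MP terms.
    """
    if direction == "mp_to_go":
        ant_index, cons_index = network.mp_index, network.go_index
        ant_of = study_terms(network, "mp")
    elif direction == "go_to_mp":
        ant_index, cons_index = network.go_index, network.mp_index
        ant_of = study_terms(network, "go")
    else:
        raise ValueError(f"unknown direction {direction!r}")

    n_univ = network.n
    cons_terms = sorted(cons_index)
    # pair score: tail(n=|PM(ant)|, j=|PM(ant) ∩ PM(cons)|); j=0 gives p=1
    score_of: dict[tuple[str, str], float] = {}
    for a, pm_a in ant_index.items():
        for c in cons_terms:
            j = len(pm_a & cons_index[c])
            score_of[(a, c)] = (
                0.0 if j == 0 else log10_fraction(binomial_tail(len(pm_a), j, n_univ))
            )

    scores: list[float] = []
    labels: list[bool] = []
    for key in network.universe:
        for a in sorted(ant_of[key]):
            for c in cons_terms:
                scores.append(score_of[(a, c)])
                labels.append(key in cons_index[c])
    return roc_from_scores(scores, labels, direction=direction)


# ---------------------------------------------------------------------------
# PPV

def ppv_by_cutoff(
    predictions: Sequence[Prediction],
    truth_labels: Mapping[str, bool],
    cutoffs: Sequence[float],
) -> list[tuple[float, float | None]]:
    """Positive predictive value TP/(TP+FP) at each p-value cutoff.

    Every prediction must be labeled (by prediction_id).  A cutoff that
    admits no prediction reports None, not 0.
    """
    labeled = []
    for pred in predictions:
        if pred.prediction_id not in truth_labels:
            raise KeyError(f"prediction {pred.prediction_id} has no truth label")
        labeled.append((pred.p_value, bool(truth_labels[pred.prediction_id])))
    out: list[tuple[float, float | None]] = []
    for cutoff in cutoffs:
        hits = [ok for p, ok in labeled if p <= cutoff]
        out.append((cutoff, sum(hits) / len(hits) if hits else None))
    return out


# ---------------------------------------------------------------------------
# ontology depth

def load_obo(path: str | Path) -> nx.MultiDiGraph:
    """Parse an OBO 1.2 file into a child→parent multigraph (obonet)."""
    return obonet.read_obo(path)


def term_depth(dag: nx.MultiDiGraph, term: str, *, method: str = "shortest") -> int:
    """is_a depth of ``term``: path length up to a root (a node with no is_a parent).

    ``method='shortest'`` (default) is BFS shortest-path depth;
    ``'longest'`` is the longest is_a chain.  Root depth is 0.
    """
    if term not in dag:
        raise KeyError(f"term {term!r} not in ontology")

    def parents(u: str) -> list[str]:
        return sorted(v for _, v, k in dag.out_edges(u, keys=True) if k == "is_a")

    if method == "shortest":
        frontier = [term]
        seen = {term}
        depth = 0
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                ps = parents(u)
                if not ps:
                    return depth
                for v in ps:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
            depth += 1
        raise ValueError(f"no is_a root reachable from {term!r} (cycle?)")
    if method == "longest":
        memo: dict[str, int] = {}
        on_stack: set[str] = set()

        def longest(u: str) -> int:
            if u in memo:
                return memo[u]
            if u in on_stack:
                raise ValueError(f"is_a cycle detected at {u!r}")
            on_stack.add(u)
            ps = parents(u)
            depth = 0 if not ps else 1 + max(longest(v) for v in ps)
            on_stack.discard(u)
            memo[u] = depth
            return depth

        return longest(term)
    raise ValueError(f"unknown depth method {method!r}")


def mean_go_depth(dag: nx.MultiDiGraph, rules: Iterable[Rule], *, method: str = "shortest") -> float:
    """Average consequent-term depth over a rule set (terms absent from the DAG are skipped)."""
    depths = [term_depth(dag, r.go_term, method=method) for r in rules if r.go_term in dag]
    if not depths:
        raise ValueError("no rule consequent found in the ontology")
    return float(np.mean(depths))


# ---------------------------------------------------------------------------
# predictions TSV

_PRED_HEADER = (
    "prediction_id",
    "pmid",
    "allele_id",
    "gene_id",
    "go_term",
    "rule_ids",
    "p_value",
    "log10_p",
    "evidence_mp_terms",
    "ambiguous_gene",
)


def write_predictions(
    predictions: Iterable[Prediction], path: str | Path, *, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_PRED_HEADER) + "\n")
        for p in predictions:
            fh.write(
                "\t".join(
                    (
                        p.prediction_id,
                        p.study.pmid,
                        p.study.allele_id,
                        p.gene,
                        p.go_term,
                        ";".join(p.rule_ids),
                        repr(p.p_value),
                        repr(p.log10_p),
                        ";".join(p.evidence_terms),
                        "yes" if p.ambiguous_gene else "no",
                    )
                )
                + "\n"
            )


def read_predictions(path: str | Path) -> list[Prediction]:
    out: list[Prediction] = []
    with open(path, newline="") as fh:
        header: list[str] | None = None
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if header is None:
                header = cols
                if tuple(header) != _PRED_HEADER:
                    raise ValueError(f"unexpected predictions header {header!r}")
                continue
            pid, pmid, allele, gene, go, rids, p, lg, ev, amb = cols
            out.append(
                Prediction(
                    study=StudyKey(pmid=pmid, allele_id=allele),
                    gene=gene,
                    go_term=go,
                    rule_ids=tuple(rids.split(";")) if rids else (),
                    p_value=float(p),
                    log10_p=float(lg),
                    evidence_terms=tuple(ev.split(";")) if ev else (),
                    ambiguous_gene=amb == "yes",
                    prediction_id=pid,
                )
            )
    return out


def read_labels_tsv(path: str | Path) -> dict[str, bool]:
    """Read a curator labels TSV: prediction_id <TAB> yes/no."""
    labels: dict[str, bool] = {}
    with open(path, newline="") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("prediction_id"):
                continue
            pid, verdict = line.rstrip("\n").split("\t")[:2]
            labels[pid] = verdict.strip().lower() in ("yes", "true", "1")
    return labels


def write_roc_tsv(result: RocResult, path: str | Path, *, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# direction={result.direction} auc={result.auc!r}\n")
        fh.write("fpr\ttpr\n")
        for fpr, tpr in result.points:
            fh.write(f"{fpr!r}\t{tpr!r}\n")


def write_ppv_tsv(
    rows: Iterable[tuple[float, float | None]], path: str | Path, *, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("cutoff\tppv\n")
        for cutoff, ppv in rows:
            fh.write(f"{cutoff!r}\t{'NA' if ppv is None else repr(ppv)}\n")
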