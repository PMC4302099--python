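"""Synthetic annotation corpora with planted MP↔GO structure.

The generative model mirrors the premise the mining method rests on: a
single underlying genetic perturbation (a latent *process*) manifests
as one biological-process GO annotation plus a correlated set of MP
phenotype annotations in the same study.  Each synthetic study draws
one latent process and emits the process's GO term and each of its
linked MP terms independently with ``emission_prob``; on top of that,
every (study, term) cell is flipped on with probability
``background_density`` — uncorrelated curation noise that sets the
graph density of the incidence network (the real co-curation network
this emulates has density on the order of 6e-4).

Rule instances can additionally be *planted* with exact guarantees: a
planted rule's set identity is enforced on the generated training
corpus by a repair pass, so miners must recover it.  A ``test_fraction``
of studies is emitted with GO annotations withheld (recorded in the
ground-truth ledger) to serve as the MP-only test corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .mining import RuleKind
from .records import AnnotationRecord, Aspect, Ontology

__all__ = ["PlantedRule", "SyntheticConfig", "generate_corpus", "corpus_summary"]


@dataclass(frozen=True)
class PlantedRule:
    """Spec for one rule instance injected with exact set-identity guarantees.

    ``mp_terms`` uses the pattern's positional order (conjuncts first,
    then negated/disjunctive terms), as 0-based indexes into the MP
    vocabulary; ``go_term`` indexes the GO vocabulary.
    """

    kind: RuleKind
    mp_terms: tuple[int, ...]
    go_term: int
    n_supporting_studies: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", RuleKind(self.kind))
        object.__setattr__(self, "mp_terms", tuple(self.mp_terms))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    Defaults are a desk-scale rendering of the co-curation corpus the
    method was built for: a sparse bipartite incidence structure
    (background density 6e-4) in which most signal comes from latent
    processes co-emitting one GO term and a handful of MP terms.
    """

    n_studies: int = 1000
    n_mp_terms: int = 400
    n_go_terms: int = 200
    n_processes: int = 80
    mp_per_process: int = 4
    emission_prob: float = 0.9
    background_density: float = 6e-4
    planted_rules: tuple[PlantedRule, ...] = ()
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("emission_prob", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in [0, 1)")
        for name in ("n_studies", "n_mp_terms", "n_go_terms", "mp_per_process"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_processes < 0:
            raise ValueError("n_processes must be >= 0")
        for spec in self.planted_rules:
            if spec.go_term >= self.n_go_terms or any(
                t >= self.n_mp_terms for t in spec.mp_terms
            ):
                raise ValueError(f"planted rule {spec} exceeds the vocabulary sizes")
            if spec.n_supporting_studies < 1:
                raise ValueError("planted rules need at least one supporting study")


def _mp_name(i: int) -> str:
    return f"MP:{i + 1:07d}"


def _go_name(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord], dict]:
    """Generate (training records, test records, ground-truth ledger).

    Fully deterministic given ``config.seed``.  The ledger records the
    planted rules with their supporting StudyKeys, the per-study latent
    process, and the withheld GO annotations of every test study.
    """
    rng = np.random.default_rng(config.seed)
    n, n_mp, n_go = config.n_studies, config.n_mp_terms, config.n_go_terms

    pmids = [f"7{i:07d}" for i in range(n)]
    alleles = [f"MGI:3{i:06d}" for i in range(n)]
    genes = [f"MGI:1{i:06d}" for i in range(n)]

    # membership matrices, rows = studies
    mp_mat = np.zeros((n, n_mp), dtype=bool)
    go_mat = np.zeros((n, n_go), dtype=bool)

    # latent processes: one GO term plus mp_per_process linked MP terms each
    processes: list[tuple[int, np.ndarray]] = []
    process_of = np.full(n, -1, dtype=int)
    if config.n_processes > 0:
        for p in range(config.n_processes):
            go_t = int(rng.integers(n_go))
            mp_ts = rng.choice(n_mp, size=min(config.mp_per_process, n_mp), replace=False)
            processes.append((go_t, mp_ts))
        process_of = rng.integers(config.n_processes, size=n)
        for i in range(n):
            go_t, mp_ts = processes[process_of[i]]
            if rng.random() < config.emission_prob:
                go_mat[i, go_t] = True
            mp_mat[i, mp_ts] |= rng.random(mp_ts.size) < config.emission_prob

    # uncorrelated background noise at the target cell density
    if config.background_density > 0:
        mp_mat |= rng.random((n, n_mp)) < config.background_density
        go_mat |= rng.random((n, n_go)) < config.background_density

    # train/test split (planted supports are drawn from the training side)
    n_test = int(round(config.test_fraction * n))
    test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    is_test = np.zeros(n, dtype=bool)
    is_test[test_idx] = True
    train_pool = [i for i in range(n) if not is_test[i]]

    # inject planted rules, supports sampled disjointly
    taken: set[int] = set()
    supports: list[frozenset[int]] = []
    planted_ledger: list[dict] = []
    for spec in config.planted_rules:
        avail = [i for i in train_pool if i not in taken]
        if len(avail) < spec.n_supporting_studies:
            raise ValueError("not enough training studies to support the planted rules")
        support = [int(i) for i in rng.choice(avail, size=spec.n_supporting_studies, replace=False)]
        taken.update(support)
        supports.append(frozenset(support))
        for pos, i in enumerate(support):
            _imprint(mp_mat[i], go_mat[i], spec, pos)
        planted_ledger.append(
            {
                "kind": spec.kind.value,
                "mp_terms": [_mp_name(t) for t in spec.mp_terms],
                "go_term": _go_name(spec.go_term),
                "support_studies": sorted(f"{pmids[i]}|{alleles[i]}" for i in support),
            }
        )

    # contrast rows: each planted rule also gets the false-positive /
    # near-miss studies that motivate its pattern (e.g. a study with the
    # minus rule's both MP terms and no GO term).  They guarantee every
    # planted term occurs in the corpus, keep the negated-term coverage
    # non-vacuous (no equal-p sibling rules), and are chosen so no
    # planted identity is disturbed.
    for spec in config.planted_rules:
        for set_terms, clear_terms in _contrast_rows(spec):
            eligible = [i for i in train_pool if i not in taken]
            pick = rng.choice(eligible, size=min(2, len(eligible)), replace=False)
            for i in pick:
                i = int(i)
                taken.add(i)
                mp_mat[i, list(set_terms)] = True
                mp_mat[i, list(clear_terms)] = False
                go_mat[i, spec.go_term] = False

    # repair pass: enforce each planted rule's set identity on the training
    # rows.  A rule's own supports are never modified for that rule, but
    # remain repairable for other rules (which touch disjoint terms when
    # the planted specs are term-disjoint, the supported configuration).
    for _ in range(10):
        changed = False
        for k, spec in enumerate(config.planted_rules):
            for i in train_pool:
                if i in supports[k]:
                    continue
                changed |= _repair_row(mp_mat[i], go_mat[i], spec)
        if not changed:
            break
    else:  # pragma: no cover - pathological planted-rule interactions
        raise ValueError("planted-rule repair did not converge; simplify the planted set")

    training: list[AnnotationRecord] = []
    test: list[AnnotationRecord] = []
    withheld_go: dict[str, list[str]] = {}
    for i in range(n):
        mp_terms = [_mp_name(t) for t in np.nonzero(mp_mat[i])[0]]
        go_terms = [_go_name(t) for t in np.nonzero(go_mat[i])[0]]
        common = dict(pmid=pmids[i], allele_id=alleles[i], gene_id=genes[i])
        mp_records = [
            AnnotationRecord(term_id=t, ontology=Ontology.MP, **common) for t in mp_terms
        ]
        go_records = [
            AnnotationRecord(
                term_id=t, ontology=Ontology.GO, evidence="IMP", aspect=Aspect.P, **common
            )
            for t in go_terms
        ]
        if is_test[i]:
            test.extend(mp_records)
            if go_terms:
                withheld_go[f"{pmids[i]}|{alleles[i]}"] = go_terms
        else:
            training.extend(mp_records)
            training.extend(go_records)

    ledger = {
        "config": _config_dict(config),
        "planted_rules": planted_ledger,
        "process_go": {str(p): _go_name(go_t) for p, (go_t, _) in enumerate(processes)},
        "process_of": {
            f"{pmids[i]}|{alleles[i]}": int(process_of[i]) for i in range(n) if process_of[i] >= 0
        },
        "test_studies": sorted(f"{pmids[i]}|{alleles[i]}" for i in np.nonzero(is_test)[0]),
        "withheld_go": {k: withheld_go[k] for k in sorted(withheld_go)},
        "gene_of": {f"{pmids[i]}|{alleles[i]}": genes[i] for i in range(n)},
    }
    return training, test, ledger


def _contrast_rows(spec: PlantedRule) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """(terms to set, terms to clear) per contrast-row template for a kind.

    Templates instantiate near-miss studies that stay outside the
    pattern's success set: a lone conjunct for plus-family patterns, a
    blocked antecedent (negated term present, GO absent) for
    minus-family patterns.
    """
    ts = spec.mp_terms
    if spec.kind is RuleKind.PLUS:
        return [((ts[0],), (ts[1],)), ((ts[1],), (ts[0],))]
    if spec.kind is RuleKind.MINUS:
        return [((ts[0], ts[1]), ())]
    if spec.kind is RuleKind.PLUS_PLUS:
        return [((ts[0],), (ts[1], ts[2])), ((ts[2],), (ts[0],))]
    if spec.kind is RuleKind.MINUS_MINUS:
        return [((ts[0], ts[1]), (ts[2],)), ((ts[0], ts[2]), (ts[1],))]
    return [((ts[0], ts[1], ts[2]), ())]  # plus-minus


def _imprint(mp_row: np.ndarray, go_row: np.ndarray, spec: PlantedRule, pos: int = 0) -> None:
    """Force one supporting study to instantiate the planted pattern."""
    kind, ts = spec.kind, spec.mp_terms
    go_row[spec.go_term] = True
    if kind is RuleKind.PLUS:
        mp_row[list(ts)] = True
    elif kind is RuleKind.MINUS:
        mp_row[ts[0]] = True
        mp_row[ts[1]] = False
    elif kind is RuleKind.PLUS_PLUS:
        mp_row[ts[0]] = True
        mp_row[ts[1 + pos % 2]] = True  # alternate the satisfied disjunct
    elif kind is RuleKind.MINUS_MINUS:
        mp_row[ts[0]] = True
        mp_row[ts[1]] = False
        mp_row[ts[2]] = False
    else:  # PLUS_MINUS
        mp_row[ts[0]] = True
        mp_row[ts[1]] = True
        mp_row[ts[2]] = False


def _repair_row(mp_row: np.ndarray, go_row: np.ndarray, spec: PlantedRule) -> bool:
    """Remove any violation of the planted rule's guarantees from one study row.

    Positive patterns: a study must not satisfy the antecedent without
    carrying the GO term (the antecedent is broken instead of the GO
    term granted, keeping supports the only antecedent carriers).
    Negative patterns additionally withdraw the GO term where a blocked
    antecedent co-occurs with it, mirroring the planted contrast.
    """
    kind, ts, go_t = spec.kind, spec.mp_terms, spec.go_term
    changed = False
    if kind is RuleKind.PLUS:
        if mp_row[ts[0]] and mp_row[ts[1]] and not go_row[go_t]:
            mp_row[ts[1]] = False
            changed = True
    elif kind is RuleKind.MINUS:
        if mp_row[ts[0]] and not mp_row[ts[1]] and not go_row[go_t]:
            mp_row[ts[1]] = True  # block the antecedent via the negated term
            changed = True
        if mp_row[ts[0]] and mp_row[ts[1]] and go_row[go_t]:
            go_row[go_t] = False
            changed = True
    elif kind is RuleKind.PLUS_PLUS:
        if mp_row[ts[0]] and (mp_row[ts[1]] or mp_row[ts[2]]) and not go_row[go_t]:
            mp_row[ts[1]] = False
            mp_row[ts[2]] = False
            changed = True
    elif kind is RuleKind.MINUS_MINUS:
        if mp_row[ts[0]] and not (mp_row[ts[1]] or mp_row[ts[2]]) and not go_row[go_t]:
            mp_row[ts[1]] = True
            changed = True
        if mp_row[ts[0]] and (mp_row[ts[1]] or mp_row[ts[2]]) and go_row[go_t]:
            go_row[go_t] = False
            changed = True
    else:  # PLUS_MINUS
        if mp_row[ts[0]] and mp_row[ts[1]] and not mp_row[ts[2]] and not go_row[go_t]:
            mp_row[ts[1]] = False
            changed = True
        if mp_row[ts[0]] and mp_row[ts[1]] and mp_row[ts[2]] and go_row[go_t]:
            go_row[go_t] = False
            changed = True
    return changed


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["planted_rules"] = [
        {**asdict(s), "kind": s.kind.value} for s in config.planted_rules
    ]
    return d


def corpus_summary(
    records: Sequence[AnnotationRecord],
    *,
    n_studies: int | None = None,
    n_terms: int | None = None,
) -> dict:
    """Scale diagnostics for a record stream.

    Density is incidences over (studies × terms); the matrix dimensions
    default to the studies and terms *observed* in the records, but the
    configured totals can be passed explicitly (rows or columns with no
    incidence are invisible in a record stream, which biases the
    observed-dimension density upward in sparse corpora).  Pair counts
    tally per-study MP-GO co-occurrences, total and deduplicated.
    """
    studies: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for rec in records:
        key = (rec.pmid, rec.allele_id)
        mp, go = studies.setdefault(key, (set(), set()))
        (mp if rec.ontology is Ontology.MP else go).add(rec.term_id)
    mp_terms: set[str] = set()
    go_terms: set[str] = set()
    incidences = 0
    total_pairs = 0
    unique_pairs: set[tuple[str, str]] = set()
    per_term_counts: dict[str, int] = {}
    for mp, go in studies.values():
        mp_terms |= mp
        go_terms |= go
        incidences += len(mp) + len(go)
        total_pairs += len(mp) * len(go)
        for m in mp:
            per_term_counts[m] = per_term_counts.get(m, 0) + 1
            for g in go:
                unique_pairs.add((m, g))
        for g in go:
            per_term_counts[g] = per_term_counts.get(g, 0) + 1
    if n_studies is None:
        n_studies = len(studies)
    if n_terms is None:
        n_terms = len(mp_terms) + len(go_terms)
    density = incidences / (n_studies * n_terms) if n_studies and n_terms else 0.0
    hist: dict[int, int] = {}
    for count in per_term_counts.values():
        hist[count] = hist.get(count, 0) + 1
    return {
        "n_studies": n_studies,
        "n_mp_terms": len(mp_terms),
        "n_go_terms": len(go_terms),
        "n_incidences": incidences,
        "density": density,
        "mp_go_pairs_total": total_pairs,
        "mp_go_pairs_unique": len(unique_pairs),
        "incidence_histogram": dict(sorted(hist.items())),
    }
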