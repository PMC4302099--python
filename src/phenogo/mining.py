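"""Mining of the five composite rule patterns.

Each pattern is an exact set-identity condition over PM(·) sets; all of
them reduce to "the pattern's success set S is contained in PM(GO)":

    plus         MP1 AND MP2 → GO            S = PM(MP1) ∩ PM(MP2)
    minus        MP1 AND NOT MP2 → GO        S = PM(MP1) \\ PM(MP2)
    plus-plus    MP1 AND (MP2 OR MP3) → GO   S = PM(MP1) ∩ (PM(MP2) ∪ PM(MP3))
    minus-minus  MP1 AND NOT (MP2 OR MP3)    S = PM(MP1) \\ (PM(MP2) ∪ PM(MP3))
    plus-minus   MP1 AND MP2 AND NOT MP3     S = (PM(MP1) ∩ PM(MP2)) \\ PM(MP3)

The search enumerates candidates through inverted indexes (only terms
that can change the relevant false-positive set are tried); the
exhaustiveness of that pruning relative to brute-force enumeration is a
tested property, not an assumption.

By default a degenerate-pattern guard is applied: a composite is only
sought where the underlying simple pair actually has false positives to
fix (see ``mine_rules``).  Disable it to reproduce the literal identity
conditions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from .network import AnnotationNetwork, StudyKey, shared_set, study_terms
from .stats import RuleScore, composite_pvalue, simple_rule_pvalue

logger = logging.getLogger(__name__)


class RuleKind(str, Enum):
    PLUS = "plus"
    MINUS = "minus"
    PLUS_PLUS = "plus_plus"
    MINUS_MINUS = "minus_minus"
    PLUS_MINUS = "plus_minus"


ALL_KINDS = tuple(RuleKind)

#: required (positive, negative, disjunctive) arity per kind
_ARITY = {
    RuleKind.PLUS: (2, 0, 0),
    RuleKind.MINUS: (1, 1, 0),
    RuleKind.PLUS_PLUS: (1, 0, 2),
    RuleKind.MINUS_MINUS: (1, 0, 2),
    RuleKind.PLUS_MINUS: (2, 1, 0),
}


@dataclass(frozen=True)
class Rule:
    """A mined, canonicalized rule instance.

    Symmetric positions (the two conjuncts of plus and plus-minus, the
    two disjuncts of plus-plus / minus-minus) are stored sorted, so
    equal rules compare equal.  ``score`` keeps full factor provenance
    and the exact rational p-value; ``p_value``/``log10_p`` are its
    float projections and survive TSV round-trips.
    """

    kind: RuleKind
    mp_positive: tuple[str, ...]
    mp_negative: tuple[str, ...]
    mp_disjunctive: tuple[str, ...]
    go_term: str
    support: int
    p_value: float
    log10_p: float
    rule_id: str = field(default="", compare=False)
    score: RuleScore | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        want = _ARITY[self.kind]
        have = (len(self.mp_positive), len(self.mp_negative), len(self.mp_disjunctive))
        if want != have:
            raise ValueError(f"{self.kind.value} rule has arity {have}, expected {want}")
        terms = self.mp_positive + self.mp_negative + self.mp_disjunctive
        if len(set(terms)) != len(terms):
            raise ValueError("MP terms of a rule must be pairwise distinct")

    @property
    def antecedent_terms(self) -> tuple[str, ...]:
        return self.mp_positive + self.mp_negative + self.mp_disjunctive

    @property
    def pattern_terms(self) -> tuple[str, ...]:
        """MP terms in the positional order check_pattern expects."""
        return self.mp_positive + self.mp_disjunctive + self.mp_negative

    def key(self) -> tuple:
        return (self.kind.value, self.mp_positive, self.mp_negative, self.mp_disjunctive, self.go_term)


def make_rule(
    kind: RuleKind,
    mp_terms: Sequence[str],
    go_term: str,
    *,
    support: int = 0,
    score: RuleScore | None = None,
    rule_id: str = "",
) -> Rule:
    """Build a canonical Rule from positionally-ordered MP terms.

    ``mp_terms`` follows the pattern order: conjuncts first, then the
    negated or disjunctive terms (minus: (MP1, MP2⁻); plus-minus:
    (MP1, MP2, MP3⁻); plus-plus / minus-minus: (MP1, MP2, MP3) with
    MP2, MP3 the union clause).
    """
    kind = RuleKind(kind)
    if kind is RuleKind.PLUS:
        pos, neg, dis = tuple(sorted(mp_terms)), (), ()
    elif kind is RuleKind.MINUS:
        pos, neg, dis = (mp_terms[0],), (mp_terms[1],), ()
    elif kind is RuleKind.PLUS_MINUS:
        pos, neg, dis = tuple(sorted(mp_terms[:2])), (mp_terms[2],), ()
    else:  # plus_plus / minus_minus
        pos, neg, dis = (mp_terms[0],), (), tuple(sorted(mp_terms[1:3]))
    p = score.p_float if score else float("nan")
    lg = score.log10_p if score else float("nan")
    return Rule(
        kind=kind,
        mp_positive=pos,
        mp_negative=neg,
        mp_disjunctive=dis,
        go_term=go_term,
        support=support,
        p_value=p,
        log10_p=lg,
        rule_id=rule_id,
        score=score,
    )


def check_pattern(
    kind: RuleKind | str,
    mp_terms: Sequence[str],
    go_term: str,
    network: AnnotationNetwork,
) -> tuple[bool, frozenset[StudyKey]]:
    """Evaluate a pattern's set identity literally; return (holds, success set S).

    Every identity is equivalent to S ⊆ PM(GO) for the kind's S.
    """
    kind = RuleKind(kind)
    if len(set(mp_terms)) != len(mp_terms):
        raise ValueError("MP terms must be pairwise distinct")
    pm = network.pm
    if kind is RuleKind.PLUS:
        a, b = mp_terms
        s = pm(a) & pm(b)
    elif kind is RuleKind.MINUS:
        a, b = mp_terms
        s = pm(a) - pm(b)
    elif kind is RuleKind.PLUS_PLUS:
        a, d1, d2 = mp_terms
        s = pm(a) & (pm(d1) | pm(d2))
    elif kind is RuleKind.MINUS_MINUS:
        a, d1, d2 = mp_terms
        s = pm(a) - (pm(d1) | pm(d2))
    else:
        a, b, c = mp_terms
        s = (pm(a) & pm(b)) - pm(c)
    return s <= pm(go_term), frozenset(s)


def find_simple_pairs(
    network: AnnotationNetwork,
) -> list[tuple[str, str, RuleScore]]:
    """Every co-annotated (MP, GO) pair, scored and sorted by ascending p-value.

    Ties break on (mp_term, go_term) lexical order for determinism.
    """
    mp_of = study_terms(network, "mp")
    go_of = study_terms(network, "go")
    pairs: set[tuple[str, str]] = set()
    for key in network.universe:
        for mp_term in mp_of[key]:
            for go_term in go_of[key]:
                pairs.add((mp_term, go_term))
    scored = [
        (mp_term, go_term, simple_rule_pvalue(mp_term, go_term, network))
        for mp_term, go_term in pairs
    ]
    scored.sort(key=lambda item: (item[2].p_value, item[0], item[1]))
    return scored


def mine_rules(
    network: AnnotationNetwork,
    kinds: Iterable[RuleKind | str] = ALL_KINDS,
    min_support: int = 1,
    max_pvalue: float | Fraction = 1,
    require_false_positive: bool = True,
) -> list[Rule]:
    """Search the training network for all instances of the requested patterns.

    Every emitted rule satisfies its set identity (re-checkable through
    :func:`check_pattern`), has |S| >= ``min_support`` (>= 1 always, so
    vacuously-true identities with empty S are never emitted) and
    p-value <= ``max_pvalue``.

    With ``require_false_positive`` (the default) a composite is emitted
    only where it has false positives to explain away: plus-family
    patterns require PM(MP1)\\PM(GO) nonempty for at least one conjunct,
    minus-family patterns require a nonempty set to subtract (for
    plus-minus, (PM(MP1)∩PM(MP2))\\PM(GO) nonempty).  Where the simple
    pair is already a perfect predictor the composite adds nothing.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    kinds = {RuleKind(k) for k in kinds}
    max_p = Fraction(max_pvalue)  # exact comparison against exact rational p-values

    pm = network.pm
    mp_of = study_terms(network, "mp")
    all_mp = sorted(network.mp_index)
    found: dict[tuple, Rule] = {}

    def emit(kind: RuleKind, terms: Sequence[str], go: str, s: frozenset) -> None:
        if len(s) < min_support:
            return
        rule = make_rule(kind, terms, go, support=len(s))
        if rule.key() in found:
            return
        score = composite_pvalue(rule, network)
        if score.p_value > max_p:
            return
        found[rule.key()] = replace(rule, score=score, p_value=score.p_float, log10_p=score.log10_p)

    for go in sorted(network.go_index):
        pm_go = pm(go)
        for mp1 in all_mp:
            pm1 = pm(mp1)
            s0 = pm1 & pm_go
            if not s0:
                continue
            fp = pm1 - pm_go
            # terms co-annotated with a true positive of the simple pair
            cand_s0 = sorted({t for key in s0 for t in mp_of[key]} - {mp1})

            if RuleKind.PLUS in kinds:
                # second conjunct must keep all of S inside PM(GO): avoid FP entirely
                for mp2 in cand_s0:
                    if pm(mp2) & fp:
                        continue
                    if require_false_positive and not (fp or (pm(mp2) - pm_go)):
                        continue
                    emit(RuleKind.PLUS, (mp1, mp2), go, pm1 & pm(mp2))

            if RuleKind.MINUS in kinds and not (require_false_positive and not fp):
                # negated term must cover every false positive
                if fp:
                    cand = _terms_covering(fp, mp_of)
                else:
                    cand = set(all_mp)
                for mp2 in sorted(cand - {mp1}):
                    s = pm1 - pm(mp2)
                    if s:
                        emit(RuleKind.MINUS, (mp1, mp2), go, s)

            if RuleKind.PLUS_PLUS in kinds and not (require_false_positive and not fp):
                # both disjuncts avoid FP; at least one must hit S0 for S nonempty
                avoid_fp = [t for t in all_mp if t != mp1 and not (pm(t) & fp)]
                hits_s0 = [t for t in cand_s0 if not (pm(t) & fp)]
                hit_set = set(hits_s0)
                for d1 in hits_s0:
                    for d2 in avoid_fp:
                        if d2 == d1 or (d2 in hit_set and d2 < d1):
                            continue
                        emit(RuleKind.PLUS_PLUS, (mp1, d1, d2), go, pm1 & (pm(d1) | pm(d2)))

            if RuleKind.MINUS_MINUS in kinds and not (require_false_positive and not fp):
                if fp:
                    # the union of the two disjuncts must cover every false positive
                    touch_fp = sorted({t for key in fp for t in mp_of[key]} - {mp1})
                    touch_set = set(touch_fp)
                    for d1 in touch_fp:
                        rem = fp - pm(d1)
                        if rem:
                            partners = sorted(_terms_covering(rem, mp_of) - {mp1, d1})
                        else:
                            partners = [t for t in all_mp if t not in (mp1, d1)]
                        for d2 in partners:
                            if d2 in touch_set and d2 < d1:
                                continue
                            s = pm1 - (pm(d1) | pm(d2))
                            if s:
                                emit(RuleKind.MINUS_MINUS, (mp1, d1, d2), go, s)
                else:
                    # no false positives: the identity holds for any union clause
                    others = [t for t in all_mp if t != mp1]
                    for i, d1 in enumerate(others):
                        for d2 in others[i + 1 :]:
                            s = pm1 - (pm(d1) | pm(d2))
                            if s:
                                emit(RuleKind.MINUS_MINUS, (mp1, d1, d2), go, s)

            if RuleKind.PLUS_MINUS in kinds:
                for mp2 in cand_s0:
                    base = pm1 & pm(mp2)
                    fp12 = base - pm_go
                    if require_false_positive and not fp12:
                        continue
                    if fp12:
                        cand3 = sorted(_terms_covering(fp12, mp_of) - {mp1, mp2})
                    else:
                        cand3 = [t for t in all_mp if t not in (mp1, mp2)]
                    for mp3 in cand3:
                        s = base - pm(mp3)
                        if s:
                            emit(RuleKind.PLUS_MINUS, (mp1, mp2, mp3), go, s)

    rules = sorted(
        found.values(),
        key=lambda r: (r.score.p_value, r.kind.value, r.mp_positive, r.mp_disjunctive, r.mp_negative, r.go_term),
    )
    counters: dict[RuleKind, int] = {}
    out = []
    for rule in rules:
        idx = counters.get(rule.kind, 0)
        counters[rule.kind] = idx + 1
        out.append(replace(rule, rule_id=f"{rule.kind.value}-{idx}"))
    logger.info(
        "mine_rules: %s", ", ".join(f"{k.value}={counters.get(k, 0)}" for k in sorted(kinds, key=lambda x: x.value))
    )
    return out


def _terms_covering(keys: frozenset[StudyKey], mp_of: dict[StudyKey, frozenset[str]]) -> set[str]:
    """MP terms annotated to *every* StudyKey in ``keys`` (nonempty)."""
    it = iter(keys)
    cover = set(mp_of[next(it)])
    for key in it:
        cover &= mp_of[key]
        if not cover:
            break
    return cover


# ---------------------------------------------------------------------------
# rules TSV round-trip

_RULES_HEADER = (
    "rule_id",
    "kind",
    "mp_positive",
    "mp_negative",
    "mp_disjunctive",
    "go_term",
    "support",
    "p_value",
    "log10_p",
)


def write_rules(
    rules: Iterable[Rule],
    path: str | Path,
    *,
    header_lines: Iterable[str] = (),
    sidecar: str | Path | None = None,
) -> None:
    """Write the rules TSV (and optionally a JSON sidecar of factor provenance).

    Floats are serialized with ``repr`` so extreme exponents (1e-36 and
    below) round-trip without loss.
    """
    rules = list(rules)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_RULES_HEADER) + "\n")
        for r in rules:
            fh.write(
                "\t".join(
                    (
                        r.rule_id,
                        r.kind.value,
                        ";".join(r.mp_positive),
                        ";".join(r.mp_negative),
                        ";".join(r.mp_disjunctive),
                        r.go_term,
                        str(r.support),
                        repr(r.p_value),
                        repr(r.log10_p),
                    )
                )
                + "\n"
            )
    if sidecar is not None:
        payload = {
            r.rule_id: {
                "factors": [
                    {"term": t, "n": n, "j": j} for t, n, j in (r.score.factor_terms if r.score else ())
                ],
                "log10_p": r.log10_p,
            }
            for r in rules
        }
        with open(sidecar, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def read_rules(path: str | Path) -> list[Rule]:
    """Re-read a rules TSV; factor provenance (score) is not reconstructed."""
    out: list[Rule] = []
    with open(path, newline="") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if header is None:
                header = cols
                if tuple(header) != _RULES_HEADER:
                    raise ValueError(f"{path}:{lineno}: unexpected rules header {header!r}")
                continue
            if len(cols) != len(_RULES_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_RULES_HEADER)} columns")
            rid, kind, pos, neg, dis, go, support, p, lg = cols
            out.append(
                Rule(
                    kind=RuleKind(kind),
                    mp_positive=tuple(pos.split(";")) if pos else (),
                    mp_negative=tuple(neg.split(";")) if neg else (),
                    mp_disjunctive=tuple(dis.split(";")) if dis else (),
                    go_term=go,
                    support=int(support),
                    p_value=float(p),
                    log10_p=float(lg),
                    rule_id=rid,
                )
            )
    return out
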