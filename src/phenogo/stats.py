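"""Significance model for mined rules.

The null model: each of the N StudyKeys in the training universe is an
independent draw with per-draw success probability 1/N, and the p-value
of observing a success set S inside PM(term) is the upper tail of a
Binomial(n = |PM(term)|, 1/N) at threshold j = |S|.  Composite rules
multiply one such tail factor per participating set.

Tails are computed *exactly* over the rationals (integer suffix sums of
the binomial terms).  This is deliberate: real rule p-values reach
1e-41 and products over several factors fall far below the double-
precision floating range, so exact values are kept end-to-end and only
converted to floats / log10 at reporting time.  At the corpus scales
involved (n ≤ a few hundred) the integer arithmetic is cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .network import AnnotationNetwork, StudyKey


class NoAssociationError(ValueError):
    """The MP-GO pair shares no StudyKey; there is no association to score."""


class ContractError(ValueError):
    """A success set was not a subset of the factor's incidence set."""


def binomial_tail(n: int, j: int, N: int, p: Fraction | None = None) -> Fraction:
    """Exact upper tail P(X_n >= j) for X_n ~ Binomial(n, p), p = 1/N by default.

    Returns 1 when j == 0, 0 when j > n.  Computed as an integer suffix
    sum: sum_{i=j}^{n} C(n,i) (N-1)^(n-i) over N^n, accumulating the
    terms from i = n downward so each term derives from the previous by
    one exact multiply/divide.
    """
    if n < 0 or j < 0:
        raise ValueError(f"n and j must be non-negative (n={n}, j={j})")
    if N < 1:
        raise ValueError(f"N must be >= 1 (N={N})")
    if p is None:
        num_p, den_p = 1, N
    else:
        if not 0 <= p <= 1:
            raise ValueError(f"p must be in [0, 1] (p={p})")
        num_p, den_p = p.numerator, p.denominator
    if j > n:
        return Fraction(0)
    if j == 0:
        return Fraction(1)
    if num_p == 0:
        return Fraction(0)
    q = den_p - num_p  # failure weight per draw, over den_p
    # term_i = C(n, i) * num_p^i * q^(n-i); start at i = n and walk down.
    term = num_p**n
    acc = 0
    for i in range(n, j - 1, -1):
        acc += term
        if i > j:
            # C(n, i-1) = C(n, i) * i / (n - i + 1); shed one success, add one failure
            term = term * i * q // ((n - i + 1) * num_p)
    return Fraction(acc, den_p**n)


def log10_fraction(p: Fraction) -> float:
    """log10 of a non-negative rational, -inf for zero; robust to huge num/den."""
    if p == 0:
        return float("-inf")
    return math.log10(p.numerator) - math.log10(p.denominator)


def fraction_to_float(p: Fraction) -> float:
    """Fraction → float; values below the double range underflow to 0.0."""
    try:
        return p.numerator / p.denominator
    except OverflowError:
        return 0.0 if p < 1 else float("inf")


@dataclass(frozen=True)
class RuleScore:
    """A rule p-value with its provenance.

    ``factor_terms`` holds one (term_label, n, j) triple per tail factor
    (pooled disjunctive factors are labelled "T1|T2"); the stored
    p_value always equals the product of the factors recomputed from
    those triples — a checkable self-consistency invariant.
    """

    p_value: Fraction
    success_set: frozenset
    factor_terms: tuple[tuple[str, int, int], ...]

    @property
    def p_float(self) -> float:
        return fraction_to_float(self.p_value)

    @property
    def log10_p(self) -> float:
        return log10_fraction(self.p_value)

    def verify(self, N: int) -> bool:
        prod = Fraction(1)
        for _term, n, j in self.factor_terms:
            prod *= binomial_tail(n, j, N)
        return prod == self.p_value


def subset_prob(success_set: Iterable, term: str, network: "AnnotationNetwork") -> Fraction:
    """p[S ⊆ PM(term)]: the tail factor shared by every rule p-value.

    Precondition: S really is a subset of PM(term) — the event already
    obtains in the data; violating it means the caller computed S wrongly.
    """
    s = frozenset(success_set)
    incident = network.pm(term)
    if not s <= incident:
        raise ContractError(f"success set is not contained in PM({term})")
    return binomial_tail(len(incident), len(s), network.n)


def _factor(s: frozenset, label: str, reference: frozenset, N: int) -> tuple[tuple[str, int, int], Fraction]:
    if not s <= reference:
        raise ContractError(f"success set is not contained in the {label} factor set")
    n, j = len(reference), len(s)
    return (label, n, j), binomial_tail(n, j, N)


def simple_rule_pvalue(mp_term: str, go_term: str, network: "AnnotationNetwork") -> RuleScore:
    """Score the simple rule MP_i → GO_j: p_tot = p[S ⊆ PM(MP_i)], S = PM(MP_i) ∩ PM(GO_j).

    The single MP-side factor is the printed definition of p_tot; no
    GO-side factor enters the simple rule.
    """
    s = network.pm(mp_term) & network.pm(go_term)
    if not s:
        raise NoAssociationError(f"{mp_term} and {go_term} share no StudyKey")
    meta, p = _factor(s, mp_term, network.pm(mp_term), network.n)
    return RuleScore(p_value=p, success_set=s, factor_terms=(meta,))


def composite_pvalue(rule, network: "AnnotationNetwork") -> RuleScore:
    """Score a composite rule (plus / minus / plus-plus / minus-minus / plus-minus).

    plus:        S = PM(MP1)∩PM(MP2);             p = f(S,MP1)·f(S,MP2)·f(S,GO)
    minus:       S = PM(MP1)\\PM(MP2);             p = f(S,MP1)·f(S,GO)·f(S^c,MP2)
                 with S^c the complement of S within PM(MP1), i.e. PM(MP1)∩PM(MP2)
    plus-plus:   S = PM(MP1)∩(PM(MP2)∪PM(MP3));   the union is pooled as one factor
    minus-minus: S = PM(MP1)\\(PM(MP2)∪PM(MP3));   pooled complement factor likewise
    plus-minus:  S = (PM(MP1)∩PM(MP2))\\PM(MP3);   S^c taken within PM(MP1)∩PM(MP2)

    where f(S, T) = p[S ⊆ PM(T)].  The three extended forms follow this
    package's pooled-union extension of the plus/minus factorizations.
    """
    kind = str(getattr(rule.kind, "value", rule.kind))
    pm = network.pm
    N = network.n
    go = rule.go_term
    factors: list[tuple[tuple[str, int, int], Fraction]] = []

    if kind == "plus":
        a, b = rule.mp_positive
        s = pm(a) & pm(b)
        _check_identity(s, pm(go), kind)
        for term in (a, b, go):
            factors.append(_factor(s, term, pm(term), N))
    elif kind == "minus":
        (a,) = rule.mp_positive
        (b,) = rule.mp_negative
        s = pm(a) - pm(b)
        _check_identity(s, pm(go), kind)
        factors.append(_factor(s, a, pm(a), N))
        factors.append(_factor(s, go, pm(go), N))
        s_c = pm(a) & pm(b)  # complement of S relative to PM(MP1)
        factors.append(_factor(s_c, b, pm(b), N))
    elif kind == "plus_plus":
        (a,) = rule.mp_positive
        d1, d2 = rule.mp_disjunctive
        union = pm(d1) | pm(d2)
        s = pm(a) & union
        _check_identity(s, pm(go), kind)
        factors.append(_factor(s, a, pm(a), N))
        factors.append(_factor(s, f"{d1}|{d2}", union, N))
        factors.append(_factor(s, go, pm(go), N))
    elif kind == "minus_minus":
        (a,) = rule.mp_positive
        d1, d2 = rule.mp_disjunctive
        union = pm(d1) | pm(d2)
        s = pm(a) - union
        _check_identity(s, pm(go), kind)
        factors.append(_factor(s, a, pm(a), N))
        factors.append(_factor(s, go, pm(go), N))
        s_c = pm(a) & union
        factors.append(_factor(s_c, f"{d1}|{d2}", union, N))
    elif kind == "plus_minus":
        a, b = rule.mp_positive
        (c,) = rule.mp_negative
        base = pm(a) & pm(b)
        s = base - pm(c)
        _check_identity(s, pm(go), kind)
        factors.append(_factor(s, a, pm(a), N))
        factors.append(_factor(s, b, pm(b), N))
        factors.append(_factor(s, go, pm(go), N))
        s_c = base & pm(c)  # complement of S relative to PM(MP1)∩PM(MP2)
        factors.append(_factor(s_c, c, pm(c), N))
    else:
        raise ValueError(f"unknown rule kind {kind!r}")

    p = Fraction(1)
    for _, f in factors:
        p *= f
    return RuleScore(
        p_value=p,
        success_set=frozenset(s),
        factor_terms=tuple(meta for meta, _ in factors),
    )


def _check_identity(s: frozenset, pm_go: frozenset, kind: str) -> None:
    if not s <= pm_go:
        raise ContractError(f"{kind} rule does not satisfy its set identity on this network")


def benjamini_hochberg(pvalues: Iterable[Fraction | float]) -> list[float]:
    """BH-adjusted q-values (optional post-hoc correction; ranking uses raw p)."""
    ps = [float(fraction_to_float(p)) if isinstance(p, Fraction) else float(p) for p in pvalues]
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, ps[idx] * m / rank)
        q[idx] = prev
    return q
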