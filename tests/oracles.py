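"""Independent oracles used by the test suite.

These deliberately re-derive results by the most literal route possible
(naive summation, exhaustive enumeration) and share no code with the
implementation paths they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

from phenogo.network import AnnotationNetwork, StudyKey


def naive_binomial_tail(n: int, j: int, N: int) -> Fraction:
    """Direct per-term rational summation of the upper binomial tail."""
    p = Fraction(1, N)
    total = Fraction(0)
    for i in range(j, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return total


def naive_tail_suffix_numerators(n: int, N: int) -> tuple[list[int], int]:
    """Integer tail numerators over N^n for all thresholds j = 0..n.

    Terms are built independently with math.comb and an explicit power
    table; each threshold sums its suffix directly.
    """
    pows = [1] * (n + 1)
    for k in range(1, n + 1):
        pows[k] = pows[k - 1] * (N - 1)
    terms = [math.comb(n, i) * pows[n - i] for i in range(n + 1)]
    return [sum(terms[j:]) for j in range(n + 1)], N**n


def random_network(
    rng: np.random.Generator,
    max_studies: int = 20,
    max_mp: int = 12,
    max_go: int = 6,
    density: float = 0.25,
) -> AnnotationNetwork:
    """A small random incidence network; every study gets >= 1 MP and >= 1 GO."""
    n = int(rng.integers(4, max_studies + 1))
    n_mp = int(rng.integers(3, max_mp + 1))
    n_go = int(rng.integers(2, max_go + 1))
    keys = [StudyKey(pmid=f"p{i:03d}", allele_id="a") for i in range(n)]
    mp_terms = [f"MP:{i + 1:07d}" for i in range(n_mp)]
    go_terms = [f"GO:{i + 1:07d}" for i in range(n_go)]
    mp_mat = rng.random((n, n_mp)) < density
    go_mat = rng.random((n, n_go)) < density
    for i in range(n):  # training-mode rows need both families
        if not mp_mat[i].any():
            mp_mat[i, rng.integers(n_mp)] = True
        if not go_mat[i].any():
            go_mat[i, rng.integers(n_go)] = True
    return AnnotationNetwork.from_sets(
        {t: {keys[i] for i in np.nonzero(mp_mat[:, c])[0]} for c, t in enumerate(mp_terms)},
        {t: {keys[i] for i in np.nonzero(go_mat[:, c])[0]} for c, t in enumerate(go_terms)},
        universe=keys,
    )


def brute_force_rules(
    network: AnnotationNetwork,
    kind: str,
    min_support: int = 1,
    require_false_positive: bool = False,
) -> set[tuple]:
    """Exhaustive enumeration of all rule instances of one kind.

    Returns canonical keys (kind, mp_positive, mp_negative,
    mp_disjunctive, go_term) with symmetric positions sorted, matching
    Rule.key().  The set-identity conditions and the degenerate-pattern
    guard are evaluated literally, by definition.
    """
    pm = network.pm
    mps = sorted(network.mp_index)
    gos = sorted(network.go_index)
    out: set[tuple] = set()

    def fp(mp: str, go: str) -> frozenset:
        return pm(mp) - pm(go)

    for go in gos:
        pm_go = pm(go)
        if kind == "plus":
            for a, b in itertools.combinations(mps, 2):
                s = pm(a) & pm(b)
                if len(s) < min_support or not s <= pm_go:
                    continue
                if require_false_positive and not (fp(a, go) or fp(b, go)):
                    continue
                out.add(("plus", (a, b), (), (), go))
        elif kind == "minus":
            for a, b in itertools.permutations(mps, 2):
                s = pm(a) - pm(b)
                if len(s) < min_support or not s <= pm_go:
                    continue
                if require_false_positive and not fp(a, go):
                    continue
                out.add(("minus", (a,), (b,), (), go))
        elif kind == "plus_plus":
            for a in mps:
                for d1, d2 in itertools.combinations([t for t in mps if t != a], 2):
                    s = pm(a) & (pm(d1) | pm(d2))
                    if len(s) < min_support or not s <= pm_go:
                        continue
                    if require_false_positive and not fp(a, go):
                        continue
                    out.add(("plus_plus", (a,), (), (d1, d2), go))
        elif kind == "minus_minus":
            for a in mps:
                for d1, d2 in itertools.combinations([t for t in mps if t != a], 2):
                    s = pm(a) - (pm(d1) | pm(d2))
                    if len(s) < min_support or not s <= pm_go:
                        continue
                    if require_false_positive and not fp(a, go):
                        continue
                    out.add(("minus_minus", (a,), (), (d1, d2), go))
        elif kind == "plus_minus":
            for a, b in itertools.combinations(mps, 2):
                for c in mps:
                    if c in (a, b):
                        continue
                    s = (pm(a) & pm(b)) - pm(c)
                    if len(s) < min_support or not s <= pm_go:
                        continue
                    if require_false_positive and not ((pm(a) & pm(b)) - pm_go):
                        continue
                    out.add(("plus_minus", (a, b), (c,), (), go))
        else:
            raise ValueError(kind)
    return out


def auc_by_rank_statistic(scores, labels) -> float:
    """AUC via the Mann-Whitney rank-sum identity (lower score = stronger call)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        wins += np.sum(p < neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))
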