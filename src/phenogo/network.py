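"""The study/allele-keyed incidence network.

Rows are StudyKeys (PMID + allele), columns are MP and GO terms; the
structure is two rectangular incidence relations sharing the row set.
The core query is ``PM(term)`` — the set of StudyKeys annotated to a
term — from which every rule pattern and p-value downstream is defined.

In *training* mode only StudyKeys carrying at least one MP and at least
one GO annotation enter the universe (these are the co-curated studies
the rules are learned from); in *test* mode only MP-annotated StudyKeys
with no GO annotation enter (the corpus rules are applied to).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .records import AnnotationRecord, Ontology


class EmptyNetworkError(ValueError):
    """No StudyKey survived the mode filter."""


@dataclass(frozen=True, order=True, slots=True)
class StudyKey:
    """Joint publication + allele identifier; ordered lexicographically."""

    pmid: str
    allele_id: str

    def __str__(self) -> str:
        return f"{self.pmid}|{self.allele_id}"

    @classmethod
    def parse(cls, s: str) -> "StudyKey":
        pmid, _, allele = s.partition("|")
        return cls(pmid=pmid, allele_id=allele)


@dataclass(frozen=True)
class AnnotationNetwork:
    universe: tuple[StudyKey, ...]
    mp_index: Mapping[str, frozenset[StudyKey]]
    go_index: Mapping[str, frozenset[StudyKey]]
    gene_of: Mapping[StudyKey, frozenset[str]]
    mode: str = "training"
    _universe_set: frozenset[StudyKey] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_universe_set", frozenset(self.universe))
        for index in (self.mp_index, self.go_index):
            for term, keys in index.items():
                if not keys <= self._universe_set:
                    raise ValueError(f"incidence set of {term} escapes the universe")

    @property
    def n(self) -> int:
        """Universe size N — the number of distinct StudyKeys (matrix rows)."""
        return len(self.universe)

    def pm(self, term: str) -> frozenset[StudyKey]:
        """PM(term): StudyKeys annotated to ``term`` (empty for unknown terms)."""
        index = self.mp_index if term.startswith("MP:") else self.go_index
        return index.get(term, frozenset())

    @classmethod
    def from_sets(
        cls,
        mp_index: Mapping[str, Iterable[StudyKey]],
        go_index: Mapping[str, Iterable[StudyKey]],
        universe: Iterable[StudyKey] | None = None,
        gene_of: Mapping[StudyKey, Iterable[str]] | None = None,
        mode: str = "training",
    ) -> "AnnotationNetwork":
        """Build directly from PM(·) sets (mainly for tests and small examples)."""
        mp = {t: frozenset(v) for t, v in mp_index.items()}
        go = {t: frozenset(v) for t, v in go_index.items()}
        if universe is None:
            keys: set[StudyKey] = set()
            for v in list(mp.values()) + list(go.values()):
                keys |= v
        else:
            keys = set(universe)
        if not keys:
            raise EmptyNetworkError("empty universe")
        genes = {k: frozenset(v) for k, v in (gene_of or {}).items()}
        return cls(
            universe=tuple(sorted(keys)),
            mp_index=dict(sorted(mp.items())),
            go_index=dict(sorted(go.items())),
            gene_of=genes,
            mode=mode,
        )


def build_network(records: Iterable[AnnotationRecord], mode: str = "training") -> AnnotationNetwork:
    """Group records by StudyKey, apply the mode filter, invert to PM(·) indexes."""
    if mode not in ("training", "test"):
        raise ValueError(f"mode must be 'training' or 'test', got {mode!r}")
    mp_of: dict[StudyKey, set[str]] = {}
    go_of: dict[StudyKey, set[str]] = {}
    genes: dict[StudyKey, set[str]] = {}
    for rec in records:
        key = StudyKey(pmid=rec.pmid, allele_id=rec.allele_id)
        target = mp_of if rec.ontology is Ontology.MP else go_of
        target.setdefault(key, set()).add(rec.term_id)
        if rec.gene_id:
            genes.setdefault(key, set()).add(rec.gene_id)

    if mode == "training":
        keep = set(mp_of) & set(go_of)
    else:
        keep = set(mp_of) - set(go_of)
    if not keep:
        raise EmptyNetworkError(f"empty network: no StudyKey survives {mode} filtering")

    mp_index: dict[str, set[StudyKey]] = {}
    go_index: dict[str, set[StudyKey]] = {}
    for key in keep:
        for term in mp_of.get(key, ()):
            mp_index.setdefault(term, set()).add(key)
        if mode == "training":
            for term in go_of.get(key, ()):
                go_index.setdefault(term, set()).add(key)
    return AnnotationNetwork(
        universe=tuple(sorted(keep)),
        mp_index={t: frozenset(v) for t, v in sorted(mp_index.items())},
        go_index={t: frozenset(v) for t, v in sorted(go_index.items())},
        gene_of={k: frozenset(v) for k, v in genes.items() if k in keep},
        mode=mode,
    )


def pm(network: AnnotationNetwork, term: str) -> frozenset[StudyKey]:
    return network.pm(term)


def shared_set(network: AnnotationNetwork, mp_term: str, go_term: str) -> frozenset[StudyKey]:
    """S = PM(MP_i) ∩ PM(GO_j): the data-confirmed studies behind a simple rule."""
    return network.pm(mp_term) & network.pm(go_term)


def network_density(network: AnnotationNetwork) -> float:
    """Fraction of filled cells over both rectangular incidence matrices."""
    n_terms = len(network.mp_index) + len(network.go_index)
    if network.n == 0 or n_terms == 0:
        raise EmptyNetworkError("density undefined for an empty network")
    filled = sum(len(v) for v in network.mp_index.values()) + sum(
        len(v) for v in network.go_index.values()
    )
    return filled / (network.n * n_terms)


def study_terms(network: AnnotationNetwork, which: str = "mp") -> dict[StudyKey, frozenset[str]]:
    """Invert an incidence index to a StudyKey → term-set map."""
    index = network.mp_index if which == "mp" else network.go_index
    out: dict[StudyKey, set[str]] = {key: set() for key in network.universe}
    for term, keys in index.items():
        for key in keys:
            out[key].add(term)
    return {k: frozenset(v) for k, v in out.items()}


def permute_go_columns(network: AnnotationNetwork, rng: np.random.Generator) -> AnnotationNetwork:
    """Reassign GO incidences across StudyKeys by a random row permutation.

    Breaks any real MP↔GO co-emission while preserving every column's
    cardinality — the null model for the signal-vs-permutation check.
    """
    perm = rng.permutation(network.n)
    relabel = {network.universe[i]: network.universe[perm[i]] for i in range(network.n)}
    go_index = {
        term: frozenset(relabel[k] for k in keys) for term, keys in network.go_index.items()
    }
    return AnnotationNetwork(
        universe=network.universe,
        mp_index=network.mp_index,
        go_index=go_index,
        gene_of=network.gene_of,
        mode=network.mode,
    )


def export_incidence_tsv(network: AnnotationNetwork, path: str | Path, *, header_lines=()) -> None:
    """Plain-text export of both incidence lists (term_id, pmid, allele_id)."""
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("term_id\tpmid\tallele_id\n")
        for index in (network.mp_index, network.go_index):
            for term in sorted(index):
                for key in sorted(index[term]):
                    fh.write(f"{term}\t{key.pmid}\t{key.allele_id}\n")
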