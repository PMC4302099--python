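"""Normalized annotation records.

A record is one curated statement linking a publication (PMID) and an
allele to an ontology term, either a GO biological-process/function/
component annotation or an MP phenotype annotation.  The joint
(PMID, allele) pair — not the gene — is the unit of co-curation
evidence everywhere downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum


class Ontology(str, Enum):
    GO = "GO"
    MP = "MP"


class Aspect(str, Enum):
    """GAF aspect column: P(rocess), F(unction), C(omponent); NA for MP."""

    P = "P"
    F = "F"
    C = "C"
    NA = "NA"


_TERM_RE = re.compile(r"^(GO|MP):(\d+)$")


def normalize_term(term_id: str) -> str:
    """Canonicalize a term accession: keep the GO:/MP: prefix, zero-pad to 7 digits."""
    m = _TERM_RE.match(term_id.strip())
    if not m:
        raise ValueError(f"not a GO:/MP: term accession: {term_id!r}")
    return f"{m.group(1)}:{int(m.group(2)):07d}"


def normalize_pmid(ref: str) -> str:
    """Strip a 'PMID:' prefix; PMIDs are stored bare for stable join keys."""
    ref = ref.strip()
    return ref[5:] if ref.upper().startswith("PMID:") else ref


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    pmid: str
    allele_id: str
    gene_id: str
    term_id: str
    ontology: Ontology
    evidence: str = ""
    aspect: Aspect = Aspect.NA
    qualifier_not: bool = False

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if not self.allele_id:
            raise ValueError("allele_id must be non-empty")
        prefix = self.term_id.split(":", 1)[0]
        if prefix != self.ontology.value:
            raise ValueError(
                f"term {self.term_id!r} does not match ontology {self.ontology.value}"
            )
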