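"""Readers and writers for annotation files.

Function annotations come in as GAF 2.1/2.2 (17-column tab-delimited,
``!`` comment lines); phenotype annotations as tab-delimited MP report
rows (allele, MP term, PMID by default — the column order of MGI's
phenotype reports, configurable).  Both readers emit the same
:class:`~phenogo.records.AnnotationRecord` stream, which can be dumped
to / reloaded from a normalized TSV so every later stage has one input
format.

GAF rows are gene-keyed while the method pairs on PMID+allele; an
optional gene→allele mapping table (columns gene_id, allele_id, pmid)
resolves that.  Without one, the gene accession is used as the pairing
key and the reader logs that it is running in gene-keyed mode.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .records import AnnotationRecord, Aspect, Ontology, normalize_pmid, normalize_term

logger = logging.getLogger(__name__)

GAF_COLUMNS = 17

#: default column positions for MGI-shaped MP reports
DEFAULT_MP_COLUMNS: Mapping[str, int] = {"allele_id": 0, "term_id": 1, "pmid": 2}

NORMALIZED_HEADER = ("pmid", "allele_id", "gene_id", "term_id", "ontology", "evidence")


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def load_gene_allele_map(path: str | Path) -> dict[tuple[str, str], list[str]]:
    """Read a gene→allele mapping TSV (gene_id, allele_id, pmid).

    Returns a map from (gene_id, pmid) to the list of alleles that gene
    was studied through in that publication.
    """
    mapping: dict[tuple[str, str], list[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "gene_id":
                continue
            gene, allele, pmid = row[0], row[1], normalize_pmid(row[2])
            mapping.setdefault((gene, pmid), []).append(allele)
    return mapping


def read_gaf(
    path: str | Path,
    dialect: str = "gaf2.2",
    *,
    strict: bool = False,
    gene_to_allele: Mapping[tuple[str, str], list[str]] | None = None,
) -> Iterator[AnnotationRecord]:
    """Yield one AnnotationRecord per GAF annotation line.

    Lines without a PMID reference are skipped (counted in the log);
    malformed lines raise :class:`ParseError` in strict mode and are
    skipped with a log message otherwise.
    """
    if dialect not in ("gaf2.1", "gaf2.2"):
        raise ValueError(f"unknown GAF dialect: {dialect!r}")
    if gene_to_allele is None:
        logger.info("read_gaf %s: no gene->allele map; pairing on gene accession", path)
    n_skipped_nopmid = 0
    n_skipped_malformed = 0
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                if strict:
                    raise ParseError(path, lineno, f"expected {GAF_COLUMNS} columns, got {len(cols)}")
                n_skipped_malformed += 1
                continue
            db, obj_id, _symbol, qualifier, go_id = cols[0], cols[1], cols[2], cols[3], cols[4]
            reference, evidence, aspect = cols[5], cols[6], cols[8]
            pmid = ""
            for ref in reference.split("|"):
                if ref.upper().startswith("PMID:"):
                    pmid = normalize_pmid(ref)
                    break
            if not pmid:
                n_skipped_nopmid += 1
                continue
            try:
                term = normalize_term(go_id)
                asp = Aspect(aspect) if aspect in ("P", "F", "C") else Aspect.NA
                gene_id = obj_id if ":" in obj_id else f"{db}:{obj_id}"
                qual_not = "NOT" in qualifier.split("|")
            except ValueError as exc:
                if strict:
                    raise ParseError(path, lineno, str(exc)) from exc
                n_skipped_malformed += 1
                continue
            if gene_to_allele is None:
                alleles = [gene_id]
            else:
                # unmapped (gene, pmid): fall back to the gene accession as key
                alleles = gene_to_allele.get((gene_id, pmid)) or [gene_id]
            for allele in alleles:
                yield AnnotationRecord(
                    pmid=pmid,
                    allele_id=allele,
                    gene_id=gene_id,
                    term_id=term,
                    ontology=Ontology.GO,
                    evidence=evidence,
                    aspect=asp,
                    qualifier_not=qual_not,
                )
    if n_skipped_nopmid:
        logger.info("read_gaf %s: skipped %d lines without PMID reference", path, n_skipped_nopmid)
    if n_skipped_malformed:
        logger.warning("read_gaf %s: skipped %d malformed lines", path, n_skipped_malformed)


def read_mp_report(
    path: str | Path,
    *,
    columns: Mapping[str, int] = DEFAULT_MP_COLUMNS,
    strict: bool = False,
) -> Iterator[AnnotationRecord]:
    """Yield MP AnnotationRecords from a tab-delimited phenotype report.

    ``columns`` maps field names (allele_id, term_id, pmid, optionally
    gene_id and evidence) to 0-based column positions.
    """
    required = ("allele_id", "term_id", "pmid")
    for name in required:
        if name not in columns:
            raise ValueError(f"column map missing {name!r}")
    width = max(columns.values()) + 1
    n_skipped = 0
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "!")):
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                if len(cols) < width:
                    raise ValueError(f"expected >= {width} columns, got {len(cols)}")
                allele = cols[columns["allele_id"]].strip()
                term = normalize_term(cols[columns["term_id"]])
                pmid = normalize_pmid(cols[columns["pmid"]])
                gene = cols[columns["gene_id"]].strip() if "gene_id" in columns else ""
                evidence = cols[columns["evidence"]].strip() if "evidence" in columns else ""
                yield AnnotationRecord(
                    pmid=pmid,
                    allele_id=allele,
                    gene_id=gene,
                    term_id=term,
                    ontology=Ontology.MP,
                    evidence=evidence,
                    aspect=Aspect.NA,
                )
            except ValueError as exc:
                if strict:
                    raise ParseError(path, lineno, str(exc)) from exc
                n_skipped += 1
                logger.warning("read_mp_report %s:%d: skipped (%s)", path, lineno, exc)
    if n_skipped:
        logger.info("read_mp_report %s: skipped %d malformed lines", path, n_skipped)


def filter_training_records(records: Iterable[AnnotationRecord]) -> Iterator[AnnotationRecord]:
    """Apply the training filters.

    GO records are kept only for the biological-process aspect with IMP
    ("inferred from mutant phenotype") evidence; MP records pass
    unconditionally.  NOT-qualified annotations are dropped everywhere —
    a NOT annotation is not evidence of function.
    """
    n_in = n_out = 0
    for rec in records:
        n_in += 1
        if rec.qualifier_not:
            continue
        if rec.ontology is Ontology.GO and not (
            rec.aspect is Aspect.P and rec.evidence == "IMP"
        ):
            continue
        n_out += 1
        yield rec
    logger.info("filter_training_records: kept %d of %d records", n_out, n_in)


def write_records_tsv(
    records: Iterable[AnnotationRecord], path: str | Path, *, header_lines: Iterable[str] = ()
) -> int:
    """Write the normalized TSV (pmid, allele_id, gene_id, term_id, ontology, evidence)."""
    n = 0
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(NORMALIZED_HEADER) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    (rec.pmid, rec.allele_id, rec.gene_id, rec.term_id, rec.ontology.value, rec.evidence)
                )
                + "\n"
            )
            n += 1
    return n


def read_records_tsv(path: str | Path) -> Iterator[AnnotationRecord]:
    """Re-read a normalized TSV written by :func:`write_records_tsv`.

    GO rows were training-filtered before writing, so aspect is restored
    as P for GO and NA for MP; qualifier_not is False by construction.
    """
    with open(path, newline="") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if header is None:
                header = cols
                if tuple(header) != NORMALIZED_HEADER:
                    raise ParseError(path, lineno, f"unexpected header {header!r}")
                continue
            if len(cols) != len(NORMALIZED_HEADER):
                raise ParseError(path, lineno, f"expected {len(NORMALIZED_HEADER)} columns")
            pmid, allele, gene, term, onto, evidence = cols
            ontology = Ontology(onto)
            yield AnnotationRecord(
                pmid=pmid,
                allele_id=allele,
                gene_id=gene,
                term_id=term,
                ontology=ontology,
                evidence=evidence,
                aspect=Aspect.P if ontology is Ontology.GO else Aspect.NA,
            )


def write_gaf(records: Iterable[AnnotationRecord], path: str | Path) -> int:
    """Write GO records as a minimal GAF 2.2 file (one row per record)."""
    n = 0
    with open(path, "w", newline="") as fh:
        fh.write("!gaf-version: 2.2\n")
        for rec in records:
            if rec.ontology is not Ontology.GO:
                continue
            db, _, obj = rec.gene_id.partition(":")
            if not obj:
                db, obj = "MGI", rec.gene_id
            row = [""] * GAF_COLUMNS
            row[0] = db
            row[1] = f"{db}:{obj}" if ":" not in rec.gene_id else rec.gene_id
            row[2] = obj
            row[3] = "NOT|involved_in" if rec.qualifier_not else "involved_in"
            row[4] = rec.term_id
            row[5] = f"PMID:{rec.pmid}"
            row[6] = rec.evidence or "IMP"
            row[8] = rec.aspect.value if rec.aspect is not Aspect.NA else "P"
            row[11] = "protein"
            row[12] = "taxon:10090"
            row[13] = "20130610"
            row[14] = "MGI"
            fh.write("\t".join(row) + "\n")
            n += 1
    return n


def write_mp_report(records: Iterable[AnnotationRecord], path: str | Path) -> int:
    """Write MP records as a 3-column report (allele_id, MP term, PMID)."""
    n = 0
    with open(path, "w", newline="") as fh:
        for rec in records:
            if rec.ontology is not Ontology.MP:
                continue
            fh.write(f"{rec.allele_id}\t{rec.term_id}\t{rec.pmid}\n")
            n += 1
    return n
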