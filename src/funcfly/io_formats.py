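"""Readers and writers for the standard files the pipeline touches.

Formats: tab-separated tables (UTF-8, ``#``-prefixed comments ignored) for
expression and feature matrices; OBO 1.2/1.4 for the ontology; GAF 2.1/2.2
for annotations; a fixed-layout TSV for prediction output.

Round-trip guarantee: for every writer/reader pair in this module,
``read(write(x))`` reproduces ``x`` (floats to their printed precision where
a fixed format is used).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import obonet
import pandas as pd

from .containers import (
    EXPRESSION_META_COLUMNS,
    N_TIMEPOINTS,
    AnnotationSet,
    FeatureMatrix,
    GoDag,
    PredictionRecord,
    TranscriptExpressionTable,
    namespace_long_name,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_GAF_ASPECT = {"BP": "P", "MF": "F", "CC": "C"}


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_transcript_expression(path) -> TranscriptExpressionTable:
    """Read a transcript-level expression TSV.

    The header must name the four metadata columns
    ``transcript_id, gene_id, protein_id, isoform_length`` followed by the 30
    time-point columns in temporal order.
    """
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed TSV ({exc})") from exc
    missing = [c for c in EXPRESSION_META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    time_labels = [c for c in frame.columns if c not in EXPRESSION_META_COLUMNS]
    if len(time_labels) != N_TIMEPOINTS:
        raise FormatError(
            f"{path}: expected {N_TIMEPOINTS} expression columns, "
            f"found {len(time_labels)}"
        )
    for col in ("transcript_id", "gene_id", "protein_id"):
        frame[col] = frame[col].astype(str)
    return TranscriptExpressionTable(frame, tuple(time_labels))


def write_transcript_expression(table: TranscriptExpressionTable, path) -> None:
    cols = list(EXPRESSION_META_COLUMNS) + list(table.time_labels)
    table.frame.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def read_feature_matrix(path, group: str = "Seq") -> FeatureMatrix:
    """Read a protein x numeric-feature TSV; all columns get one group label.

    The first column holds protein ids. Non-numeric cells and duplicated
    protein ids raise :class:`ValidationError` naming the offending cell/row.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    frame.index = frame.index.astype(str)
    frame.index.name = "protein_id"
    return FeatureMatrix(frame, group)


def read_expression_features(path) -> FeatureMatrix:
    """Read an expression-feature TSV written by :func:`write_feature_matrix`,
    assigning groups from the ``num_``/``ave_``/``main_`` column-name prefixes."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    frame.index = frame.index.astype(str)
    frame.index.name = "protein_id"
    groups = {}
    for col in frame.columns:
        prefix = col.split("_", 1)[0]
        label = {"num": "Num", "ave": "Ave", "main": "Main"}.get(prefix)
        if label is None:
            raise FormatError(f"{path}: cannot infer feature group of column {col!r}")
        groups[col] = label
    return FeatureMatrix(frame, groups)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------------

def read_obo(path) -> GoDag:
    """Read an OBO 1.2/1.4 file into a :class:`GoDag`.

    Only ``is_a`` and ``part_of`` relationships are retained; obsolete
    stanzas are dropped. A directed cycle raises :class:`CycleError` listing
    the cycle.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    return GoDag(graph)


def write_obo(dag: GoDag, path) -> None:
    """Write the DAG as a minimal OBO 1.2 stanza file (deterministic order)."""
    lines = ["format-version: 1.2", "ontology: go-synthetic", ""]
    for term in dag.terms():
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.name(term)}")
        lines.append(f"namespace: {namespace_long_name(dag.namespace(term))}")
        for child, parent, rel in dag.edges():
            if child != term:
                continue
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {dag.name(parent)}")
            else:
                lines.append(f"relationship: part_of {parent} ! {dag.name(parent)}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# GAF annotations
# ---------------------------------------------------------------------------

def read_gaf(
    path,
    dag: Optional[GoDag] = None,
    evidence_exclude: Iterable = (),
) -> AnnotationSet:
    """Read a GAF 2.1/2.2 file into an :class:`AnnotationSet`.

    Rows whose qualifier contains ``NOT`` are always dropped. Evidence codes
    in `evidence_exclude` are dropped (empty by default). When a `dag` is
    given, rows referencing terms absent from it are skipped with a logged
    count. Duplicate triples are collapsed.
    """
    exclude = {str(e) for e in evidence_exclude}
    triples = []
    skipped_unknown = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise FormatError(
                    f"{path}:{lineno}: GAF row has {len(cols)} columns, expected >= 7"
                )
            protein_id = cols[1]
            qualifier = cols[3]
            term_id = cols[4]
            evidence = cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in exclude:
                continue
            if dag is not None and term_id not in dag:
                skipped_unknown += 1
                continue
            triples.append((protein_id, term_id, evidence))
    if skipped_unknown:
        logger.warning(
            "%s: skipped %d annotation row(s) referencing terms absent from the DAG",
            path,
            skipped_unknown,
        )
    return AnnotationSet.from_iterable(triples)


def write_gaf(annotations: AnnotationSet, path, dag: Optional[GoDag] = None) -> None:
    """Write annotations as GAF 2.1 (deterministic row order)."""
    rows = []
    for protein_id, term_id, evidence in sorted(annotations.triples):
        aspect = "P"
        if dag is not None and term_id in dag:
            aspect = _GAF_ASPECT[dag.namespace(term_id)]
        rows.append(
            "\t".join(
                [
                    "SYNTH",          # DB
                    protein_id,       # DB object id
                    protein_id,       # symbol
                    "",               # qualifier
                    term_id,          # GO id
                    "SYNTH:0000001",  # reference
                    evidence,         # evidence code
                    "",               # with/from
                    aspect,           # aspect
                    "",               # name
                    "",               # synonym
                    "protein",        # type
                    "taxon:7227",     # taxon
                    "20140901",       # date
                    "SYNTH",          # assigned by
                    "",               # annotation extension
                    "",               # gene product form id
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        fh.write("\n".join(rows))
        if rows:
            fh.write("\n")


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(records: Iterable, path) -> None:
    """Write prediction records as TSV sorted by (protein, term);
    confidences carry fixed 4-decimal formatting."""
    ordered = sorted(records, key=lambda r: (r.protein_id, r.term_id))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tterm_id\tconfidence\tpredicted_label\n")
        for r in ordered:
            fh.write(
                f"{r.protein_id}\t{r.term_id}\t{r.confidence:.4f}\t{r.predicted_label}\n"
            )


def read_predictions(path) -> list:
    frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    expected = ["protein_id", "term_id", "confidence", "predicted_label"]
    if list(frame.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    return [
        PredictionRecord(row.protein_id, row.term_id, float(row.confidence),
                         int(row.predicted_label))
        for row in frame.itertuples(index=False)
    ]
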