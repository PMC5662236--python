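"""Core in-memory containers shared across the pipeline.

The pipeline revolves around four kinds of objects:

* :class:`TranscriptExpressionTable` -- per-transcript expression over a
  30-point developmental time course, plus the transcript/gene/protein
  mapping and isoform lengths needed to pick a gene's main transcript.
* :class:`FeatureMatrix` -- a protein x named-feature numeric block in which
  every column belongs to one of the four feature groups
  (``Seq``, ``Num``, ``Ave``, ``Main``).
* :class:`GoDag` -- the Gene Ontology hierarchy restricted to ``is_a`` and
  ``part_of`` edges, one root per namespace (BP / MF / CC).
* :class:`AnnotationSet` -- deduplicated (protein, term, evidence) triples.

All identifiers are case-sensitive opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CycleError, FormatError, ValidationError

#: Number of time-points in the developmental series.
N_TIMEPOINTS = 30

#: Default ordered labels for the 30 time-points.
TIME_LABELS = tuple(f"T{i:02d}" for i in range(1, N_TIMEPOINTS + 1))

#: Fixed composition order of the feature groups.
FEATURE_GROUPS = ("Seq", "Num", "Ave", "Main")

#: GO namespaces in canonical order.
NAMESPACES = ("BP", "MF", "CC")

_NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}

_NAMESPACE_LONG = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}

#: Required metadata columns of an expression table, in file order.
EXPRESSION_META_COLUMNS = ("transcript_id", "gene_id", "protein_id", "isoform_length")


def normalize_namespace(value: str) -> str:
    """Map a long or short GO namespace name onto ``BP``/``MF``/``CC``."""
    try:
        return _NAMESPACE_ALIASES[value]
    except KeyError:
        raise ValidationError(f"unknown GO namespace: {value!r}") from None


def namespace_long_name(ns: str) -> str:
    return _NAMESPACE_LONG[normalize_namespace(ns)]


@dataclass
class TranscriptExpressionTable:
    """Per-transcript expression over the developmental time course.

    Parameters
    ----------
    frame
        One row per transcript with the metadata columns
        ``transcript_id, gene_id, protein_id, isoform_length`` followed by the
        30 expression columns named by `time_labels`. Row order is preserved.
    time_labels
        Ordered names of the 30 expression columns.
    """

    frame: pd.DataFrame
    time_labels: tuple = TIME_LABELS

    def __post_init__(self) -> None:
        self.time_labels = tuple(self.time_labels)
        if len(self.time_labels) != N_TIMEPOINTS:
            raise FormatError(
                f"expected {N_TIMEPOINTS} time-point labels, got {len(self.time_labels)}"
            )
        missing = [c for c in EXPRESSION_META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"expression table lacks columns: {missing}")
        missing_t = [c for c in self.time_labels if c not in self.frame.columns]
        if missing_t:
            raise FormatError(f"expression table lacks time columns: {missing_t}")

        frame = self.frame.reset_index(drop=True)
        dup = frame["transcript_id"][frame["transcript_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicated transcript_id: {sorted(set(dup))}")

        lengths = pd.to_numeric(frame["isoform_length"], errors="coerce")
        bad = frame.index[~np.isfinite(lengths) | (lengths <= 0) | (lengths % 1 != 0)]
        if len(bad):
            raise ValidationError(
                f"isoform_length must be a positive integer (row {bad[0]}, "
                f"transcript {frame.loc[bad[0], 'transcript_id']!r})"
            )
        frame["isoform_length"] = lengths.astype(int)

        expr = frame.loc[:, list(self.time_labels)].apply(
            pd.to_numeric, errors="coerce"
        )
        nan_rows = expr.index[expr.isna().any(axis=1)]
        if len(nan_rows):
            row = nan_rows[0]
            col = expr.columns[expr.loc[row].isna()][0]
            raise FormatError(
                f"non-numeric or missing expression value at row {row}, column {col!r}"
            )
        neg = expr.lt(0)
        if neg.to_numpy().any():
            row = expr.index[neg.any(axis=1)][0]
            col = expr.columns[neg.loc[row]][0]
            raise ValidationError(
                f"negative expression value at row {row}, column {col!r} "
                f"(transcript {frame.loc[row, 'transcript_id']!r})"
            )
        frame.loc[:, list(self.time_labels)] = expr.astype(float)
        self.frame = frame

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def expression(self) -> pd.DataFrame:
        """Transcript x time-point block, indexed by transcript id."""
        return self.frame.set_index("transcript_id").loc[:, list(self.time_labels)]

    @property
    def gene_ids(self) -> list:
        """Gene ids in first-appearance order."""
        return list(dict.fromkeys(self.frame["gene_id"]))

    def transcripts_of(self, gene_id: str) -> pd.DataFrame:
        """Rows of one gene, in table order."""
        sub = self.frame[self.frame["gene_id"] == gene_id]
        if sub.empty:
            raise KeyError(f"unknown gene_id: {gene_id!r}")
        return sub

    def by_gene(self) -> Iterator:
        """Yield ``(gene_id, sub_frame)`` in first-appearance order of genes."""
        for gene_id in self.gene_ids:
            yield gene_id, self.frame[self.frame["gene_id"] == gene_id]

    def protein_gene_pairs(self) -> pd.DataFrame:
        """Distinct (protein_id, gene_id) pairs in first-appearance order."""
        return self.frame[["protein_id", "gene_id"]].drop_duplicates(
            subset=["protein_id", "gene_id"]
        )


@dataclass
class FeatureMatrix:
    """Protein x named-feature numeric block with per-column group labels.

    ``groups`` may be a single group name applied to every column, or a
    mapping / Series from column name to group.
    """

    values: pd.DataFrame
    groups: object = "Seq"

    def __post_init__(self) -> None:
        values = self.values
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated protein id(s): {dup}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated feature column(s): {dup}")

        if isinstance(self.groups, str):
            groups = pd.Series(self.groups, index=values.columns, dtype=object)
        else:
            groups = pd.Series(dict(self.groups), dtype=object)
        if set(groups.index) != set(values.columns):
            raise ValidationError("group labels do not cover the feature columns")
        groups = groups.reindex(values.columns)
        unknown = sorted(set(groups) - set(FEATURE_GROUPS))
        if unknown:
            raise ValidationError(f"unknown feature group(s): {unknown}")

        numeric = values.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna()
        if bad.to_numpy().any():
            row = numeric.index[bad.any(axis=1)][0]
            col = numeric.columns[bad.loc[row]][0]
            raise ValidationError(
                f"non-numeric or missing value at protein {row!r}, feature {col!r}"
            )
        self.values = numeric.astype(float)
        self.groups = groups

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return len(self.values)

    def group_columns(self, group: str) -> list:
        """Column names belonging to one feature group, in matrix order."""
        return [c for c, g in self.groups.items() if g == group]

    def present_groups(self) -> tuple:
        return tuple(g for g in FEATURE_GROUPS if g in set(self.groups))

    def subset(self, proteins: Iterable) -> "FeatureMatrix":
        """Row-subset preserving the given protein order."""
        return FeatureMatrix(self.values.loc[list(proteins)], self.groups)


class GoDag:
    """GO hierarchy over ``is_a``/``part_of`` edges, one root per namespace.

    The underlying graph has edges pointing from child term to parent term.
    Obsolete terms are expected to have been dropped by the reader.
    """

    RELATIONS = ("is_a", "part_of")

    def __init__(self, graph: nx.MultiDiGraph):
        kept = nx.MultiDiGraph()
        for node, attrs in graph.nodes(data=True):
            ns = normalize_namespace(attrs.get("namespace", ""))
            kept.add_node(node, name=attrs.get("name", node), namespace=ns)
        for child, parent, key in graph.edges(keys=True):
            if key in self.RELATIONS:
                if child not in kept or parent not in kept:
                    continue
                kept.add_edge(child, parent, key=key)

        if not nx.is_directed_acyclic_graph(kept):
            cycle = [u for u, _v, _k in nx.find_cycle(kept)]
            raise CycleError(cycle + [cycle[0]])

        self.graph = kept
        self._roots: dict = {}
        for term in kept.nodes:
            ns = kept.nodes[term]["namespace"]
            if not any(
                kept.nodes[p]["namespace"] == ns for p in kept.successors(term)
            ):
                if ns in self._roots:
                    raise ValidationError(
                        f"namespace {ns} has multiple roots: "
                        f"{self._roots[ns]!r}, {term!r}"
                    )
                self._roots[ns] = term
        self._ancestor_cache: dict = {}

    @classmethod
    def from_edges(
        cls,
        terms: Iterable,
        edges: Iterable,
    ) -> "GoDag":
        """Build a DAG from ``(id, name, namespace)`` terms and
        ``(child, parent, relation)`` edges."""
        g = nx.MultiDiGraph()
        for term_id, name, ns in terms:
            g.add_node(term_id, name=name, namespace=ns)
        for child, parent, rel in edges:
            g.add_edge(child, parent, key=rel)
        return cls(g)

    # -- queries -----------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def terms(self) -> list:
        return sorted(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term]["name"]

    def namespace(self, term: str) -> str:
        try:
            return self.graph.nodes[term]["namespace"]
        except KeyError:
            raise KeyError(f"unknown GO term: {term!r}") from None

    @property
    def roots(self) -> dict:
        """Mapping namespace -> root term id."""
        return dict(self._roots)

    def is_root(self, term: str) -> bool:
        return term in self._roots.values()

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of `term` via is_a/part_of, restricted to the term's
        namespace; does not include the term itself."""
        if term not in self.graph:
            raise KeyError(f"unknown GO term: {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        ns = self.namespace(term)
        out: set = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for parent in self.graph.successors(node):
                if self.graph.nodes[parent]["namespace"] != ns:
                    continue
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def edges(self) -> list:
        """Sorted ``(child, parent, relation)`` triples."""
        return sorted(self.graph.edges(keys=True))


@dataclass(frozen=True)
class AnnotationSet:
    """Deduplicated (protein_id, term_id, evidence_code) triples."""

    triples: frozenset

    @classmethod
    def from_iterable(cls, triples: Iterable) -> "AnnotationSet":
        return cls(frozenset((str(p), str(t), str(e)) for p, t, e in triples))

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(sorted(self.triples))

    @property
    def pairs(self) -> frozenset:
        """Distinct (protein_id, term_id) pairs."""
        return frozenset((p, t) for p, t, _e in self.triples)

    def proteins_for(self, term: str) -> frozenset:
        return frozenset(p for p, t, _e in self.triples if t == term)

    def terms(self) -> list:
        return sorted({t for _p, t, _e in self.triples})

    def proteins(self) -> list:
        return sorted({p for p, _t, _e in self.triples})

    def term_counts(self) -> dict:
        """Term -> number of distinct annotated proteins."""
        counts: dict = {}
        for p, t in self.pairs:
            counts[t] = counts.get(t, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.triples), columns=["protein_id", "term_id", "evidence_code"]
        )


@dataclass(frozen=True)
class PredictionRecord:
    """One scored (protein, term) prediction."""

    protein_id: str
    term_id: str
    confidence: float
    predicted_label: int

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"confidence outside [0, 1]: {self.confidence} "
                f"({self.protein_id}, {self.term_id})"
            )
        if self.predicted_label not in (0, 1):
            raise ValidationError(f"predicted_label must be 0/1: {self.predicted_label}")
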