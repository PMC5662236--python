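"""Seeded synthetic benchmarks with known ground truth.

The generator emulates the shapes of the four real inputs the pipeline
consumes -- a multi-isoform transcript expression table over 30 time-points,
a protein x sequence-feature matrix, a small GO DAG spanning the three
namespaces, and a GAF annotation file -- with *plantable* class signal:

* baseline transcript expression is log-normal (meanlog 1.0, sdlog 1.0),
  right-skewed like RNA-seq abundance estimates;
* sequence features are standard normal;
* every namespace has a root, two intermediate terms and a configurable
  number of leaf terms; planted terms attach to leaves;
* an *expression-driven* term shifts the log-mean of its positive genes'
  transcripts by ``expression_effect`` at its informative time-points
  (all isoforms shifted, so transcript counts stay uninformative);
* a *sequence-driven* term shifts a subset of sequence features of its
  positive proteins by ``seq_effect`` standard deviations;
* ``mixed`` plants both signals and ``null`` plants none.

Everything is deterministic under the config seed, and the emitted GAF
round-trips through :mod:`funcfly.io_formats` to exactly the manifest's
positive sets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    N_TIMEPOINTS,
    TIME_LABELS,
    AnnotationSet,
    FeatureMatrix,
    GoDag,
    TranscriptExpressionTable,
)
from .errors import ParameterError
from . import io_formats

DRIVERS = ("expression", "sequence", "mixed", "null")


@dataclass(frozen=True)
class PlantedTermSpec:
    """Ground-truth recipe for one GO term."""

    namespace: str = "BP"
    n_positives: int = 100
    driver: str = "expression"
    informative_timepoints: tuple = (5, 6, 7)   # 1-based
    expression_effect: float = 2.0              # log-scale shift on positives
    seq_effect: float = 1.5                     # SD shift on affected features
    n_seq_affected: int = 10

    def __post_init__(self):
        if self.driver not in DRIVERS:
            raise ParameterError(f"driver must be one of {DRIVERS}: {self.driver!r}")
        if self.expression_effect < 0 or self.seq_effect < 0:
            raise ParameterError("effect sizes must be >= 0")
        bad = [t for t in self.informative_timepoints if not 1 <= t <= N_TIMEPOINTS]
        if bad:
            raise ParameterError(f"informative time-points out of 1..30: {bad}")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Full recipe for one synthetic benchmark."""

    n_genes: int = 500
    transcripts_per_gene: tuple = (1, 3)
    n_seq_features: int = 258
    terms: tuple = (
        PlantedTermSpec(namespace="BP", driver="expression"),
        PlantedTermSpec(namespace="MF", driver="sequence"),
        PlantedTermSpec(namespace="CC", driver="null"),
    )
    meanlog: float = 1.0
    sdlog: float = 1.0
    leaves_per_mid: int = 2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.transcripts_per_gene
        if not 1 <= lo <= hi:
            raise ParameterError(
                f"invalid transcripts_per_gene range: {self.transcripts_per_gene}"
            )
        for spec in self.terms:
            if spec.n_positives > self.n_genes:
                raise ParameterError(
                    f"term requests {spec.n_positives} positives but only "
                    f"{self.n_genes} genes exist"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["terms"] = [dataclasses.asdict(t) for t in self.terms]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        d = dict(d)
        terms = tuple(
            PlantedTermSpec(**{**t, "informative_timepoints":
                               tuple(t.get("informative_timepoints", (5, 6, 7)))})
            for t in d.pop("terms", [])
        )
        if "transcripts_per_gene" in d:
            d["transcripts_per_gene"] = tuple(d["transcripts_per_gene"])
        if not terms:
            return cls(**d)
        return cls(terms=terms, **d)


@dataclass
class TermTruth:
    """Realised ground truth of one planted term."""

    term_id: str
    namespace: str
    driver: str
    informative_timepoints: tuple
    affected_seq_features: tuple
    positive_proteins: tuple


@dataclass
class GroundTruthManifest:
    """Ground truth of a generated benchmark, keyed by term id."""

    terms: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {t: dataclasses.asdict(v) for t, v in self.terms.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        terms = {
            t: TermTruth(
                term_id=v["term_id"],
                namespace=v["namespace"],
                driver=v["driver"],
                informative_timepoints=tuple(v["informative_timepoints"]),
                affected_seq_features=tuple(v["affected_seq_features"]),
                positive_proteins=tuple(v["positive_proteins"]),
            )
            for t, v in payload.items()
        }
        return cls(terms=terms)


@dataclass
class Benchmark:
    """A generated benchmark: the four standard inputs plus ground truth."""

    expression: TranscriptExpressionTable
    seq_features: FeatureMatrix
    dag: GoDag
    annotations: AnnotationSet
    manifest: GroundTruthManifest


def _build_dag(leaves_per_mid: int):
    """Three-namespace DAG: root -> 2 mids -> leaves_per_mid leaves each.

    One leaf per namespace links to its mid via part_of for relationship
    coverage; everything else is is_a.
    """
    terms, edges = [], []
    leaves = {"BP": [], "MF": [], "CC": []}
    counter = 1

    def next_id():
        nonlocal counter
        term_id = f"GO:{counter:07d}"
        counter += 1
        return term_id

    for ns in ("BP", "MF", "CC"):
        root = next_id()
        terms.append((root, f"synthetic {ns} root", ns))
        for m in range(2):
            mid = next_id()
            terms.append((mid, f"synthetic {ns} mid {m + 1}", ns))
            edges.append((mid, root, "is_a"))
            for l in range(leaves_per_mid):
                leaf = next_id()
                terms.append((leaf, f"synthetic {ns} leaf {m * leaves_per_mid + l + 1}", ns))
                rel = "part_of" if (m == 0 and l == 0) else "is_a"
                edges.append((leaf, mid, rel))
                leaves[ns].append(leaf)
    return GoDag.from_edges(terms, edges), leaves


def generate_benchmark(config: BenchmarkConfig) -> Benchmark:
    """Generate a complete benchmark; byte-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    lo, hi = config.transcripts_per_gene

    gene_ids = [f"gene{i:05d}" for i in range(1, n_genes + 1)]
    protein_ids = [f"prot{i:05d}" for i in range(1, n_genes + 1)]
    n_transcripts_per_gene = rng.integers(lo, hi + 1, size=n_genes)

    rows = []
    gene_row_slices = {}
    row_start = 0
    for g, gene in enumerate(gene_ids):
        k = int(n_transcripts_per_gene[g])
        lengths = rng.choice(np.arange(80, 3000), size=k, replace=False)
        for j in range(k):
            rows.append(
                (f"{gene}.t{j + 1}", gene, protein_ids[g], int(lengths[j]))
            )
        gene_row_slices[gene] = (row_start, row_start + k)
        row_start += k
    n_rows = row_start

    log_expr = rng.normal(config.meanlog, config.sdlog, size=(n_rows, N_TIMEPOINTS))
    seq_values = rng.normal(0.0, 1.0, size=(n_genes, config.n_seq_features))
    seq_names = [f"seq_f{i:04d}" for i in range(1, config.n_seq_features + 1)]

    dag, leaves = _build_dag(config.leaves_per_mid)
    next_leaf = {ns: 0 for ns in leaves}
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    manifest = GroundTruthManifest()
    triples = []
    for spec in config.terms:
        ns = spec.namespace
        if next_leaf[ns] >= len(leaves[ns]):
            raise ParameterError(
                f"namespace {ns} has only {len(leaves[ns])} leaves; "
                "increase leaves_per_mid to plant more terms"
            )
        term_id = leaves[ns][next_leaf[ns]]
        next_leaf[ns] += 1

        pos_genes = sorted(rng.choice(gene_ids, size=spec.n_positives, replace=False))
        pos_proteins = tuple(protein_ids[gene_index[g]] for g in pos_genes)
        tp_idx = np.array([t - 1 for t in spec.informative_timepoints], dtype=int)
        affected: tuple = ()

        if spec.driver in ("expression", "mixed") and spec.expression_effect > 0:
            for gene in pos_genes:
                a, b = gene_row_slices[gene]
                log_expr[a:b][:, tp_idx] += spec.expression_effect
        if spec.driver in ("sequence", "mixed") and spec.seq_effect > 0:
            cols = np.sort(
                rng.choice(config.n_seq_features, size=spec.n_seq_affected,
                           replace=False)
            )
            affected = tuple(seq_names[c] for c in cols)
            pos_rows = [gene_index[g] for g in pos_genes]
            seq_values[np.ix_(pos_rows, cols)] += spec.seq_effect

        manifest.terms[term_id] = TermTruth(
            term_id=term_id,
            namespace=ns,
            driver=spec.driver,
            informative_timepoints=tuple(spec.informative_timepoints),
            affected_seq_features=affected,
            positive_proteins=pos_proteins,
        )
        triples.extend((p, term_id, "IEA") for p in pos_proteins)

    frame = pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "protein_id", "isoform_length"]
    )
    expr = np.exp(log_expr)
    for t, label in enumerate(TIME_LABELS):
        frame[label] = expr[:, t]
    expression = TranscriptExpressionTable(frame, TIME_LABELS)

    seq_frame = pd.DataFrame(seq_values, index=protein_ids, columns=seq_names)
    seq_frame.index.name = "protein_id"
    seq_features = FeatureMatrix(seq_frame, "Seq")

    return Benchmark(
        expression=expression,
        seq_features=seq_features,
        dag=dag,
        annotations=AnnotationSet.from_iterable(triples),
        manifest=manifest,
    )


def write_benchmark(bench: Benchmark, out_dir) -> dict:
    """Write a benchmark's four standard files plus the truth manifest.

    Returns the mapping of artifact name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "seq_features": out / "seq_features.tsv",
        "obo": out / "go.obo",
        "gaf": out / "annotations.gaf",
        "truth": out / "truth.json",
    }
    io_formats.write_transcript_expression(bench.expression, paths["expression"])
    io_formats.write_feature_matrix(bench.seq_features, paths["seq_features"])
    io_formats.write_obo(bench.dag, paths["obo"])
    io_formats.write_gaf(bench.annotations, paths["gaf"], bench.dag)
    bench.manifest.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def worked_example_gene() -> TranscriptExpressionTable:
    """A deterministic one-gene table with three transcripts whose expression
    values are pairwise distinct at every time-point.

    The isoform lengths are distinct, so the main transcript is the longest
    isoform (the first row) and every Num value equals 3.
    """
    t = np.arange(1, N_TIMEPOINTS + 1, dtype=float)
    profiles = {
        "gene00001.t1": (620, 12.0 + 0.5 * t),   # longest isoform -> main
        "gene00001.t2": (430, 8.0 + 0.3 * t),
        "gene00001.t3": (310, 3.0 + 0.1 * t),
    }
    rows = []
    for i, (tid, (length, profile)) in enumerate(profiles.items(), start=1):
        rows.append([tid, "gene00001", f"prot00001.{i}", length, *profile])
    frame = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "protein_id", "isoform_length",
                 *TIME_LABELS],
    )
    return TranscriptExpressionTable(frame, TIME_LABELS)
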