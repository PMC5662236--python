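"""End-to-end orchestration: simulate -> features -> build -> train ->
predict -> evaluate -> importance.

Every stage reads its inputs from disk and writes its outputs to a fixed
location under the run directory, so a partially complete run can resume:
a stage is skipped when all of its outputs already exist and nothing
upstream was re-run. A single root seed derives per-stage seeds by fixed
offsets, and per-term seeds by the term's position in the sorted term list,
so two runs with the same config produce byte-identical prediction and RFI
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd

from . import io_formats
from .classifier_bank import ClassifierSpec, default_specs, select_opt_classifier
from .containers import NAMESPACES
from .dataset_builder import (
    GoTermDataset,
    build_datasets,
    propagate_annotations,
    select_terms,
)
from .errors import ParameterError
from .evaluation import auroc, confusion_at_threshold, mcc
from .expression_features import compose_feature_group, gene_to_protein_features
from .importance import (
    cluster_profiles,
    expression_profile,
    forest_importance,
    high_relevance_terms,
)
from .synthetic_data import BenchmarkConfig, generate_benchmark, write_benchmark

logger = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {
    "simulate": 11,
    "build": 23,
    "train": 37,
    "importance": 53,
}

#: Per-namespace feature-group selections used for training; the defaults are
#: the best-performing combinations per namespace (all four groups for BP and
#: MF, sequence plus Ave and Main for CC).
DEFAULT_GROUPS = {
    "BP": ("Seq", "Num", "Ave", "Main"),
    "MF": ("Seq", "Num", "Ave", "Main"),
    "CC": ("Seq", "Ave", "Main"),
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every switch has a default."""

    out_dir: str
    seed: int = 17
    benchmark: Optional[BenchmarkConfig] = field(default_factory=BenchmarkConfig)
    # external inputs, used when `benchmark` is None
    expression_path: Optional[str] = None
    seq_features_path: Optional[str] = None
    obo_path: Optional[str] = None
    gaf_path: Optional[str] = None
    # feature construction
    num_mode: str = "distinct"
    tolerance: float = 0.0
    # dataset construction
    evidence_exclude: tuple = ()
    min_positives: int = 100
    train_fraction: float = 0.7
    # classifiers
    rf_trees: int = 500
    ada_learners: int = 200
    knn_k: int = 5
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    # reporting / interpretation
    prediction_threshold: float = 0.5
    rfi_threshold: float = 0.7
    rf_only_importance: bool = False

    def __post_init__(self):
        self.evidence_exclude = tuple(self.evidence_exclude)
        for ns, sel in self.groups.items():
            if ns not in NAMESPACES:
                raise ParameterError(f"unknown namespace in groups: {ns!r}")
            bad = set(sel) - {"Seq", "Num", "Ave", "Main"}
            if bad:
                raise ParameterError(f"unknown feature group(s) for {ns}: {sorted(bad)}")
            self.groups[ns] = tuple(sel)
        if self.benchmark is None:
            missing = [
                name
                for name in ("expression_path", "seq_features_path", "obo_path",
                             "gaf_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise ParameterError(
                    f"no benchmark config and missing input path(s): {missing}"
                )

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["benchmark"] = self.benchmark.to_dict() if self.benchmark else None
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        bench = d.pop("benchmark", None)
        config = cls(
            benchmark=BenchmarkConfig.from_dict(bench) if bench else None, **d
        )
        return config

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED_OFFSETS[stage]) % (2**31)


# ---------------------------------------------------------------------------
# stage implementations (path -> path, callable standalone from the CLI)
# ---------------------------------------------------------------------------

def stage_features(
    expression_path, out_path, num_mode: str = "distinct", tolerance: float = 0.0
) -> None:
    """Expression TSV -> per-protein Num/Ave/Main feature TSV."""
    table = io_formats.read_transcript_expression(expression_path)
    matrix = gene_to_protein_features(table, tolerance=tolerance, num_mode=num_mode)
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    io_formats.write_feature_matrix(matrix, out_path)


def _load_feature_blocks(seq_features_path, expression_features_path) -> list:
    return [
        io_formats.read_feature_matrix(seq_features_path, group="Seq"),
        io_formats.read_expression_features(expression_features_path),
    ]


def _term_filename(term_id: str) -> str:
    return term_id.replace(":", "_")


def stage_build(
    seq_features_path,
    expression_features_path,
    obo_path,
    gaf_path,
    out_dir,
    min_positives: int = 100,
    evidence_exclude: tuple = (),
    train_fraction: float = 0.7,
    seed: int = 0,
) -> list:
    """Annotations + features -> per-term labeled, split datasets on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dag = io_formats.read_obo(obo_path)
    annotations = io_formats.read_gaf(gaf_path, dag, evidence_exclude)
    propagated = propagate_annotations(annotations, dag)
    terms = select_terms(propagated, dag, min_positives)

    blocks = _load_feature_blocks(seq_features_path, expression_features_path)
    full = compose_feature_group(blocks, ("Seq", "Num", "Ave", "Main"))
    datasets = build_datasets(terms, full, propagated, dag,
                              train_fraction=train_fraction, seed=seed)

    index = []
    for term, ds in datasets.items():
        entry = {
            "term_id": term,
            "namespace": ds.namespace,
            "n_positive": ds.n_positive,
            "n_proteins": len(ds.proteins),
        }
        index.append(entry)
        payload = {
            **entry,
            "proteins": ds.proteins,
            "labels": ds.labels.tolist(),
            "train_idx": ds.train_idx.tolist(),
            "test_idx": ds.test_idx.tolist(),
        }
        (out / f"{_term_filename(term)}.json").write_text(
            json.dumps(payload, sort_keys=True)
        )
    (out / "terms.json").write_text(json.dumps(sorted(index, key=lambda e: e["term_id"]),
                                               indent=1))
    return [e["term_id"] for e in index]


def _load_term_index(datasets_dir) -> list:
    return json.loads((Path(datasets_dir) / "terms.json").read_text())


def _load_dataset(datasets_dir, term_id, blocks, selection) -> GoTermDataset:
    payload = json.loads(
        (Path(datasets_dir) / f"{_term_filename(term_id)}.json").read_text()
    )
    matrix = compose_feature_group(blocks, selection).subset(payload["proteins"])
    return GoTermDataset(
        term_id=payload["term_id"],
        namespace=payload["namespace"],
        features=matrix,
        labels=np.asarray(payload["labels"], dtype=int),
        train_idx=np.asarray(payload["train_idx"], dtype=int),
        test_idx=np.asarray(payload["test_idx"], dtype=int),
    )


def stage_train(
    datasets_dir,
    seq_features_path,
    expression_features_path,
    models_dir,
    groups: Optional[dict] = None,
    seed: int = 0,
    rf_trees: int = 500,
    ada_learners: int = 200,
    knn_k: int = 5,
) -> None:
    """Select and fit the Opt-Classifier of every built term."""
    groups = dict(DEFAULT_GROUPS) if groups is None else groups
    out = Path(models_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = _load_feature_blocks(seq_features_path, expression_features_path)
    specs = default_specs(rf_trees, ada_learners, knn_k)
    for i, entry in enumerate(_load_term_index(datasets_dir)):
        term = entry["term_id"]
        selection = groups.get(entry["namespace"], ("Seq", "Num", "Ave", "Main"))
        dataset = _load_dataset(datasets_dir, term, blocks, selection)
        model = select_opt_classifier(dataset, specs, seed=(seed + 13 * i) % (2**31))
        joblib.dump(model, out / f"{_term_filename(term)}.joblib")
        meta = {
            "term_id": term,
            "namespace": entry["namespace"],
            "algorithm": model.algorithm,
            "groups": list(selection),
            "n_features": len(model.feature_names),
            "standardization": {
                "mean": np.round(model.mean, 6).tolist(),
                "scale": np.round(model.scale, 6).tolist(),
            },
            "cv": {
                alg: {
                    "mcc_per_fold": list(s.mcc_per_fold),
                    "auroc_per_fold": list(s.auroc_per_fold),
                    "mean_mcc": s.mean_mcc,
                    "mean_auroc": s.mean_auroc,
                }
                for alg, s in model.cv.items()
            },
        }
        (out / f"{_term_filename(term)}.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )


def _iter_models(models_dir, datasets_dir, blocks):
    for entry in _load_term_index(datasets_dir):
        term = entry["term_id"]
        model = joblib.load(Path(models_dir) / f"{_term_filename(term)}.joblib")
        meta = json.loads(
            (Path(models_dir) / f"{_term_filename(term)}.json").read_text()
        )
        dataset = _load_dataset(datasets_dir, term, blocks, tuple(meta["groups"]))
        yield term, model, meta, dataset


def stage_predict(
    models_dir,
    datasets_dir,
    seq_features_path,
    expression_features_path,
    out_path,
    threshold: float = 0.5,
) -> None:
    """Score every term's held-out test proteins and write one TSV."""
    blocks = _load_feature_blocks(seq_features_path, expression_features_path)
    records = []
    for term, model, _meta, dataset in _iter_models(models_dir, datasets_dir, blocks):
        test_proteins = [dataset.proteins[i] for i in dataset.test_idx]
        conf = model.predict_confidence(dataset.features.subset(test_proteins))
        for protein, c in zip(test_proteins, conf):
            records.append(
                io_formats.PredictionRecord(protein, term, float(c),
                                            int(c > threshold))
            )
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    io_formats.write_predictions(records, out_path)


def stage_evaluate(
    models_dir,
    datasets_dir,
    seq_features_path,
    expression_features_path,
    report_dir,
    threshold: float = 0.5,
) -> None:
    """Test-set MCC/AUROC per term plus a per-namespace summary."""
    out = Path(report_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = _load_feature_blocks(seq_features_path, expression_features_path)
    rows = []
    for term, model, meta, dataset in _iter_models(models_dir, datasets_dir, blocks):
        test_proteins = [dataset.proteins[i] for i in dataset.test_idx]
        conf = model.predict_confidence(dataset.features.subset(test_proteins))
        y = dataset.y_test
        test_mcc = mcc(confusion_at_threshold(conf, y, threshold))
        test_auroc = auroc(conf, y) if len(np.unique(y)) == 2 else float("nan")
        rows.append(
            {
                "term_id": term,
                "namespace": meta["namespace"],
                "algorithm": meta["algorithm"],
                "cv_mean_mcc": meta["cv"][meta["algorithm"]]["mean_mcc"],
                "cv_mean_auroc": meta["cv"][meta["algorithm"]]["mean_auroc"],
                "test_mcc": test_mcc,
                "test_auroc": test_auroc,
            }
        )
    frame = pd.DataFrame(rows).sort_values("term_id")
    frame.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
    summary = {}
    for ns in NAMESPACES:
        sub = frame[frame["namespace"] == ns]
        if sub.empty:
            continue
        summary[ns] = {
            "n_terms": int(len(sub)),
            "mean_test_mcc": float(sub["test_mcc"].mean()),
            "mean_test_auroc": float(sub["test_auroc"].mean()),
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def stage_importance(
    models_dir,
    datasets_dir,
    seq_features_path,
    expression_features_path,
    rfi_dir,
    threshold: float = 0.7,
    rf_only: bool = False,
    seed: int = 0,
    rf_trees: int = 500,
) -> None:
    """Per-term RFI profiles over time-points and stages, the >threshold
    screen, and hierarchical clustering of the profiles.

    Terms whose Opt-Classifier is not a forest are either skipped
    (`rf_only`) or analysed through a forest refitted on the same training
    split purely for interpretation.
    """
    out = Path(rfi_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = _load_feature_blocks(seq_features_path, expression_features_path)
    profiles = []
    for i, (term, model, meta, dataset) in enumerate(
        _iter_models(models_dir, datasets_dir, blocks)
    ):
        if model.algorithm == "RF":
            fi = forest_importance(model)
        elif rf_only:
            logger.info("importance: skipping %s (Opt-Classifier %s)", term,
                        model.algorithm)
            continue
        else:
            rf = ClassifierSpec("RF", (("n_estimators", rf_trees),)).build(
                seed=(seed + 13 * i) % (2**31)
            )
            X = (dataset.X_train - model.mean) / model.scale
            rf.fit(X, dataset.y_train)
            fi = forest_importance(rf, feature_names=model.feature_names)
        groups = dataset.features.groups.to_dict()
        profiles.append(expression_profile(term, fi, groups))

    stage_names = list(profiles[0].rfi_stage) if profiles else []
    with open(out / "profiles.tsv", "w", encoding="utf-8") as fh:
        cols = (
            ["term_id"]
            + [f"t{i:02d}" for i in range(1, 31)]
            + stage_names
            + ["fi_max_global", "fi_max_local"]
        )
        fh.write("\t".join(cols) + "\n")
        for p in sorted(profiles, key=lambda p: p.term_id):
            vals = [f"{v:.6f}" for v in p.rfi_timepoint]
            vals += [f"{p.rfi_stage[s]:.6f}" for s in stage_names]
            vals += [f"{p.fi_max_global:.6g}", f"{p.fi_max_local:.6g}"]
            fh.write("\t".join([p.term_id] + vals) + "\n")

    screened = high_relevance_terms(profiles, threshold)
    (out / "screened_terms.txt").write_text("\n".join(sorted(screened)) + "\n")

    if len(profiles) >= 2:
        clustering = cluster_profiles(sorted(profiles, key=lambda p: p.term_id))
        (out / "clustering.json").write_text(
            json.dumps(
                {
                    "order": clustering.order,
                    "linkage": np.round(clustering.linkage, 8).tolist(),
                },
                indent=1,
            )
        )
    else:
        (out / "clustering.json").write_text(json.dumps({"order": [], "linkage": []}))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    out_dir: str
    manifest: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, resume: bool = True) -> PipelineResult:
    """Run all stages in order, skipping completed ones when resuming."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.benchmark is not None:
        bench_dir = out / "bench"
        input_paths = {
            "expression": bench_dir / "expression.tsv",
            "seq_features": bench_dir / "seq_features.tsv",
            "obo": bench_dir / "go.obo",
            "gaf": bench_dir / "annotations.gaf",
        }
    else:
        input_paths = {
            "expression": Path(config.expression_path),
            "seq_features": Path(config.seq_features_path),
            "obo": Path(config.obo_path),
            "gaf": Path(config.gaf_path),
        }

    features_path = out / "features" / "expression_features.tsv"
    datasets_dir = out / "datasets"
    models_dir = out / "models"
    predictions_path = out / "predictions.tsv"
    report_dir = out / "report"
    rfi_dir = out / "rfi"

    def simulate():
        bench_config = dataclasses.replace(
            config.benchmark, seed=config.stage_seed("simulate")
        )
        write_benchmark(generate_benchmark(bench_config), out / "bench")

    def features():
        stage_features(input_paths["expression"], features_path,
                       config.num_mode, config.tolerance)

    def build():
        stage_build(
            input_paths["seq_features"], features_path, input_paths["obo"],
            input_paths["gaf"], datasets_dir,
            min_positives=config.min_positives,
            evidence_exclude=config.evidence_exclude,
            train_fraction=config.train_fraction,
            seed=config.stage_seed("build"),
        )

    def train():
        stage_train(
            datasets_dir, input_paths["seq_features"], features_path, models_dir,
            groups=config.groups, seed=config.stage_seed("train"),
            rf_trees=config.rf_trees, ada_learners=config.ada_learners,
            knn_k=config.knn_k,
        )

    def predict():
        stage_predict(models_dir, datasets_dir, input_paths["seq_features"],
                      features_path, predictions_path,
                      threshold=config.prediction_threshold)

    def evaluate():
        stage_evaluate(models_dir, datasets_dir, input_paths["seq_features"],
                       features_path, report_dir,
                       threshold=config.prediction_threshold)

    def importance():
        stage_importance(
            models_dir, datasets_dir, input_paths["seq_features"], features_path,
            rfi_dir, threshold=config.rfi_threshold,
            rf_only=config.rf_only_importance,
            seed=config.stage_seed("importance"), rf_trees=config.rf_trees,
        )

    stages = []
    if config.benchmark is not None:
        stages.append(("simulate", list(input_paths.values()), simulate, ()))
    stages += [
        ("features", [features_path], features, ("simulate",)),
        ("build", [datasets_dir / "terms.json"], build, ("features",)),
        ("train", [models_dir / ".trained"], train, ("build",)),
        ("predict", [predictions_path], predict, ("train",)),
        ("evaluate", [report_dir / "metrics.tsv", report_dir / "summary.json"],
         evaluate, ("train",)),
        ("importance", [rfi_dir / "profiles.tsv", rfi_dir / "screened_terms.txt"],
         importance, ("train",)),
    ]

    executed = []
    for name, outputs, runner, deps in stages:
        done = all(Path(p).exists() for p in outputs)
        dep_ran = any(d in executed for d in deps)
        if resume and done and not dep_ran:
            logger.info("stage %s: outputs present, skipping", name)
            continue
        logger.info("stage %s: running", name)
        runner()
        if name == "train":
            (models_dir / ".trained").write_text("ok\n")
        executed.append(name)

    config.to_json(out / "run_config.json")
    manifest: dict = {"seed": config.seed, "executed": executed, "files": {}}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(str(out), manifest)
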