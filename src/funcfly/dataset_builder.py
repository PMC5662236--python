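"""Per-GO-term labeled datasets from annotations and a feature matrix.

Annotations are first closed under the true-path rule (a protein annotated
to a term is annotated to every ancestor via is_a/part_of within the term's
namespace). Each selected term then yields a binary dataset over the
proteins of the feature matrix -- positives are the annotated proteins,
negatives are all the rest -- which is split 7:3 into train and test,
stratified per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .containers import NAMESPACES, AnnotationSet, FeatureMatrix, GoDag
from .errors import DatasetError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class GoTermDataset:
    """Labeled protein set for one GO term, optionally train/test split."""

    term_id: str
    namespace: Optional[str]
    features: FeatureMatrix
    labels: np.ndarray
    train_idx: Optional[np.ndarray] = None
    test_idx: Optional[np.ndarray] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.features):
            raise DatasetError(
                f"{self.term_id}: label vector length {len(self.labels)} does not "
                f"match protein count {len(self.features)}"
            )

    @property
    def proteins(self) -> list:
        return list(self.features.proteins)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def is_split(self) -> bool:
        return self.train_idx is not None

    @property
    def X(self) -> np.ndarray:
        return self.features.values.to_numpy(dtype=float)

    def _require_split(self):
        if not self.is_split:
            raise DatasetError(f"{self.term_id}: dataset has not been split")

    @property
    def X_train(self) -> np.ndarray:
        self._require_split()
        return self.X[self.train_idx]

    @property
    def y_train(self) -> np.ndarray:
        self._require_split()
        return self.labels[self.train_idx]

    @property
    def X_test(self) -> np.ndarray:
        self._require_split()
        return self.X[self.test_idx]

    @property
    def y_test(self) -> np.ndarray:
        self._require_split()
        return self.labels[self.test_idx]


def propagate_annotations(annotations: AnnotationSet, dag: GoDag) -> AnnotationSet:
    """Close an annotation set under ancestry (the true-path rule).

    Every (protein, term) pair gains (protein, ancestor) for each ancestor
    reachable via is_a/part_of within the term's namespace; the evidence code
    of the originating annotation is carried along. The result is a superset
    of the input and the operation is idempotent.
    """
    out = set(annotations.triples)
    for protein_id, term_id, evidence in annotations.triples:
        if term_id not in dag:
            raise DatasetError(f"annotation references unknown term {term_id!r}")
        for ancestor in dag.ancestors(term_id):
            out.add((protein_id, ancestor, evidence))
    return AnnotationSet(frozenset(out))


def select_terms(
    annotations: AnnotationSet, dag: GoDag, min_positives: int = 100
) -> list:
    """Non-root terms with at least `min_positives` annotated proteins,
    sorted by namespace (BP, MF, CC) then term id.

    Expects propagated annotations; `min_positives` must be >= 2.
    """
    if min_positives < 2:
        raise ParameterError(f"min_positives must be >= 2, got {min_positives}")
    counts = annotations.term_counts()
    ns_rank = {ns: i for i, ns in enumerate(NAMESPACES)}
    selected = [
        t
        for t, n in counts.items()
        if n >= min_positives and t in dag and not dag.is_root(t)
    ]
    return sorted(selected, key=lambda t: (ns_rank[dag.namespace(t)], t))


def build_term_dataset(
    term_id: str,
    features: FeatureMatrix,
    annotations: AnnotationSet,
    dag: Optional[GoDag] = None,
) -> GoTermDataset:
    """Label the proteins of a feature matrix for one term.

    Positives are the term's (propagated) annotated proteins present in the
    matrix; all other matrix proteins are negatives. Annotated proteins
    missing from the matrix are dropped with a logged count; zero surviving
    positives raises :class:`DatasetError`.
    """
    annotated = annotations.proteins_for(term_id)
    present = set(features.proteins)
    missing = annotated - present
    if missing:
        logger.info(
            "%s: %d annotated protein(s) absent from the feature matrix",
            term_id,
            len(missing),
        )
    positives = annotated & present
    if not positives:
        raise DatasetError(
            f"{term_id}: no annotated protein present in the feature matrix"
        )
    labels = np.array([1 if p in positives else 0 for p in features.proteins])
    namespace = dag.namespace(term_id) if dag is not None and term_id in dag else None
    return GoTermDataset(term_id, namespace, features, labels)


def _train_size(n: int, fraction: float) -> int:
    # half-up rounding of fraction*n, clamped so each side keeps >= 1 member
    size = int(np.floor(fraction * n + 0.5))
    return max(1, min(n - 1, size))


def split_train_test(
    dataset: GoTermDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> GoTermDataset:
    """Stratified 7:3 split of a term dataset.

    Positives and negatives are each split with a per-class train size of
    round(`train_fraction` * class size); the shuffle is deterministic under
    `seed`. Requires at least two proteins of each class.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError(f"train_fraction must lie in (0, 1): {train_fraction}")
    labels = dataset.labels
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise DatasetError(
            f"{dataset.term_id}: need >= 2 positives and >= 2 negatives to split "
            f"(have {n_pos} / {n_neg})"
        )
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        k = _train_size(len(idx), train_fraction)
        train_parts.append(perm[:k])
        test_parts.append(perm[k:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return replace(dataset, train_idx=train_idx, test_idx=test_idx)


def build_datasets(
    terms: Sequence[str],
    features: FeatureMatrix,
    annotations: AnnotationSet,
    dag: Optional[GoDag] = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> dict:
    """Build and split datasets for several terms; terms that cannot be built
    or split are skipped with a warning. Each term's split seed is derived
    deterministically from `seed` and the term's position."""
    out = {}
    for i, term in enumerate(terms):
        try:
            ds = build_term_dataset(term, features, annotations, dag)
            out[term] = split_train_test(ds, train_fraction, seed=seed + 13 * i)
        except DatasetError as exc:
            logger.warning("skipping term %s: %s", term, exc)
    return out
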