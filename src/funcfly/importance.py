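"""Forest feature importance and its relative form over developmental stages.

For a trained random forest, the importance of a feature f is the mean over
trees of the total weighted Gini impurity decrease at the nodes splitting on
f, with each node weighted by the fraction of the tree's bootstrap sample
reaching it:

    FI_f = (1 / n_trees) * sum_tau sum_{j in tau, split on f}
           (n_j / n_root) * [ i(j) - (n_L/n_j) i(L) - (n_R/n_j) i(R) ]

The *relative feature importance* of an expression-derived feature compares
its FI to the global maximum over all features and to the local maximum over
the expression features:

    RFI_f = sqrt( (FI_f / FI_max_global) * (FI_f / FI_max_local) )

RFI reaches 1.0 exactly when a feature attains both maxima. Because RFI is
proportional to FI (RFI_f = FI_f / sqrt(FI_max_global * FI_max_local)),
taking per-time-point maxima across the Num/Ave/Main groups commutes with
the RFI transform.

Time-points map onto the four main developmental stages of the fly:
embryo T1-T12, larva T13-T18, pupa T19-T24, adult T25-T30. A term is
flagged as expression-relevant when its maximum stage RFI exceeds 0.7.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.ensemble import RandomForestClassifier

from .containers import N_TIMEPOINTS
from .errors import DegenerateModelError, ParameterError, ValidationError

#: 1-based inclusive time-point ranges of the main developmental stages.
STAGE_BOUNDARIES = {
    "embryo": (1, 12),
    "larva": (13, 18),
    "pupa": (19, 24),
    "adult": (25, 30),
}

#: Screening threshold on the maximum stage RFI.
RFI_THRESHOLD = 0.7

_TIMEPOINT_RE = re.compile(r"_t(\d{2})$")


def default_stage_map() -> dict:
    """Stage name -> tuple of 0-based time-point indices."""
    return {
        stage: tuple(range(lo - 1, hi))
        for stage, (lo, hi) in STAGE_BOUNDARIES.items()
    }


@dataclass
class ForestImportance:
    """Per-feature FI of one forest, with per-tree contributions for audit."""

    fi: pd.Series            # feature name -> FI_f (>= 0)
    n_trees: int
    per_tree: pd.DataFrame   # tree x feature contributions; FI = column mean


def _extract_forest(model):
    if isinstance(model, RandomForestClassifier):
        return model, None
    # duck-typed TrainedTermModel
    spec = getattr(model, "spec", None)
    inner = getattr(model, "model", None)
    if spec is not None and isinstance(inner, RandomForestClassifier):
        return inner, tuple(model.feature_names)
    raise TypeError(
        "forest_importance requires a fitted RandomForestClassifier "
        f"(or a term model wrapping one); got {type(model).__name__}"
    )


def forest_importance(
    model,
    feature_names: Optional[Sequence[str]] = None,
    denominator: str = "root",
    n_samples: Optional[int] = None,
) -> ForestImportance:
    """Mean weighted Gini impurity decrease per feature, averaged over trees.

    ``denominator`` selects the node-weight normalisation: ``"root"`` divides
    by the tree's bootstrap-sample weight at the root (the default, identical
    to textbook mean-decrease-impurity), ``"dataset"`` divides by `n_samples`.
    With scikit-learn's default bootstrap size the two coincide.
    """
    forest, inferred = _extract_forest(model)
    if denominator not in ("root", "dataset"):
        raise ParameterError(f"denominator must be 'root' or 'dataset': {denominator!r}")
    if feature_names is None:
        feature_names = inferred
    if feature_names is None:
        feature_names = tuple(
            getattr(forest, "feature_names_in_",
                    [f"f{i}" for i in range(forest.n_features_in_)])
        )
    if len(feature_names) != forest.n_features_in_:
        raise ValidationError(
            f"{len(feature_names)} feature names for {forest.n_features_in_} features"
        )

    n_trees = len(forest.estimators_)
    contributions = np.zeros((n_trees, forest.n_features_in_))
    for k, est in enumerate(forest.estimators_):
        t = est.tree_
        left, right = t.children_left, t.children_right
        w = t.weighted_n_node_samples
        imp = t.impurity
        internal = left >= 0
        if denominator == "root":
            denom = w[0]
        else:
            denom = float(n_samples if n_samples is not None else w[0])
        decrease = (
            w[internal] * imp[internal]
            - w[left[internal]] * imp[left[internal]]
            - w[right[internal]] * imp[right[internal]]
        ) / denom
        np.add.at(contributions[k], t.feature[internal], decrease)

    fi = pd.Series(contributions.mean(axis=0), index=list(feature_names), name="FI")
    per_tree = pd.DataFrame(contributions, columns=list(feature_names))
    return ForestImportance(fi=fi, n_trees=n_trees, per_tree=per_tree)


def relative_importance(
    fi, expression_feature_names: Iterable[str]
) -> pd.Series:
    """RFI of each expression-derived feature.

    `fi` is a :class:`ForestImportance` or a feature -> FI Series/mapping.
    Raises :class:`DegenerateModelError` when every FI is zero; when only the
    expression features are all-zero, their RFIs are all zero.
    """
    if isinstance(fi, ForestImportance):
        fi = fi.fi
    fi = pd.Series(fi, dtype=float)
    expr_names = list(expression_feature_names)
    missing = [n for n in expr_names if n not in fi.index]
    if missing:
        raise ValidationError(f"expression feature(s) absent from FI map: {missing[:5]}")
    gmax = float(fi.max())
    if gmax <= 0.0:
        raise DegenerateModelError("all feature importances are zero")
    lmax = float(fi.loc[expr_names].max())
    if lmax <= 0.0:
        return pd.Series(0.0, index=expr_names, name="RFI")
    rfi = np.sqrt((fi.loc[expr_names] / gmax) * (fi.loc[expr_names] / lmax))
    return rfi.rename("RFI")


def collapse_timepoints(group_values: Mapping) -> np.ndarray:
    """Per-time-point maximum across the Num/Ave/Main groups present.

    `group_values` maps a group name to its 30 per-time-point values; e.g.
    values (0.2, 0.5, 0.4) at one time-point collapse to 0.5.
    """
    if not group_values:
        raise ParameterError("at least one feature group is required")
    stacked = []
    for group, values in group_values.items():
        values = np.asarray(values, dtype=float)
        if values.shape != (N_TIMEPOINTS,):
            raise ParameterError(
                f"group {group!r} must provide {N_TIMEPOINTS} values, "
                f"got shape {values.shape}"
            )
        stacked.append(values)
    return np.max(np.vstack(stacked), axis=0)


def stage_summary(
    values: Sequence[float], stage_map: Optional[Mapping] = None
) -> dict:
    """Per-stage maximum of a 30-point profile.

    `stage_map` maps stage name -> 0-based time-point indices and must
    partition 0..29; defaults to embryo/larva/pupa/adult boundaries.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (N_TIMEPOINTS,):
        raise ParameterError(f"expected a {N_TIMEPOINTS}-point profile")
    if stage_map is None:
        stage_map = default_stage_map()
    covered: list = []
    for idx in stage_map.values():
        covered.extend(idx)
    if sorted(covered) != list(range(N_TIMEPOINTS)):
        raise ParameterError("stage_map must partition time-points 0..29")
    return {stage: float(values[list(idx)].max()) for stage, idx in stage_map.items()}


@dataclass
class ImportanceProfile:
    """Collapsed RFI profile of one term's forest."""

    term_id: str
    rfi_timepoint: np.ndarray   # 30 values in [0, 1]
    rfi_stage: dict             # stage -> max RFI over the stage's time-points
    fi_max_global: float
    fi_max_local: float

    @property
    def max_stage_rfi(self) -> float:
        return max(self.rfi_stage.values())


def expression_profile(
    term_id: str,
    fi: ForestImportance,
    feature_groups: Mapping,
    stage_map: Optional[Mapping] = None,
) -> ImportanceProfile:
    """Build the collapsed per-time-point / per-stage RFI profile of a term.

    `feature_groups` maps each feature name to its group; expression columns
    must end in ``_tNN`` with NN in 01..30.
    """
    groups = pd.Series(dict(feature_groups), dtype=object)
    expr_names = [n for n, g in groups.items() if g in ("Num", "Ave", "Main")]
    if not expr_names:
        raise ParameterError(f"{term_id}: no expression features in the group map")
    rfi = relative_importance(fi, expr_names)

    per_group: dict = {}
    for name in expr_names:
        m = _TIMEPOINT_RE.search(name)
        if m is None:
            raise ValidationError(f"cannot parse time-point from feature {name!r}")
        t = int(m.group(1)) - 1
        if not 0 <= t < N_TIMEPOINTS:
            raise ValidationError(f"time-point out of range in feature {name!r}")
        vec = per_group.setdefault(groups[name], np.zeros(N_TIMEPOINTS))
        vec[t] = rfi[name]

    collapsed = collapse_timepoints(per_group)
    stages = stage_summary(collapsed, stage_map)
    fi_series = fi.fi if isinstance(fi, ForestImportance) else pd.Series(fi, dtype=float)
    return ImportanceProfile(
        term_id=term_id,
        rfi_timepoint=collapsed,
        rfi_stage=stages,
        fi_max_global=float(fi_series.max()),
        fi_max_local=float(fi_series.loc[expr_names].max()),
    )


def high_relevance_terms(
    profiles: Iterable[ImportanceProfile], threshold: float = RFI_THRESHOLD
) -> list:
    """Terms whose maximum stage RFI strictly exceeds `threshold`."""
    return [p.term_id for p in profiles if p.max_stage_rfi > threshold]


@dataclass
class ProfileClustering:
    """Agglomerative clustering of RFI profiles (Euclidean, average linkage)."""

    term_ids: list          # input order
    linkage: np.ndarray     # scipy linkage matrix
    order: list             # term ids in dendrogram leaf order

    def n_profiles(self) -> int:
        return len(self.term_ids)


def cluster_profiles(profiles: Sequence[ImportanceProfile]) -> ProfileClustering:
    """Hierarchically cluster terms by their 30-point RFI profiles."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ParameterError("clustering requires at least two profiles")
    X = np.vstack([p.rfi_timepoint for p in profiles])
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    leaf_order = hierarchy.leaves_list(Z)
    ids = [p.term_id for p in profiles]
    return ProfileClustering(
        term_ids=ids, linkage=Z, order=[ids[i] for i in leaf_order]
    )
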