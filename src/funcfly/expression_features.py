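"""Num / Ave / Main feature families from transcript-level expression.

For each gene and each of the 30 time-points the three families summarise
the gene's isoform-level expression:

* ``Num`` -- how many *differently expressed* transcripts the gene shows at
  that time-point, implemented as the number of equivalence classes of the
  transcript expression values under an absolute tolerance (default 0, i.e.
  the count of distinct values). An alternative reading -- the count of
  transcripts expressed above the tolerance -- is available via
  ``num_mode="expressed"``.
* ``Ave`` -- the arithmetic mean expression over all the gene's transcripts.
* ``Main`` -- the profile of the gene's *main transcript*: the isoform with
  the longest protein sequence, ties broken by the larger total expression
  summed over the 30 time-points, then by lexicographically smallest id.

Proteins inherit the features of their (unique) gene, and the per-group
blocks compose with sequence-derived features in the fixed order
Seq, Num, Ave, Main.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    FEATURE_GROUPS,
    N_TIMEPOINTS,
    FeatureMatrix,
    TranscriptExpressionTable,
)
from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical expression-feature column names, per group.
EXPRESSION_COLUMNS = {
    "Num": tuple(f"num_t{i:02d}" for i in range(1, N_TIMEPOINTS + 1)),
    "Ave": tuple(f"ave_t{i:02d}" for i in range(1, N_TIMEPOINTS + 1)),
    "Main": tuple(f"main_t{i:02d}" for i in range(1, N_TIMEPOINTS + 1)),
}


@dataclass
class GeneExpressionFeatures:
    """The three 30-point feature vectors of one gene."""

    gene_id: str
    num: np.ndarray
    ave: np.ndarray
    main: np.ndarray
    main_transcript_id: str


def _expr_block(transcripts: pd.DataFrame, time_labels: Sequence[str]) -> np.ndarray:
    if transcripts.empty:
        raise ParameterError("transcript list of a gene must be non-empty")
    return transcripts.loc[:, list(time_labels)].to_numpy(dtype=float)


def select_main_transcript(
    transcripts: pd.DataFrame, time_labels: Sequence[str]
) -> str:
    """Pick a gene's main transcript.

    Selection rule: (1) longest isoform; (2) among ties, largest expression
    summed over the 30 time-points; (3) among remaining ties, smallest
    transcript id. The rule is total, so a unique id is always returned.
    """
    expr = _expr_block(transcripts, time_labels)
    totals = expr.sum(axis=1)
    keyed = [
        (-int(length), -float(total), str(tid))
        for tid, length, total in zip(
            transcripts["transcript_id"], transcripts["isoform_length"], totals
        )
    ]
    return min(keyed)[2]


def compute_num(
    transcripts: pd.DataFrame,
    time_labels: Sequence[str],
    tolerance: float = 0.0,
    num_mode: str = "distinct",
) -> np.ndarray:
    """Per-time-point count of differently expressed transcripts.

    ``distinct`` mode counts equivalence classes of the expression values,
    where values chained within `tolerance` of each other fall in one class
    (tolerance 0 counts distinct values). ``expressed`` mode counts
    transcripts with expression strictly above `tolerance`.
    """
    if tolerance < 0:
        raise ParameterError(f"tolerance must be >= 0, got {tolerance}")
    if num_mode not in ("distinct", "expressed"):
        raise ParameterError(f"num_mode must be 'distinct' or 'expressed': {num_mode!r}")
    expr = _expr_block(transcripts, time_labels)
    if num_mode == "expressed":
        return (expr > tolerance).sum(axis=0).astype(int)
    svals = np.sort(expr, axis=0)
    if svals.shape[0] == 1:
        return np.ones(expr.shape[1], dtype=int)
    return (1 + (np.diff(svals, axis=0) > tolerance).sum(axis=0)).astype(int)


def compute_ave(
    transcripts: pd.DataFrame, time_labels: Sequence[str]
) -> np.ndarray:
    """Arithmetic mean expression per time-point over all transcripts."""
    return _expr_block(transcripts, time_labels).mean(axis=0)


def compute_main(
    transcripts: pd.DataFrame, time_labels: Sequence[str]
) -> np.ndarray:
    """Expression profile of the main transcript."""
    main_id = select_main_transcript(transcripts, time_labels)
    row = transcripts[transcripts["transcript_id"] == main_id]
    return _expr_block(row, time_labels)[0]


def gene_features(
    table: TranscriptExpressionTable,
    gene_id: str,
    tolerance: float = 0.0,
    num_mode: str = "distinct",
) -> GeneExpressionFeatures:
    """Num/Ave/Main vectors of one gene in a table."""
    sub = table.transcripts_of(gene_id)
    return GeneExpressionFeatures(
        gene_id=gene_id,
        num=compute_num(sub, table.time_labels, tolerance, num_mode),
        ave=compute_ave(sub, table.time_labels),
        main=compute_main(sub, table.time_labels),
        main_transcript_id=select_main_transcript(sub, table.time_labels),
    )


def gene_to_protein_features(
    table: TranscriptExpressionTable,
    tolerance: float = 0.0,
    num_mode: str = "distinct",
) -> FeatureMatrix:
    """One 90-column row per protein: the Num, Ave and Main vectors of its gene.

    Every protein must map to exactly one gene; a protein appearing under
    several genes raises :class:`ValidationError`.
    """
    pairs = table.protein_gene_pairs()
    multi = pairs["protein_id"][pairs["protein_id"].duplicated()]
    if len(multi):
        raise ValidationError(
            f"protein(s) mapped to multiple genes: {sorted(set(multi))}"
        )

    per_gene = {
        gene_id: gene_features(table, gene_id, tolerance, num_mode)
        for gene_id in table.gene_ids
    }
    columns = (
        list(EXPRESSION_COLUMNS["Num"])
        + list(EXPRESSION_COLUMNS["Ave"])
        + list(EXPRESSION_COLUMNS["Main"])
    )
    rows = {}
    for protein_id, gene_id in pairs.itertuples(index=False):
        feats = per_gene[gene_id]
        rows[protein_id] = np.concatenate(
            [feats.num.astype(float), feats.ave, feats.main]
        )
    values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    values.index.name = "protein_id"
    groups = {c: g for g in ("Num", "Ave", "Main") for c in EXPRESSION_COLUMNS[g]}
    return FeatureMatrix(values, groups)


def compose_feature_group(
    blocks: Iterable[FeatureMatrix], selection: Iterable[str]
) -> FeatureMatrix:
    """Horizontally concatenate the selected groups in fixed order
    Seq, Num, Ave, Main.

    All blocks must cover a common protein set; proteins missing from any
    block carrying a selected group are dropped with a logged count.
    """
    blocks = list(blocks)
    selection = set(selection)
    if not selection:
        raise ParameterError("feature-group selection must be non-empty")
    unknown = selection - set(FEATURE_GROUPS)
    if unknown:
        raise ParameterError(f"unknown feature group(s): {sorted(unknown)}")

    relevant = [b for b in blocks if selection & set(b.present_groups())]
    if not relevant:
        raise ParameterError(f"no block provides any of the groups {sorted(selection)}")

    proteins = list(relevant[0].proteins)
    common = set(proteins)
    universe = set(proteins)
    for b in relevant[1:]:
        common &= set(b.proteins)
        universe |= set(b.proteins)
    dropped = len(universe) - len(common)
    if dropped:
        logger.info("compose_feature_group: dropped %d protein(s) missing from "
                    "at least one selected block", dropped)
    proteins = [p for p in proteins if p in common]

    pieces = []
    seen_cols: set = set()
    for group in FEATURE_GROUPS:
        if group not in selection:
            continue
        for b in relevant:
            cols = b.group_columns(group)
            if not cols:
                continue
            clash = seen_cols & set(cols)
            if clash:
                raise ValidationError(f"duplicated feature column(s): {sorted(clash)}")
            seen_cols |= set(cols)
            piece = b.values.loc[proteins, cols]
            pieces.append((piece, pd.Series(group, index=cols, dtype=object)))

    values = pd.concat([p for p, _g in pieces], axis=1)
    groups = pd.concat([g for _p, g in pieces])
    return FeatureMatrix(values, groups)
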