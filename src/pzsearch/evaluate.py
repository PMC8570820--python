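"""Precision/recall evaluation against Smith-Waterman ground truth.

Ground truth is the set of (query, subject) pairs whose *optimal* local
alignment (full Smith-Waterman, affine gaps) reaches the E-value threshold —
the role SSEARCH plays when benchmarking heuristic aligners.  A "hit" is a
query-subject pair (the best HSP of the pair), so precision and recall count
subject sequences, not alignment segments.

Rates are *truncated* (floored) at the second decimal, not rounded:
215/303, 221/303 and 224/303 print as 70.95, 72.93 and 73.92 under this
convention.  Display strings trim trailing zeros (``91.8``, ``100``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import HitTableFormatError
from .extend import smith_waterman_score
from .scoring import (
    KarlinAltschulParams,
    SubstitutionMatrix,
    default_params,
    evalue as ka_evalue,
    load_matrix,
)
from .seqio import AminoAcidSequence, HitRecord, read_hits_tab

Pair = tuple[str, str]


@dataclass
class GroundTruth:
    """All query-subject pairs whose optimal alignment meets the threshold."""

    threshold: float
    pairs: set[Pair]
    scores: dict[Pair, tuple[int, float]] = field(default_factory=dict)
    total_reference_residues: int = 0

    def pairs_for(self, query_id: str) -> set[Pair]:
        return {p for p in self.pairs if p[0] == query_id}


def make_ground_truth(
    queries: Sequence[AminoAcidSequence],
    reference: Sequence[AminoAcidSequence],
    threshold: float = 1e-8,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    params: KarlinAltschulParams | None = None,
    total_reference_residues: int | None = None,
) -> GroundTruth:
    """Exhaustive Smith-Waterman over all query-subject pairs.

    Feasible at desk scale only (full dynamic programming per pair).  The
    E-value search space uses the total reference residue count so truths are
    directly comparable with heuristic search output on the same reference.
    """
    matrix = matrix or load_matrix()
    params = params or default_params(matrix.name, gap_open, gap_extend)
    n_total = total_reference_residues or sum(len(s) for s in reference)
    senc = [(s.id, matrix.encode(s.residues), len(s)) for s in reference]
    pairs: set[Pair] = set()
    scores: dict[Pair, tuple[int, float]] = {}
    for q in queries:
        qenc = matrix.encode(q.residues)
        for sid, se, _slen in senc:
            raw = smith_waterman_score(qenc, se, matrix.array, gap_open, gap_extend)
            e = ka_evalue(raw, len(q), n_total, params)
            if e <= threshold:
                pairs.add((q.id, sid))
                scores[(q.id, sid)] = (raw, e)
    return GroundTruth(
        threshold=threshold,
        pairs=pairs,
        scores=scores,
        total_reference_residues=n_total,
    )


def truncate_pct(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` floored at the second decimal.

    Computed in integer arithmetic so the truncation is exact.
    """
    if denominator == 0:
        raise ZeroDivisionError("truncate_pct with zero denominator")
    return (10_000 * numerator // denominator) / 100.0


def format_rate(rate: float | None) -> str:
    """Display form: two decimals with trailing zeros trimmed; ``NA`` for None."""
    if rate is None:
        return "NA"
    text = f"{rate:.2f}".rstrip("0").rstrip(".")
    return text if text else "0"


def precision_recall(
    predicted: set[Pair], truth: set[Pair]
) -> tuple[float | None, float | None, int]:
    """(precision_pct, recall_pct, true_positives), truncated at 2 decimals.

    Precision is undefined (None) when nothing was predicted but truth is
    non-empty; recall is undefined when truth is empty but predictions exist.
    When both sets are empty the search was vacuously perfect (100, 100).
    """
    tp = len(predicted & truth)
    if not predicted and not truth:
        return 100.0, 100.0, 0
    precision = truncate_pct(tp, len(predicted)) if predicted else None
    recall = truncate_pct(tp, len(truth)) if truth else None
    return precision, recall, tp


@dataclass
class EvaluationReport:
    """Per-query and pooled precision/recall at one E-value threshold."""

    threshold: float
    table: pd.DataFrame  # columns: query_id, predicted_hits, true_positives,
    #                                precision_pct, recall_pct ("ALL" row pools)

    @property
    def overall(self) -> pd.Series:
        return self.table[self.table["query_id"] == "ALL"].iloc[0]


def _predicted_pairs(hits: Iterable[HitRecord], threshold: float) -> set[Pair]:
    return {h.pair for h in hits if h.evalue <= threshold}


def evaluate_tool(
    hits, truth: GroundTruth, threshold: float | None = None
) -> EvaluationReport:
    """Score a tool's 12-column hit table against ground truth.

    *hits* is a path to a tabular file or an iterable of :class:`HitRecord`.
    Duplicate rows for one query-subject pair count once.
    """
    threshold = truth.threshold if threshold is None else threshold
    if isinstance(hits, (str, bytes)) or hasattr(hits, "__fspath__"):
        records = read_hits_tab(hits)
    else:
        records = list(hits)
    predicted = _predicted_pairs(records, threshold)
    query_ids = sorted({p[0] for p in predicted} | {p[0] for p in truth.pairs})
    rows = []
    for qid in query_ids:
        pred_q = {p for p in predicted if p[0] == qid}
        truth_q = {p for p in truth.pairs if p[0] == qid}
        prec, rec, tp = precision_recall(pred_q, truth_q)
        rows.append((qid, len(pred_q), tp, prec, rec))
    prec, rec, tp = precision_recall(predicted, truth.pairs)
    rows.append(("ALL", len(predicted), tp, prec, rec))
    table = pd.DataFrame(
        rows,
        columns=["query_id", "predicted_hits", "true_positives", "precision_pct", "recall_pct"],
    )
    return EvaluationReport(threshold=threshold, table=table)


def write_truth_tsv(truth: GroundTruth, path) -> None:
    """Pairs with oracle raw score and E-value, one row per pair."""
    rows = sorted(truth.pairs)
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\traw_score\tevalue\n")
        for qid, sid in rows:
            raw, e = truth.scores.get((qid, sid), (0, float("nan")))
            fh.write(f"{qid}\t{sid}\t{raw}\t{e:.3e}\n")


def read_truth_tsv(path, threshold: float = 1e-8) -> GroundTruth:
    pairs: set[Pair] = set()
    scores: dict[Pair, tuple[int, float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query_id\t"):
            raise HitTableFormatError(f"{path}: missing truth header row")
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise HitTableFormatError(f"{path}: row {ln}: expected 4 columns")
            e = float(parts[3])
            if e <= threshold:
                pairs.add((parts[0], parts[1]))
                scores[(parts[0], parts[1])] = (int(parts[2]), e)
    return GroundTruth(threshold=threshold, pairs=pairs, scores=scores)
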