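"""Per-cluster carriage fractions, dual-threshold marker filtering, ranking.

For every ortholog cluster the carriage fraction is computed separately in
the target and the background group; a cluster passes the *enriched* filter
when it is carried by at least ``min_target_fraction`` of target genomes and
at most ``max_background_fraction`` of background genomes.  *Depleted* mode
mirrors the thresholds to find clusters characteristically missing from the
target group (a transcription-regulator-like pattern).

The ranking score is ``f_target - f_background``; survivors are ordered by
``|score|`` descending with lexicographic tie-break, which is the simplest
monotone statistic consistent with the dual-threshold semantics.  A
hypergeometric tail p-value is also emitted for reference but never used
for filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom

from .groups import BACKGROUND, GroupLabelError, GroupLabels
from .matrix import MatrixError, PresenceAbsenceMatrix

__all__ = ["MarkerStats", "Thresholds", "compute_group_fractions",
           "filter_markers", "stratified_counts"]


@dataclass(frozen=True)
class MarkerStats:
    """Carriage statistics of one cluster in the two groups."""

    cluster_id: str
    n_target_present: int
    n_target: int
    n_background_present: int
    n_background: int
    f_target: float
    f_background: float
    score: float
    #: one-sided hypergeometric P(X >= n_target_present) under random carriage;
    #: reference column only, never used by the threshold filter
    p_hypergeom: float

    TSV_FIELDS = ("cluster_id", "n_target_present", "n_target",
                  "n_background_present", "n_background",
                  "f_target", "f_background", "score", "p_hypergeom")


@dataclass(frozen=True)
class Thresholds:
    """Dual carriage-fraction thresholds for marker filtering."""

    min_target_fraction: float
    max_background_fraction: float
    mode: Literal["enriched", "depleted"] = "enriched"

    def __post_init__(self) -> None:
        for name in ("min_target_fraction", "max_background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.mode not in ("enriched", "depleted"):
            raise ValueError(f"mode must be enriched/depleted, got {self.mode!r}")

    def accepts(self, f_target: float, f_background: float) -> bool:
        if self.mode == "enriched":
            return (f_target >= self.min_target_fraction
                    and f_background <= self.max_background_fraction)
        # depleted = the enriched predicate on the complemented fractions
        return (f_target <= 1.0 - self.min_target_fraction
                and f_background >= 1.0 - self.max_background_fraction)


def compute_group_fractions(matrix: PresenceAbsenceMatrix,
                            labels: GroupLabels) -> list[MarkerStats]:
    """Carriage counts and fractions of every cluster in both groups.

    Inputs must already be aligned (every matrix genome labelled); both
    groups must be non-empty.
    """
    labels.require_both_groups()
    unlabelled = [g for g in matrix.genome_ids if g not in labels.assignments]
    if unlabelled:
        raise GroupLabelError(f"unlabelled genomes in matrix: {unlabelled[:5]}")
    genome_index = {g: i for i, g in enumerate(matrix.genome_ids)}
    tgt_rows = [genome_index[g] for g in labels.target_ids if g in genome_index]
    bgd_rows = [genome_index[g] for g in labels.background_ids if g in genome_index]
    if not tgt_rows or not bgd_rows:
        raise GroupLabelError("a group has no genomes present in the matrix")
    X = matrix.values
    n_t, n_b = len(tgt_rows), len(bgd_rows)
    k_t = X[tgt_rows].sum(axis=0)
    k_b = X[bgd_rows].sum(axis=0)
    # hypergeometric: population n_t+n_b genomes, k_t+k_b carriers, draw n_t
    pvals = hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t)
    out = []
    for j, cid in enumerate(matrix.cluster_ids):
        ft = k_t[j] / n_t
        fb = k_b[j] / n_b
        out.append(MarkerStats(
            cluster_id=cid,
            n_target_present=int(k_t[j]), n_target=n_t,
            n_background_present=int(k_b[j]), n_background=n_b,
            f_target=float(ft), f_background=float(fb),
            score=float(ft - fb), p_hypergeom=float(pvals[j]),
        ))
    return out


def filter_markers(stats: Iterable[MarkerStats],
                   thresholds: Thresholds) -> list[MarkerStats]:
    """Keep clusters passing the dual thresholds, ranked by |score|.

    Ties in ``|score|`` are broken lexicographically by cluster id, making
    the ordering a deterministic total order.
    """
    survivors = [s for s in stats
                 if thresholds.accepts(s.f_target, s.f_background)]
    survivors.sort(key=lambda s: (-abs(s.score), s.cluster_id))
    return survivors


def stratified_counts(matrix: PresenceAbsenceMatrix, labels: GroupLabels,
                      cluster_ids: Sequence[str], stratum: str) -> dict[str, int]:
    """Carriage counts of named clusters within one background stratum.

    Answers the taxonomic-confound question: does a candidate marker track
    the phenotype, or merely an over-represented taxon?  Counts are taken
    over background genomes whose taxon label equals ``stratum``.
    """
    members = [g for g in labels.background_ids
               if labels.strata.get(g) == stratum]
    if not members:
        known = sorted({labels.strata[g] for g in labels.background_ids
                        if g in labels.strata})
        raise GroupLabelError(
            f"unknown background stratum {stratum!r}; available: {known}"
        )
    members = [g for g in members if g in set(matrix.genome_ids)]
    for cid in cluster_ids:
        if cid not in set(matrix.cluster_ids):
            raise MatrixError(f"unknown cluster: {cid!r}")
    sub = matrix.subset_genomes(members).subset_clusters(list(cluster_ids))
    sums = sub.values.sum(axis=0)
    return {cid: int(s) for cid, s in zip(sub.cluster_ids, sums)}


def write_marker_table(stats: Sequence[MarkerStats], path) -> None:
    """Write marker statistics as a TSV with one row per cluster."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MarkerStats.TSV_FIELDS) + "\n")
        for s in stats:
            row = [getattr(s, f) for f in MarkerStats.TSV_FIELDS]
            fh.write("\t".join(
                f"{v:.10g}" if isinstance(v, float) else str(v) for v in row
            ) + "\n")
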