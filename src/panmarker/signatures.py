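"""Boolean multi-locus typing signatures.

A signature is a conjunction "carries every cluster in P and none in A".
A genome is classified *target* exactly when it satisfies the conjunction.
The empty signature (P = A = {}) is the vacuous conjunction and classifies
every genome as target — this convention keeps the monotonicity law clean:
adding a constraint can only move genomes from target to background.

``search_signatures`` systematizes the manual gene-combination step:
it enumerates all signatures up to the requested sizes over a candidate
pool and ranks them by classification accuracy against the labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .groups import GroupLabels
from .markers import Thresholds, compute_group_fractions, filter_markers
from .matrix import MatrixError, PresenceAbsenceMatrix

__all__ = ["Signature", "ConfusionCounts", "classify", "evaluate_signature",
           "search_signatures"]

#: largest candidate pool accepted for exhaustive enumeration
EXHAUSTIVE_POOL_LIMIT = 40


@dataclass(frozen=True)
class Signature:
    """Typing rule: require every cluster in P present and every one in A absent."""

    require_present: frozenset[str]
    require_absent: frozenset[str]

    def __init__(self, require_present=(), require_absent=()):
        object.__setattr__(self, "require_present", frozenset(require_present))
        object.__setattr__(self, "require_absent", frozenset(require_absent))
        overlap = self.require_present & self.require_absent
        if overlap:
            raise ValueError(
                f"clusters cannot be required both present and absent: "
                f"{sorted(overlap)}"
            )

    @property
    def size(self) -> int:
        return len(self.require_present) + len(self.require_absent)

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.require_present)),
                tuple(sorted(self.require_absent)))

    def __str__(self) -> str:
        p = "+".join(sorted(self.require_present)) or "-"
        a = "+".join(sorted(self.require_absent)) or "-"
        return f"present[{p}] absent[{a}]"


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion matrix of a signature against the group labels."""

    tp: int
    fn: int
    tn: int
    fp: int
    false_positive_ids: tuple[str, ...] = field(default=(), compare=False)
    false_negative_ids: tuple[str, ...] = field(default=(), compare=False)

    @property
    def n_target(self) -> int:
        return self.tp + self.fn

    @property
    def n_background(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_target if self.n_target else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / self.n_background if self.n_background else float("nan")

    @property
    def accuracy(self) -> float:
        n = self.n_target + self.n_background
        return (self.tp + self.tn) / n if n else float("nan")


def classify(genome_row: Mapping[str, int], sig: Signature) -> str:
    """Classify one genome presence vector under a signature.

    Returns ``"target"`` iff every required-present cluster is 1 and every
    required-absent cluster is 0.  Unknown cluster ids are an error.
    """
    for cid in sorted(sig.require_present | sig.require_absent):
        if cid not in genome_row:
            raise MatrixError(f"unknown cluster in signature: {cid!r}")
    ok = (all(genome_row[c] == 1 for c in sig.require_present)
          and all(genome_row[c] == 0 for c in sig.require_absent))
    return "target" if ok else "background"


def _satisfies(matrix: PresenceAbsenceMatrix, sig: Signature) -> np.ndarray:
    """Boolean vector over matrix genomes: True where the signature holds."""
    have = set(matrix.cluster_ids)
    missing = sorted((sig.require_present | sig.require_absent) - have)
    if missing:
        raise MatrixError(f"unknown cluster in signature: {missing[0]!r}")
    col = {c: i for i, c in enumerate(matrix.cluster_ids)}
    X = matrix.values
    mask = np.ones(X.shape[0], dtype=bool)
    for c in sig.require_present:
        mask &= X[:, col[c]] == 1
    for c in sig.require_absent:
        mask &= X[:, col[c]] == 0
    return mask


def evaluate_signature(matrix: PresenceAbsenceMatrix, labels: GroupLabels,
                       sig: Signature) -> ConfusionCounts:
    """Exact confusion counts of a signature, with misclassified genome ids.

    The misclassified lists matter in practice: apparent false positives in
    a census of genomes are candidate members of the target phenotype that
    were simply never recognized as such.
    """
    mask = _satisfies(matrix, sig)
    genome_ids = matrix.genome_ids
    is_target = np.array([labels.assignments.get(g) == "target"
                          for g in genome_ids])
    labelled = np.array([g in labels.assignments for g in genome_ids])
    mask, is_target = mask[labelled], is_target[labelled]
    ids = [g for g, keep in zip(genome_ids, labelled) if keep]
    tp = int(np.sum(mask & is_target))
    fn = int(np.sum(~mask & is_target))
    tn = int(np.sum(~mask & ~is_target))
    fp = int(np.sum(mask & ~is_target))
    fp_ids = tuple(g for g, m, t in zip(ids, mask, is_target) if m and not t)
    fn_ids = tuple(g for g, m, t in zip(ids, mask, is_target) if not m and t)
    return ConfusionCounts(tp, fn, tn, fp, fp_ids, fn_ids)


def _rank_key(item: tuple[Signature, ConfusionCounts]) -> tuple:
    sig, cc = item
    # higher accuracy, then higher specificity, then smaller, then lexicographic
    return (-cc.accuracy, -cc.specificity, sig.size, sig.sort_key())


def search_signatures(matrix: PresenceAbsenceMatrix, labels: GroupLabels,
                      candidate_pool: Sequence[str] | None = None,
                      max_present: int = 2, max_absent: int = 1,
                      top_k: int = 10, min_sensitivity: float = 0.0,
                      greedy: bool = False,
                      ) -> list[tuple[Signature, ConfusionCounts]]:
    """Search boolean signatures over a candidate pool, best first.

    Exhaustive enumeration of all disjoint (P, A) with |P| <= max_present and
    |A| <= max_absent when the pool has at most ``EXHAUSTIVE_POOL_LIMIT``
    clusters; with ``greedy`` a forward-selection search is used instead
    (add the single constraint that most improves accuracy until no
    constraint helps or the size caps are hit).

    Ranking: accuracy desc, then specificity desc, then smaller signature,
    then lexicographic — a deterministic total order independent of pool
    ordering.  ``min_sensitivity`` discards signatures below the floor
    (use 1.0 to demand perfect recall of the target group).
    """
    labels.require_both_groups()
    if candidate_pool is None:
        stats = compute_group_fractions(matrix, labels)
        candidate_pool = [s.cluster_id for s in
                          filter_markers(stats, Thresholds(0.0, 1.0))][:20]
    pool = sorted(dict.fromkeys(candidate_pool))  # dedupe, order-independent
    known = set(matrix.cluster_ids)
    missing = [c for c in pool if c not in known]
    if missing:
        raise MatrixError(f"unknown cluster in pool: {missing[0]!r}")

    if greedy or len(pool) > EXHAUSTIVE_POOL_LIMIT:
        if not greedy:
            raise ValueError(
                f"pool of {len(pool)} exceeds the exhaustive limit of "
                f"{EXHAUSTIVE_POOL_LIMIT}; pass greedy=True"
            )
        results = [_greedy_search(matrix, labels, pool, max_present, max_absent)]
    else:
        results = []
        for p_size in range(max_present + 1):
            for P in itertools.combinations(pool, p_size):
                rest = [c for c in pool if c not in P]
                for a_size in range(max_absent + 1):
                    for A in itertools.combinations(rest, a_size):
                        sig = Signature(P, A)
                        results.append((sig, evaluate_signature(matrix, labels, sig)))
    results = [r for r in results if r[1].sensitivity >= min_sensitivity]
    results.sort(key=_rank_key)
    return results[:top_k]


def _greedy_search(matrix, labels, pool, max_present, max_absent):
    """Forward selection: repeatedly add the best single constraint."""
    sig = Signature()
    best = evaluate_signature(matrix, labels, sig)
    while True:
        candidates = []
        used = sig.require_present | sig.require_absent
        for c in pool:
            if c in used:
                continue
            if len(sig.require_present) < max_present:
                s = Signature(sig.require_present | {c}, sig.require_absent)
                candidates.append((s, evaluate_signature(matrix, labels, s)))
            if len(sig.require_absent) < max_absent:
                s = Signature(sig.require_present, sig.require_absent | {c})
                candidates.append((s, evaluate_signature(matrix, labels, s)))
        if not candidates:
            break
        candidates.sort(key=_rank_key)
        if candidates[0][1].accuracy <= best.accuracy:
            break
        sig, best = candidates[0]
    return sig, best
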