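"""Two-group genome partitions (target vs background) with optional strata.

Marker discovery contrasts a *target* group (the phenotype of interest,
e.g. predatory bacteria) against a *background* group (everything else).
An optional third column assigns each genome a free-text taxon stratum,
used to test whether a candidate marker tracks taxonomy rather than
phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .matrix import PresenceAbsenceMatrix

__all__ = ["GroupLabelError", "GroupLabels", "read_labels", "align_to_matrix"]

log = logging.getLogger(__name__)

TARGET = "target"
BACKGROUND = "background"


class GroupLabelError(ValueError):
    """Raised for malformed or inconsistent group label inputs."""


@dataclass(frozen=True)
class GroupLabels:
    """Partition of genomes into target and background groups.

    ``assignments`` maps each genome id to the canonical group name
    (``"target"`` or ``"background"``); ``strata`` optionally maps genome
    ids to taxon labels.  Every labelled genome appears exactly once by
    construction (dict keys).
    """

    assignments: Mapping[str, str]
    strata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g, grp in self.assignments.items()
               if grp not in (TARGET, BACKGROUND)}
        if bad:
            raise GroupLabelError(f"unknown group for genomes: {sorted(bad)}")
        stray = set(self.strata) - set(self.assignments)
        if stray:
            raise GroupLabelError(f"strata for unlabelled genomes: {sorted(stray)}")

    @property
    def target_ids(self) -> list[str]:
        return [g for g, grp in self.assignments.items() if grp == TARGET]

    @property
    def background_ids(self) -> list[str]:
        return [g for g, grp in self.assignments.items() if grp == BACKGROUND]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.assignments)

    def require_both_groups(self) -> None:
        """Marker discovery needs a non-empty target AND background group."""
        if not self.target_ids or not self.background_ids:
            raise GroupLabelError(
                "both groups required: "
                f"{len(self.target_ids)} target, "
                f"{len(self.background_ids)} background genomes"
            )

    def swapped(self) -> "GroupLabels":
        """Labels with target and background exchanged (for symmetry checks)."""
        flipped = {g: (BACKGROUND if grp == TARGET else TARGET)
                   for g, grp in self.assignments.items()}
        return GroupLabels(flipped, dict(self.strata))

    def restrict(self, genome_ids) -> "GroupLabels":
        keep = set(genome_ids)
        return GroupLabels(
            {g: grp for g, grp in self.assignments.items() if g in keep},
            {g: s for g, s in self.strata.items() if g in keep},
        )


def read_labels(path, target_token: str = TARGET,
                background_token: str = BACKGROUND,
                require_both: bool = True) -> GroupLabels:
    """Read a genome -> group TSV (columns: genome_id, group, [taxon]).

    Group tokens are user-declared rather than hard-coded phenotype names so
    the same reader serves any two-group contrast.  A header line starting
    with ``genome_id`` is accepted and skipped.  Row order is irrelevant.

    Raises
    ------
    GroupLabelError
        If a genome is labelled twice, if more than the two declared group
        tokens occur (listing the offenders), or — with ``require_both`` —
        if either group ends up empty.
    """
    if target_token == background_token:
        raise GroupLabelError("target and background tokens must differ")
    assignments: dict[str, str] = {}
    strata: dict[str, str] = {}
    canonical = {target_token: TARGET, background_token: BACKGROUND}
    unknown_tokens: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0] == "genome_id":
                continue
            if len(cells) not in (2, 3):
                raise GroupLabelError(
                    f"line {lineno}: expected 2 or 3 columns, got {len(cells)}"
                )
            genome, token = cells[0], cells[1]
            if genome in assignments:
                raise GroupLabelError(f"genome labelled twice: {genome!r}")
            if token not in canonical:
                unknown_tokens.add(token)
                continue
            assignments[genome] = canonical[token]
            if len(cells) == 3 and cells[2].strip():
                strata[genome] = cells[2].strip()
    if unknown_tokens:
        raise GroupLabelError(
            "group tokens other than "
            f"{target_token!r}/{background_token!r} found: "
            f"{sorted(unknown_tokens)}"
        )
    labels = GroupLabels(assignments, strata)
    if require_both:
        labels.require_both_groups()
    return labels


def write_labels(labels: GroupLabels, path) -> None:
    """Write labels in the TSV dialect read back by :func:`read_labels`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tgroup\ttaxon\n")
        for g, grp in labels.assignments.items():
            fh.write(f"{g}\t{grp}\t{labels.strata.get(g, '')}\n")


def align_to_matrix(labels: GroupLabels, matrix: PresenceAbsenceMatrix
                    ) -> tuple[GroupLabels, PresenceAbsenceMatrix]:
    """Restrict labels and matrix to their common genomes.

    Genomes on only one side are dropped with a logged count (a genome
    database holds thousands of genomes irrelevant to a given contrast);
    an empty intersection is an error.  Matrix genome order is preserved.
    """
    labelled = set(labels.assignments)
    in_matrix = matrix.genome_ids
    common = [g for g in in_matrix if g in labelled]
    if not common:
        raise GroupLabelError("no genome shared between labels and matrix")
    dropped_matrix = [g for g in in_matrix if g not in labelled]
    dropped_labels = [g for g in labels.assignments if g not in set(in_matrix)]
    if dropped_matrix:
        log.warning("dropping %d unlabelled genome(s) from matrix: %s%s",
                    len(dropped_matrix), ", ".join(dropped_matrix[:5]),
                    "..." if len(dropped_matrix) > 5 else "")
    if dropped_labels:
        log.warning("dropping %d labelled genome(s) absent from matrix: %s%s",
                    len(dropped_labels), ", ".join(dropped_labels[:5]),
                    "..." if len(dropped_labels) > 5 else "")
    return labels.restrict(common), matrix.subset_genomes(common)
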