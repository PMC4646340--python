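"""Ortholog-cluster tables and binary presence/absence matrices.

The central object of the package is the :class:`PresenceAbsenceMatrix`: a
binary genome x ortholog-cluster incidence table in which a cell is 1 when
the genome carries at least one member of the cluster (paralog multiplicity
is collapsed) and 0 otherwise.

Two on-disk dialects are supported:

* the wide ortholog-cluster table exported by microbial genome databases —
  one row per cluster, one column per genome, each cell empty or holding one
  or more gene names (space/comma/semicolon separated paralogs);
* a compact binary TSV — first column ``cluster_id``, one column per genome,
  cells a literal ``0`` or ``1``.  This dialect round-trips exactly and is
  the stable interchange format of the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatrixError",
    "RawClusterTable",
    "PresenceAbsenceMatrix",
    "read_cluster_table",
    "binarize",
    "clean",
    "read_matrix",
    "write_matrix",
]

#: characters accepted as paralog separators inside one cluster-table cell
_PARALOG_SEP = re.compile(r"[ ,;]+")


class MatrixError(ValueError):
    """Raised for malformed cluster tables or incidence matrices."""


def _check_ids(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i == "":
            raise MatrixError(f"empty {what} identifier")
        if i in seen:
            raise MatrixError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class RawClusterTable:
    """Wide ortholog-cluster table: rows are clusters, columns genomes.

    ``payloads[i][j]`` is the raw cell text for cluster ``cluster_ids[i]`` in
    genome ``genome_ids[j]`` — empty, a single gene name, or several
    delimiter-joined paralog names.
    """

    genome_ids: tuple[str, ...]
    cluster_ids: tuple[str, ...]
    payloads: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        _check_ids(self.genome_ids, "genome")
        _check_ids(self.cluster_ids, "cluster")
        for cid, row in zip(self.cluster_ids, self.payloads):
            if len(row) != len(self.genome_ids):
                raise MatrixError(
                    f"row {cid!r} has {len(row)} cells, expected "
                    f"{len(self.genome_ids)}"
                )


class PresenceAbsenceMatrix:
    """Binary genome x cluster incidence matrix.

    Backed by a pandas DataFrame (index = genome ids, columns = cluster ids,
    values 0/1 int8).  Construction validates identifiers and cell values.
    """

    def __init__(self, data: pd.DataFrame):
        _check_ids([str(g) for g in data.index], "genome")
        _check_ids([str(c) for c in data.columns], "cluster")
        values = data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            bad = values[~np.isin(values, (0, 1))].flat[0]
            raise MatrixError(f"matrix cell is not 0/1: {bad!r}")
        self._data = pd.DataFrame(
            values.astype(np.int8),
            index=[str(g) for g in data.index],
            columns=[str(c) for c in data.columns],
        )

    # -- container protocol -------------------------------------------------
    @property
    def genome_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        """Genome x cluster 0/1 array (int8, copy-free view)."""
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def to_frame(self) -> pd.DataFrame:
        return self._data.copy()

    def row(self, genome_id: str) -> pd.Series:
        """Presence vector of one genome over all clusters."""
        if genome_id not in self._data.index:
            raise MatrixError(f"unknown genome: {genome_id!r}")
        return self._data.loc[genome_id]

    def column(self, cluster_id: str) -> pd.Series:
        if cluster_id not in self._data.columns:
            raise MatrixError(f"unknown cluster: {cluster_id!r}")
        return self._data[cluster_id]

    def subset_genomes(self, genome_ids: Sequence[str]) -> "PresenceAbsenceMatrix":
        missing = [g for g in genome_ids if g not in self._data.index]
        if missing:
            raise MatrixError(f"unknown genomes: {missing}")
        return PresenceAbsenceMatrix(self._data.loc[list(genome_ids)])

    def subset_clusters(self, cluster_ids: Sequence[str]) -> "PresenceAbsenceMatrix":
        missing = [c for c in cluster_ids if c not in self._data.columns]
        if missing:
            raise MatrixError(f"unknown clusters: {missing}")
        return PresenceAbsenceMatrix(self._data[list(cluster_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, c = self.shape
        return f"PresenceAbsenceMatrix({g} genomes x {c} clusters)"


def read_cluster_table(path) -> RawClusterTable:
    """Parse a wide ortholog-cluster TSV into a :class:`RawClusterTable`.

    The first row is a header whose first column labels the cluster-id
    column; the remaining header cells are genome identifiers.  Empty lines
    are skipped; input ordering is preserved.

    Raises
    ------
    MatrixError
        On an empty file ("no header"), ragged rows (naming the 1-based line
        number) or duplicate cluster ids (naming the id).
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    # leading blank lines carry no header
    while lines and lines[0].strip() == "":
        lines.pop(0)
    if not lines:
        raise MatrixError(f"no header in cluster table {path}")
    header = lines[0].split("\t")
    genome_ids = tuple(header[1:])
    width = len(header)
    cluster_ids: list[str] = []
    payloads: list[tuple[str, ...]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if line.strip() == "":
            continue
        cells = line.split("\t")
        if len(cells) != width:
            raise MatrixError(
                f"ragged row at line {lineno}: {len(cells)} cells, "
                f"expected {width}"
            )
        cid = cells[0]
        if cid in seen:
            raise MatrixError(f"duplicate cluster id: {cid!r}")
        seen.add(cid)
        cluster_ids.append(cid)
        payloads.append(tuple(cells[1:]))
    return RawClusterTable(genome_ids, tuple(cluster_ids), tuple(payloads))


def payload_is_present(payload: str) -> bool:
    """True when a cluster-table cell names at least one gene."""
    return any(tok for tok in _PARALOG_SEP.split(payload.strip()))


def binarize(table: RawClusterTable) -> PresenceAbsenceMatrix:
    """Collapse gene names to presence: cell = 1 iff the payload is non-empty.

    Any number of paralog names in one cell collapses to a single 1; the
    output is oriented genomes x clusters.
    """
    cells = np.zeros((len(table.genome_ids), len(table.cluster_ids)), dtype=np.int8)
    for j, row in enumerate(table.payloads):
        for i, payload in enumerate(row):
            if payload_is_present(payload):
                cells[i, j] = 1
    return PresenceAbsenceMatrix(
        pd.DataFrame(cells, index=list(table.genome_ids),
                     columns=list(table.cluster_ids))
    )


def clean(matrix: PresenceAbsenceMatrix, drop_invariant: bool = True) -> PresenceAbsenceMatrix:
    """Remove clusters that can never discriminate any two-group contrast.

    With ``drop_invariant`` set, clusters present in every genome or absent
    from every genome are dropped; otherwise the matrix is returned as-is.
    Genomes are never removed here (label-driven genome filtering lives in
    :func:`panmarker.groups.align_to_matrix`).
    """
    if not drop_invariant:
        return matrix
    sums = matrix.values.sum(axis=0)
    n = matrix.shape[0]
    keep = [c for c, s in zip(matrix.cluster_ids, sums) if 0 < s < n]
    return matrix.subset_clusters(keep)


def write_matrix(matrix: PresenceAbsenceMatrix, path) -> None:
    """Write the binary TSV dialect (clusters x genomes, literal 0/1 cells)."""
    frame = matrix.to_frame().T  # rows = clusters, like the source tables
    frame.index.name = "cluster_id"
    frame.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def read_matrix(path) -> PresenceAbsenceMatrix:
    """Read the binary TSV dialect written by :func:`write_matrix`."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False, encoding="utf-8")
    if frame.index.name != "cluster_id":
        raise MatrixError(
            f"first column must be 'cluster_id', got {frame.index.name!r}"
        )
    try:
        values = frame.to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise MatrixError(f"non-numeric cell in binary matrix: {exc}") from exc
    return PresenceAbsenceMatrix(
        pd.DataFrame(values.T, index=list(frame.columns), columns=list(frame.index))
    )
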