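"""Group-specific indel regions in protein multiple sequence alignments.

A phenotype-specific insertion shows up in an MSA as a block of columns
occupied (non-gap) in the target group and gapped in the background group.
``find_group_specific_regions`` scans column-wise gap occupancy and returns
maximal runs of discriminating columns, each summarized by its
Kyte-Doolittle hydropathy and Henderson-Hasselbalch net charge computed on
the target-group consensus — the kind of block that, in a tryptophan
2,3-dioxygenase alignment, separates obligate predatory bacteria from
everything else.

Coordinates are 0-based half-open everywhere in machine output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .groups import GroupLabelError, GroupLabels

__all__ = ["MSAError", "ProteinMSA", "AlignmentRegion",
           "find_group_specific_regions", "hydropathy_stats", "net_charge",
           "KYTE_DOOLITTLE", "SIDE_CHAIN_PKA"]

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte & Doolittle hydropathy scale (kcal/mol-free units; positive =
#: hydrophobic).  Standard 20-residue table.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Side-chain pKa values, standard biochemistry textbook set; frozen so net
# charges are reproducible.  Acids carry -1 when deprotonated, bases +1 when
# protonated.
SIDE_CHAIN_PKA: dict[str, tuple[float, int]] = {
    "D": (3.65, -1), "E": (4.25, -1), "C": (8.30, -1), "Y": (10.07, -1),
    "K": (10.53, +1), "R": (12.48, +1), "H": (6.00, +1),
}
PKA_N_TERMINUS = 9.0
PKA_C_TERMINUS = 2.0


class MSAError(ValueError):
    """Raised for malformed alignments or invalid residue strings."""


@dataclass(frozen=True)
class ProteinMSA:
    """Gapped protein alignment: unique ids, uniform length, AA/gap alphabet."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise MSAError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise MSAError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise MSAError(f"unequal aligned lengths: {sorted(lengths)}")
        valid = set(AMINO_ACIDS) | {GAP}
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - valid
            if bad:
                raise MSAError(
                    f"invalid character(s) {sorted(bad)} in sequence {sid!r}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "ProteinMSA":
        ids, seqs = [], []
        for sid, seq in records:
            ids.append(sid)
            seqs.append(seq.upper().replace(".", GAP))
        return cls(tuple(ids), tuple(seqs))

    @classmethod
    def from_fasta(cls, path) -> "ProteinMSA":
        """Load an aligned FASTA; '.' gaps are normalized to '-'."""
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise MSAError(f"no sequences in {path}")
        return cls.from_records(records)

    def to_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


@dataclass(frozen=True)
class AlignmentRegion:
    """A contiguous block of columns occupied in one group, gapped in the other."""

    start_col: int          # 0-based, inclusive
    end_col: int            # 0-based, exclusive
    occupancy_target: float
    occupancy_background: float
    consensus: str          # target-group majority residues over the block
    mean_hydropathy: float
    sd_hydropathy: float
    net_charge: float

    @property
    def length(self) -> int:
        return self.end_col - self.start_col


def hydropathy_stats(sequence: str) -> tuple[float, float]:
    """Mean and population SD of per-residue Kyte-Doolittle hydropathy.

    The SD divides by n, not n-1: a candidate insert is the whole object of
    interest, not a sample from a larger population.
    """
    if not sequence:
        raise MSAError("empty sequence")
    values = []
    for pos, aa in enumerate(sequence):
        if aa not in KYTE_DOOLITTLE:
            raise MSAError(f"unknown residue {aa!r} at position {pos}")
        values.append(KYTE_DOOLITTLE[aa])
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / len(values)
    return mean, math.sqrt(var)


def net_charge(sequence: str, pH: float = 7.0,
               include_termini: bool = False) -> float:
    """Henderson-Hasselbalch net charge of a peptide at the given pH.

    Sums fractional charges of ionizable side chains (D/E/C/Y acidic,
    K/R/H basic).  ``include_termini`` adds the free alpha-amino and
    alpha-carboxyl groups; default off, appropriate for an internal region
    of a larger protein.
    """
    if not sequence:
        raise MSAError("empty sequence")
    total = 0.0
    for pos, aa in enumerate(sequence):
        if aa not in KYTE_DOOLITTLE:
            raise MSAError(f"unknown residue {aa!r} at position {pos}")
        if aa in SIDE_CHAIN_PKA:
            pka, sign = SIDE_CHAIN_PKA[aa]
            if sign > 0:
                total += 1.0 / (1.0 + 10.0 ** (pH - pka))
            else:
                total -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    if include_termini:
        total += 1.0 / (1.0 + 10.0 ** (pH - PKA_N_TERMINUS))
        total -= 1.0 / (1.0 + 10.0 ** (PKA_C_TERMINUS - pH))
    return total


def _consensus_residues(block: np.ndarray) -> str:
    """Majority residue per column, gaps excluded from the vote, ties
    alphabetical; all-gap columns contribute nothing."""
    out = []
    for j in range(block.shape[1]):
        col = block[:, j]
        residues = col[col != GAP]
        if residues.size == 0:
            continue
        values, counts = np.unique(residues, return_counts=True)
        # np.unique sorts values, so argmax takes the alphabetically first tie
        out.append(str(values[np.argmax(counts)]))
    return "".join(out)


def find_group_specific_regions(msa: ProteinMSA, labels: GroupLabels,
                                min_len: int = 30,
                                min_target_occupancy: float = 0.9,
                                max_background_occupancy: float = 0.1,
                                min_occupied_frac: float = 0.5,
                                pH: float = 7.0) -> list[AlignmentRegion]:
    """Find maximal runs of columns occupied in target, gapped in background.

    A column is *discriminating* when the non-gap fraction among target
    sequences is at least ``min_target_occupancy`` and among background
    sequences at most ``max_background_occupancy``.  Maximal runs of at
    least ``min_len`` consecutive discriminating columns are reported; the
    defaults tolerate a few ragged alignment edges while still capturing a
    ~60-residue insert.

    Per region, ``occupancy_target`` / ``occupancy_background`` are the
    fractions of group members with at least ``min_occupied_frac`` non-gap
    columns inside the interval, and the physicochemical summary is computed
    on the target-group consensus.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    unlabelled = [s for s in msa.ids if s not in labels.assignments]
    if unlabelled:
        raise GroupLabelError(f"unlabelled sequences in MSA: {unlabelled[:5]}")
    if min_len > msa.length:
        return []
    arr = np.array([list(s) for s in msa.sequences], dtype="<U1")
    is_target = np.array([labels.assignments[s] == "target" for s in msa.ids])
    if not is_target.any() or is_target.all():
        raise GroupLabelError("both groups must be represented in the MSA")
    nongap = arr != GAP
    f_tgt = nongap[is_target].mean(axis=0)
    f_bgd = nongap[~is_target].mean(axis=0)
    disc = (f_tgt >= min_target_occupancy) & (f_bgd <= max_background_occupancy)

    regions: list[AlignmentRegion] = []
    start = None
    bounds = []
    for col, flag in enumerate(disc):
        if flag and start is None:
            start = col
        elif not flag and start is not None:
            bounds.append((start, col))
            start = None
    if start is not None:
        bounds.append((start, len(disc)))

    for s, e in bounds:
        if e - s < min_len:
            continue
        window = nongap[:, s:e]
        occupied = window.mean(axis=1) >= min_occupied_frac
        occ_t = float(occupied[is_target].mean())
        occ_b = float(occupied[~is_target].mean())
        consensus = _consensus_residues(arr[is_target, s:e])
        mean_h, sd_h = hydropathy_stats(consensus) if consensus else (0.0, 0.0)
        charge = net_charge(consensus, pH=pH) if consensus else 0.0
        regions.append(AlignmentRegion(
            start_col=s, end_col=e,
            occupancy_target=occ_t, occupancy_background=occ_b,
            consensus=consensus,
            mean_hydropathy=mean_h, sd_hydropathy=sd_h, net_charge=charge,
        ))
    return regions
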