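"""In-silico PCR with IUPAC-degenerate primers.

Primer matching uses the IUPAC subset rule: a primer code matches a
template base iff the base belongs to the code's nucleotide set; a template
``N`` matches nothing (conservative — an unknown base cannot be claimed as
a binding site).  Mismatch counting is per-position Hamming; primer/template
indels are not modelled, which is the standard simplification for 16-23-mer
binding sites.  Amplicon lengths are primer-inclusive, matching what a gel
reports.

The reverse primer is given 5'->3' as synthesized; it binds where the plus
strand contains its reverse complement, exactly as at the bench.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = ["PrimerError", "Primer", "AmpliconHit", "expand_degenerate",
           "match_primer", "find_amplicons", "read_templates"]

#: IUPAC code -> set of concrete bases (from Biopython's table)
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
    if code != "X"
}
#: bit encoding A=1 C=2 G=4 T=8 for vectorized subset tests
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {code: sum(_BASE_BIT[b] for b in bases)
              for code, bases in IUPAC_SETS.items()}

DEFAULT_ENUMERATION_GUARD = 4096


class PrimerError(ValueError):
    """Raised for invalid primer or template sequences."""


@dataclass(frozen=True)
class Primer:
    """A named oligonucleotide, 5'->3', over the IUPAC nucleotide alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PrimerError(f"primer {self.name!r} is empty")
        for pos, code in enumerate(self.sequence):
            if code.upper() not in IUPAC_SETS:
                raise PrimerError(
                    f"primer {self.name!r}: invalid code {code!r} at "
                    f"position {pos}"
                )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        n = 1
        for code in self.sequence:
            n *= len(IUPAC_SETS[code])
        return n

    def reverse_complement(self) -> str:
        """IUPAC-aware reverse complement of the primer string."""
        comp = {k.upper(): v.upper() for k, v in ambiguous_dna_complement.items()}
        return "".join(comp[c] for c in reversed(self.sequence))


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product on a template."""

    template_id: str
    start: int              # 0-based half-open on the given template strand
    end: int
    length: int             # primer-inclusive, == end - start
    fwd_mismatches: int
    rev_mismatches: int
    amplicon_sequence: str  # product 5'->3' starting with the forward primer site
    strand: str = "+"       # orientation of the product on the given template


def expand_degenerate(primer: Primer,
                      guard: int = DEFAULT_ENUMERATION_GUARD
                      ) -> tuple[int, list[str] | None]:
    """Degeneracy count and (when small enough) the explicit variant list.

    The count is the product of per-position code cardinalities; the full
    enumeration is produced only when the count is at most ``guard``.
    """
    count = primer.degeneracy
    if count > guard:
        return count, None
    variants = ["".join(p) for p in itertools.product(
        *(sorted(IUPAC_SETS[c]) for c in primer.sequence))]
    return count, variants


def _encode_template(template: str) -> np.ndarray:
    bits = np.zeros(len(template), dtype=np.uint8)
    for i, base in enumerate(template.upper()):
        if base == "N":
            continue            # N stays 0: matches no primer code
        if base not in _BASE_BIT:
            raise PrimerError(f"invalid template base {base!r} at position {i}")
        bits[i] = _BASE_BIT[base]
    return bits


def match_primer(template: str, primer: Primer, max_mismatches: int = 0,
                 strand: str = "+") -> list[tuple[int, int]]:
    """All offsets where the primer binds with at most ``max_mismatches``.

    Returns ``(position, mismatches)`` pairs; ``position`` is the 0-based
    start of the binding site on the given (plus) template strand.  With
    ``strand='-'`` the primer anneals to the minus strand, i.e. the plus
    strand carries its reverse complement at the reported site.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    probe = primer.sequence if strand == "+" else primer.reverse_complement()
    m = len(probe)
    if m > len(template):
        return []
    tmpl_bits = _encode_template(template)
    probe_masks = np.array([_CODE_MASK[c] for c in probe], dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(tmpl_bits, m)
    # base matches code iff its bit is inside the code's mask (and base != N)
    ok = (windows & probe_masks) == windows
    ok &= windows != 0
    mismatches = m - ok.sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatches)[0]
    return [(int(p), int(mismatches[p])) for p in hits]


def _scan_orientation(template_id: str, seq: str, fwd: Primer, rev: Primer,
                      max_mismatches: int, min_len: int, max_len: int,
                      strand: str, total_len: int) -> list[AmpliconHit]:
    hits = []
    fwd_hits = match_primer(seq, fwd, max_mismatches, "+")
    rev_hits = match_primer(seq, rev, max_mismatches, "-")
    for fpos, fmm in fwd_hits:
        for rpos, rmm in rev_hits:
            start, end = fpos, rpos + len(rev)
            if start > rpos:        # reverse site must not precede the forward site
                continue
            length = end - start
            if not (min_len <= length <= max_len):
                continue
            product = seq[start:end]
            if strand == "+":
                hit_start, hit_end = start, end
            else:                   # mirror onto the given strand
                hit_start, hit_end = total_len - end, total_len - start
            hits.append(AmpliconHit(
                template_id=template_id, start=hit_start, end=hit_end,
                length=length, fwd_mismatches=fmm, rev_mismatches=rmm,
                amplicon_sequence=product, strand=strand,
            ))
    return hits


def find_amplicons(templates: Mapping[str, str], fwd: Primer, rev: Primer,
                   max_mismatches: int = 0, min_len: int = 1,
                   max_len: int = 10_000) -> list[AmpliconHit]:
    """Predict primer-inclusive PCR products on every template.

    Both orientations are scanned: the forward/reverse primer roles swap on
    the reverse strand, so a template and its reverse complement yield the
    same products (coordinates mirrored, sequences reverse-complemented).
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    out: list[AmpliconHit] = []
    for tid, seq in templates.items():
        seq = seq.upper()
        out.extend(_scan_orientation(tid, seq, fwd, rev, max_mismatches,
                                     min_len, max_len, "+", len(seq)))
        out.extend(_scan_orientation(tid, reverse_complement(seq), fwd, rev,
                                     max_mismatches, min_len, max_len,
                                     "-", len(seq)))
    out.sort(key=lambda h: (h.template_id, h.start, h.end, h.strand))
    return out


def read_templates(path) -> dict[str, str]:
    """Load a DNA multi-FASTA as an id -> sequence mapping."""
    from Bio import SeqIO

    templates = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in templates:
            raise PrimerError(f"duplicate template id: {rec.id!r}")
        templates[rec.id] = str(rec.seq).upper()
    if not templates:
        raise PrimerError(f"no sequences in {path}")
    return templates


def write_hits_tsv(hits: Sequence[AmpliconHit], path) -> None:
    fields = ("template_id", "start", "end", "length", "strand",
              "fwd_mismatches", "rev_mismatches", "amplicon_sequence")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(fields) + "\n")
        for h in hits:
            fh.write("\t".join(str(getattr(h, f)) for f in fields) + "\n")
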