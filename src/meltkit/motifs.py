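"""MELT-consensus motif scanning in protein sequences.

The canonical consensus of the Spc105/Knl1 repeats is M-[E/D]-[L/I/V/M]-T,
whose threonine is the phospho-acceptor read by Bub3.  Some annotated
repeats start with other hydrophobic residues, so a relaxed variant with
first class [M/I/L/V] is provided as well; neither variant is asserted as
the "correct" one.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

__all__ = ["MotifPattern", "MotifHit", "STRICT_MELT", "RELAXED_MELT",
           "scan", "scan_fasta", "hits_to_frame"]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifPattern:
    """Four position classes, each a nonempty subset of the 20 amino acids."""

    classes: tuple[frozenset, ...]

    def __post_init__(self):
        if len(self.classes) != 4:
            raise ValueError("pattern must have exactly four position classes")
        for cls in self.classes:
            if not cls or not cls <= AMINO_ACIDS:
                raise ValueError("each class must be a nonempty subset of the "
                                 "20 standard amino acids")

    def matches(self, window: str) -> bool:
        return all(aa in cls for aa, cls in zip(window, self.classes))


STRICT_MELT = MotifPattern((frozenset("M"), frozenset("ED"),
                            frozenset("LIVM"), frozenset("T")))
RELAXED_MELT = MotifPattern((frozenset("MILV"), frozenset("ED"),
                             frozenset("LIVM"), frozenset("T")))


@dataclass(frozen=True)
class MotifHit:
    """One motif match; coordinates are 1-based residue numbers and the
    phospho-site is the threonine at start + 3."""

    seq_id: str
    start: int
    motif: str

    @property
    def end(self) -> int:
        return self.start + 3

    @property
    def phospho_site(self) -> int:
        return self.start + 3


def scan(sequence: str, pattern: MotifPattern = STRICT_MELT,
         seq_id: str = "seq") -> list[MotifHit]:
    """All windows of ``sequence`` matching ``pattern``, overlapping matches
    allowed, in ascending start order.  Characters outside the standard
    one-letter amino-acid codes raise a ValueError naming the position."""
    seq = str(sequence).upper()
    for pos, aa in enumerate(seq, start=1):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino-acid character {aa!r} at "
                             f"position {pos} of {seq_id}")
    hits = []
    for i in range(len(seq) - 3):
        window = seq[i:i + 4]
        if pattern.matches(window):
            hits.append(MotifHit(seq_id=seq_id, start=i + 1, motif=window))
    return hits


def scan_fasta(path, pattern: MotifPattern = STRICT_MELT) -> list[MotifHit]:
    """Scan every record of a FASTA file; hits carry the record ids."""
    hits: list[MotifHit] = []
    for record in SeqIO.parse(str(path), "fasta"):
        hits.extend(scan(str(record.seq), pattern, seq_id=record.id))
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame([(h.seq_id, h.start, h.end, h.motif, h.phospho_site)
                         for h in hits],
                        columns=["seq_id", "start", "end", "motif",
                                 "phospho_site"])
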