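"""Gene models and coordinate arithmetic shared across modules.

Conventions: variant records are 1-based inclusive (VCF style); exon and
window intervals are 0-based half-open (BED style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from Bio.Seq import Seq

Interval = Tuple[int, int]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand-aware list of exons on one chromosome.

    ``exons`` are 0-based half-open genomic intervals, sorted and
    non-overlapping. ``frame`` is the offset (0-2) of the first complete
    codon within the spliced transcript.
    """

    name: str
    chrom: str
    strand: str = "+"
    exons: Tuple[Interval, ...] = field(default_factory=tuple)
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1, or 2")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty exon ({start}, {end}) in {self.name}")
            if start < prev_end:
                raise ValueError(f"exons overlap or are unsorted in {self.name}")
            prev_end = end
        if self.exons and self.exon_length < 3:
            raise ValueError(f"total exon length of {self.name} is < 3")

    @property
    def exon_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def contains(self, pos0: int) -> bool:
        """True if the 0-based position falls inside an exon."""
        return self.coding_index(pos0) is not None

    def coding_index(self, pos0: int) -> Optional[int]:
        """Offset of a genomic position within the spliced 5'->3' transcript.

        Returns None for intronic/intergenic positions.
        """
        offset = 0
        for start, end in self.exons:
            if start <= pos0 < end:
                plus_off = offset + (pos0 - start)
                if self.strand == "+":
                    return plus_off
                return self.exon_length - 1 - plus_off
            offset += end - start
        return None

    def exon_number(self, pos0: int) -> Optional[int]:
        """1-based exon number in transcript order (strand-aware)."""
        for i, (start, end) in enumerate(self.exons):
            if start <= pos0 < end:
                return i + 1 if self.strand == "+" else len(self.exons) - i
        return None

    def overlapping_exons(self, start: int, end: int) -> list[int]:
        """1-based exon numbers overlapping the half-open genomic interval."""
        hits = []
        for i, (es, ee) in enumerate(self.exons):
            if es < end and start < ee:
                num = i + 1 if self.strand == "+" else len(self.exons) - i
                hits.append(num)
        return sorted(hits)


def translate_codon(codon: str, table: int = 1) -> str:
    """Single-letter amino acid (``*`` for stop) for a 3-base codon."""
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return str(Seq(codon).translate(table=table))
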