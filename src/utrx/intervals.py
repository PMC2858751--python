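"""Genomic intervals in BED convention: 0-based, half-open, stranded.

The whole package reasons in "transcript orientation": downstream means
increasing coordinates on ``+`` and decreasing coordinates on ``-``, and a
feature's 3' coordinate is its ``end`` on ``+`` and its ``start`` on ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValidationError(f"interval bounds must be integers: {self!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def three_prime_coordinate(iv: GenomicInterval) -> int:
    """The 3'-most coordinate of ``iv`` in its own orientation.

    ``end`` on the plus strand, ``start`` on the minus strand (half-open
    convention: both are the boundary just 3' of the last covered base).
    """
    return iv.end if iv.strand == "+" else iv.start


def five_prime_coordinate(iv: GenomicInterval) -> int:
    """The 5'-most coordinate of ``iv`` in its own orientation."""
    return iv.start if iv.strand == "+" else iv.end
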