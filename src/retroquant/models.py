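"""Shared genomic data models (0-based, half-open coordinates throughout)."""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RepeatLocus:
    """An annotated repeat interval with completeness flags and context.

    A locus missing either terminal segment (``has_5prime_end`` /
    ``has_3prime_end`` false) is a *pseudoelement*; a full-length copy with
    both ends intact is proviral.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    has_5prime_end: bool = True
    has_3prime_end: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.locus_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_pseudoelement(self) -> bool:
        return not (self.has_5prime_end and self.has_3prime_end)


@dataclass(frozen=True)
class Gene:
    """A gene body with exon blocks (two exons and one intron in simulation)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        exs = sorted(self.exons)
        return tuple(
            (exs[i][1], exs[i + 1][0])
            for i in range(len(exs) - 1)
            if exs[i][1] < exs[i + 1][0]
        )
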