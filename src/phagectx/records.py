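"""Core domain records shared by every stage of the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; the GFF
reader/writer converts to and from the 1-based inclusive convention at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A genome (or scaffold) sequence.

    ``circular`` marks genomes curated to completion; linear scaffolds are
    the default.
    """

    genome_id: str
    sequence: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.genome_id!r}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A protein-coding gene on a genome.

    ``start``/``end`` are 0-based half-open on the forward strand regardless
    of the coding strand. Wrap-around genes on circular genomes are not
    representable (rejected at parse time).
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    product_label: str = ""
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: bad interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentRecord:
    """One mapped read, normalized away from SAM specifics.

    ``aligned_blocks`` are sorted, non-overlapping [start, end) intervals on
    the target; a read wrapping the origin of a circular genome appears as
    two blocks. ``mismatches`` is the NM-style edit count against the target,
    so per-read identity is ``1 - mismatches / read_length``.
    """

    read_id: str
    target_id: str
    target_start: int
    aligned_blocks: list[tuple[int, int]]
    read_length: int
    mismatches: int = 0
    is_rna: bool = False

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise ValueError(f"read {self.read_id!r}: negative mismatch count")
        prev_end = -1
        for s, e in self.aligned_blocks:
            if s >= e or s < prev_end:
                raise ValueError(
                    f"read {self.read_id!r}: blocks not sorted/disjoint"
                )
            prev_end = e

    @property
    def aligned_target_bases(self) -> int:
        return sum(e - s for s, e in self.aligned_blocks)

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.read_length


@dataclass
class CrisprArray:
    """A repeat-spacer array detected on a host genome."""

    genome_id: str
    start: int
    end: int
    repeat_consensus: str
    spacers: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.spacers) + 1


@dataclass
class SpacerHit:
    """A spacer-to-protospacer match satisfying the dual threshold rule.

    The rule admits ungapped matches of at least 24 nt with at most one
    mismatch, or at least 30 nt with at most three mismatches.
    """

    spacer_id: str
    target_genome_id: str
    target_start: int
    strand: str
    match_length: int
    mismatches: int
    rule: str

    def __post_init__(self) -> None:
        ok = (self.match_length >= 24 and self.mismatches <= 1) or (
            self.match_length >= 30 and self.mismatches <= 3
        )
        if not ok:
            raise ValueError(
                f"hit {self.spacer_id!r}: {self.match_length} nt / "
                f"{self.mismatches} mm violates the dual match rule"
            )
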