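"""Genome-level summary statistics and a naive ORF caller.

The ORF caller is deliberately minimal (ATG-only starts, standard code, no
ribosome-binding-site model): the rest of the pipeline is annotation-
agnostic and real users are expected to supply GFF3. Ns terminate putative
ORFs, since runs of Ns mark scaffolding gaps, not genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .intervals import union_length
from .records import GeneAnnotation, GenomeRecord, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GenomeSummary:
    genome_id: str
    length_bp: int
    gc_percent: float
    n_genes: int
    coding_density_percent: float
    circular: bool


def gc_content(seq: str) -> float:
    """GC percentage of a DNA string; Ns are excluded from the denominator."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    return 100.0 * gc / acgt


def coding_density(genes: list[GeneAnnotation], genome_length: int) -> float:
    """Percent of the genome inside at least one gene (union semantics)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return 100.0 * union_length((g.start, g.end) for g in genes) / genome_length


def _orfs_on_forward(seq: str, min_aa: int) -> list[tuple[int, int, str]]:
    """Maximal ATG→stop ORFs on the three forward frames of ``seq``.

    Returns (start, end, protein) with end past the stop codon. A codon
    containing N acts as a barrier: no ORF crosses it.
    """
    n = len(seq)
    orfs = []
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                start = None
                continue
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                end = i + 3
                n_aa = (end - start) // 3 - 1
                if n_aa >= min_aa:
                    protein = str(Seq(seq[start:i]).translate())
                    orfs.append((start, end, protein))
                start = None
    return orfs


def find_orfs(genome: GenomeRecord, min_aa: int = 60) -> list[GeneAnnotation]:
    """All maximal ORFs (both strands, six frames) of at least ``min_aa`` codons.

    Circular genomes are scanned linearly (no origin-wrapping ORFs).
    Coordinates are half-open on the forward strand; output is sorted by
    (start, end, strand).
    """
    seq = genome.sequence
    n = len(seq)
    found: list[GeneAnnotation] = []
    for s, e, prot in _orfs_on_forward(seq, min_aa):
        found.append(
            GeneAnnotation("", genome.genome_id, s, e, "+", protein=prot)
        )
    for s, e, prot in _orfs_on_forward(reverse_complement(seq), min_aa):
        found.append(
            GeneAnnotation("", genome.genome_id, n - e, n - s, "-", protein=prot)
        )
    found.sort(key=lambda g: (g.start, g.end, g.strand))
    for i, g in enumerate(found, start=1):
        g.gene_id = f"{genome.genome_id}_orf{i}"
    return found


def summarize_genome(genome: GenomeRecord, genes: list[GeneAnnotation]) -> GenomeSummary:
    own = [g for g in genes if g.genome_id == genome.genome_id]
    return GenomeSummary(
        genome_id=genome.genome_id,
        length_bp=len(genome),
        gc_percent=gc_content(genome.sequence),
        n_genes=len(own),
        coding_density_percent=coding_density(own, len(genome)),
        circular=genome.circular,
    )
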