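"""Alignment-derived genome detection, per-gene transcription, and
rpS3-marker community profiling.

Definitions follow the read-mapping conventions of the study design:

* a genome is *detected* in a sample when reads of at least 97% identity
  cover at least 90% of its positions (breadth >= 0.90);
* *coverage* is total aligned read bases divided by the covered genome
  length (not the full genome length);
* the normalized transcriptional level (NTL) of a gene is
  ``total_base_gene / length_gene / total_read_genome`` computed from RNA
  reads of at least 98% identity, reported only when at least 80% of the
  gene's bases are covered;
* rpS3 marker coverage is total mapped bases divided by marker length,
  summed per taxon after greedy dereplication of the markers.

Per-read identity is ``1 - mismatches / read_length``; reads failing the
identity filter are discarded before any counting.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from ._align import global_identity, mutual_coverage
from .intervals import merge_intervals, overlap_length, union_length
from .records import AlignmentRecord, GeneAnnotation, GenomeRecord

logger = logging.getLogger(__name__)


@dataclass
class CoverageSummary:
    genome_id: str
    sample_id: str
    breadth: float
    coverage: float
    n_reads_mapped: int
    detected: bool


@dataclass
class GeneActivity:
    gene_id: str
    covered_fraction: float
    total_base_gene: int
    length_gene: int
    total_read_genome: int
    ntl: float | None


@dataclass
class TaxonProfile:
    sample_id: str
    taxon: str
    coverage: float


def _passing(alignments: list[AlignmentRecord], min_identity: float) -> list[AlignmentRecord]:
    return [a for a in alignments if a.identity >= min_identity]


def genome_coverage(
    alignments: list[AlignmentRecord],
    genome: GenomeRecord,
    min_identity: float = 0.97,
    detection_breadth: float = 0.90,
    sample_id: str = "",
) -> CoverageSummary:
    """Breadth, coverage and the detection flag for one genome in one sample."""
    reads = [a for a in _passing(alignments, min_identity) if a.target_id == genome.genome_id]
    if not reads:
        return CoverageSummary(genome.genome_id, sample_id, 0.0, 0.0, 0, False)
    blocks = [b for a in reads for b in a.aligned_blocks]
    covered = union_length(blocks)
    breadth = covered / len(genome)
    total_bases = sum(a.aligned_target_bases for a in reads)
    coverage = total_bases / covered if covered else 0.0
    return CoverageSummary(
        genome_id=genome.genome_id,
        sample_id=sample_id,
        breadth=breadth,
        coverage=coverage,
        n_reads_mapped=len(reads),
        detected=breadth >= detection_breadth,
    )


def gene_ntl(
    alignments: list[AlignmentRecord],
    genes: list[GeneAnnotation],
    genome: GenomeRecord,
    min_identity: float = 0.98,
    min_covered: float = 0.80,
) -> list[GeneActivity]:
    """Normalized transcriptional level of every gene on one genome.

    ``total_read_genome`` counts identity-passing RNA records mapped
    anywhere on the genome, whether or not they touch a gene. A gene's
    bases are counted per read block overlap, so partially overlapping
    reads contribute only their overlapping bases.
    """
    reads = [a for a in _passing(alignments, min_identity) if a.target_id == genome.genome_id]
    total_read_genome = len(reads)
    if total_read_genome == 0:
        logger.warning(
            "no identity-passing RNA reads on %s: all NTL undefined", genome.genome_id
        )
    blocks = [b for a in reads for b in a.aligned_blocks]
    merged = merge_intervals(blocks)
    out: list[GeneActivity] = []
    for g in sorted(genes, key=lambda g: (g.start, g.gene_id)):
        total_base = overlap_length(blocks, (g.start, g.end))
        covered = overlap_length(merged, (g.start, g.end))
        covered_fraction = covered / g.length
        if total_read_genome > 0 and covered_fraction >= min_covered:
            ntl = total_base / g.length / total_read_genome
        else:
            ntl = None
        out.append(
            GeneActivity(
                gene_id=g.gene_id,
                covered_fraction=covered_fraction,
                total_base_gene=total_base,
                length_gene=g.length,
                total_read_genome=total_read_genome,
                ntl=ntl,
            )
        )
    return out


def percent_rna_mapped(
    alignments: list[AlignmentRecord],
    total_rna_reads: int,
    min_identity: float = 0.98,
) -> pd.DataFrame:
    """Percent of a sample's RNA reads mapped to each genome.

    Reads mapping to several genomes count once per genome (no
    deduplication). Columns: genome_id, percent_mapped.
    """
    if total_rna_reads <= 0:
        raise ValueError("total_rna_reads must be positive")
    counts: dict[str, int] = defaultdict(int)
    for a in _passing(alignments, min_identity):
        counts[a.target_id] += 1
    if sum(counts.values()) > 0 and total_rna_reads < max(counts.values()):
        raise ValueError("total_rna_reads smaller than mapped record count")
    return pd.DataFrame(
        [
            {"genome_id": gid, "percent_mapped": 100.0 * n / total_rna_reads}
            for gid, n in sorted(counts.items())
        ],
        columns=["genome_id", "percent_mapped"],
    )


def dereplicate_markers(
    markers: list[tuple[str, str, str]],
    dereplicate_identity: float = 0.97,
    min_len_nt: int = 300,
    min_cov: float = 0.5,
) -> list[tuple[str, str, str]]:
    """Greedy dereplication of (marker_id, sequence, taxon) triples.

    Markers shorter than ``min_len_nt`` are dropped; the rest are visited
    longest-first (ties by ID) and join an existing representative when
    global identity >= ``dereplicate_identity`` with mutual coverage >=
    ``min_cov``, otherwise become representatives themselves.
    """
    kept = [m for m in markers if len(m[1]) >= min_len_nt]
    kept.sort(key=lambda m: (-len(m[1]), m[0]))
    reps: list[tuple[str, str, str]] = []
    for mid, seq, taxon in kept:
        if not any(
            mutual_coverage(seq, rseq) >= min_cov
            and global_identity(seq, rseq) >= dereplicate_identity
            for _, rseq, _ in reps
        ):
            reps.append((mid, seq, taxon))
    return reps


def rps3_profile(
    markers: list[tuple[str, str, str]],
    alignments: list[AlignmentRecord],
    dereplicate_identity: float = 0.97,
    min_len_nt: int = 300,
    max_mismatch_frac: float = 0.03,
    sample_id: str = "",
) -> list[TaxonProfile]:
    """Per-taxon community coverage from rpS3 marker genes.

    Alignments are filtered to <= ``max_mismatch_frac`` mismatches per
    read; each representative marker's coverage is its mapped bases
    divided by its length, and coverages sum per taxon.
    """
    if not markers:
        raise ValueError("empty marker set")
    reps = dereplicate_markers(markers, dereplicate_identity, min_len_nt)
    min_identity = 1.0 - max_mismatch_frac
    passing = _passing(alignments, min_identity)
    per_taxon: dict[str, float] = defaultdict(float)
    for mid, seq, taxon in reps:
        bases = sum(
            a.aligned_target_bases for a in passing if a.target_id == mid
        )
        per_taxon[taxon] += bases / len(seq)
    return [
        TaxonProfile(sample_id=sample_id, taxon=t, coverage=c)
        for t, c in sorted(per_taxon.items())
    ]
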