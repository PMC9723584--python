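"""Readers and writers for FASTA, GFF3 and SAM.

Only plain-text flavors are supported (no BAM/CRAM, no bgzip). The SAM
reader consumes POS, FLAG, CIGAR, the query length and one NM-style
mismatch tag; ``@SQ`` header lines define target lengths.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AlignmentRecord, GeneAnnotation, GenomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_protein_fasta",
    "read_gff",
    "write_gff",
    "read_sam",
    "write_sam",
    "read_msa_fasta",
]


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read DNA FASTA into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is normalized to T. A header containing
    the token ``circular=true`` marks the record circular. Duplicate IDs and
    empty files are errors.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        circular = "circular=true" in desc.lower()
        records.append(
            GenomeRecord(
                genome_id=rec.id,
                sequence=str(rec.seq),
                circular=circular,
                description=desc,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | os.PathLike, width: int = 70) -> None:
    """Write genome records as FASTA; circularity is kept in the header."""
    with open(path, "w") as fh:
        for rec in records:
            desc_parts = []
            if rec.circular:
                desc_parts.append("circular=true")
            if rec.description and "circular=" not in rec.description:
                desc_parts.append(rec.description)
            header = " ".join([rec.genome_id] + desc_parts)
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_protein_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a protein FASTA as (id, sequence) pairs, uppercased."""
    out = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_protein_fasta(pairs: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pid, seq in pairs:
            fh.write(f">{pid}\n{seq}\n")


def read_msa_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read an aligned FASTA (equal-length rows) as (id, row) pairs."""
    rows = read_protein_fasta(path)
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows in {path} have unequal lengths {sorted(lengths)}")
    return rows


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | os.PathLike, genomes: Sequence[GenomeRecord]) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file.

    GFF 1-based inclusive coordinates become 0-based half-open. Features
    must fit inside their genome (wrap-around genes are rejected). Output is
    sorted by (genome_id, start).
    """
    lengths = {g.genome_id: len(g) for g in genomes}
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type("CDS"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"CDS {feat.id!r}: unknown strand {feat.strand!r}")
        start = feat.start - 1  # GFF is 1-based inclusive
        end = feat.end
        glen = lengths.get(feat.seqid)
        if glen is not None and (start < 0 or end > glen):
            raise ValueError(
                f"CDS {feat.id!r}: [{feat.start}, {feat.end}] outside "
                f"genome {feat.seqid!r} of length {glen}"
            )
        product = feat.attributes.get("product", [""])[0]
        genes.append(
            GeneAnnotation(
                gene_id=feat.attributes.get("ID", [feat.id])[0],
                genome_id=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand,
                product_label=product,
            )
        )
    genes.sort(key=lambda g: (g.genome_id, g.start, g.gene_id))
    return genes


def write_gff(genes: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    """Write CDS features as GFF3 (1-based inclusive), sorted deterministically."""
    rows = sorted(genes, key=lambda g: (g.genome_id, g.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in rows:
            attrs = f"ID={g.gene_id}"
            if g.product_label:
                attrs += f";product={g.product_label}"
            fh.write(
                "\t".join(
                    [
                        g.genome_id,
                        "phagectx",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_QUERY_OPS = {0, 1, 4, 7, 8}  # M, I, S, =, X consume the query


def _blocks_from_cigar(cigartuples: list[tuple[int, int]], pos: int) -> list[tuple[int, int]]:
    """Target intervals covered by a CIGAR starting at ``pos``.

    M/=/X open or extend the current block; D extends it (a deletion still
    consumes target); N closes it; I, S and H touch only the query. P is
    unsupported.
    """
    blocks: list[tuple[int, int]] = []
    cur_start: int | None = None
    t = pos
    for op, n in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if cur_start is None:
                cur_start = t
            t += n
        elif op == 2:  # D extends the block on target
            if cur_start is None:
                cur_start = t
            t += n
        elif op == 3:  # N: skip, split blocks
            if cur_start is not None:
                blocks.append((cur_start, t))
                cur_start = None
            t += n
        elif op in (1, 4, 5):  # I, S, H
            continue
        else:
            raise ValueError(f"unsupported CIGAR op code {op}")
    if cur_start is not None:
        blocks.append((cur_start, t))
    return blocks


def read_sam(path: str | os.PathLike, rna: bool = False) -> list[AlignmentRecord]:
    """Parse a plain-text SAM file into :class:`AlignmentRecord` objects.

    Unmapped records are skipped. A missing NM tag is treated as zero
    mismatches (with a logged warning).
    """
    out: list[AlignmentRecord] = []
    missing_nm = 0
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            blocks = _blocks_from_cigar(aln.cigartuples or [], aln.reference_start)
            if aln.has_tag("NM"):
                nm = int(aln.get_tag("NM"))
            else:
                nm = 0
                missing_nm += 1
            read_length = sum(n for op, n in (aln.cigartuples or []) if op in _QUERY_OPS)
            if read_length == 0:
                read_length = aln.query_length or len(aln.query_sequence or "")
            out.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target_id=aln.reference_name,
                    target_start=aln.reference_start,
                    aligned_blocks=blocks,
                    read_length=read_length,
                    mismatches=nm,
                    is_rna=rna,
                )
            )
    if missing_nm:
        logger.warning("%d SAM records lacked an NM tag; assumed 0 mismatches", missing_nm)
    return out


def write_sam(
    records: Iterable[tuple[AlignmentRecord, str]],
    target_lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write (record, read sequence) pairs as SAM.

    Multi-block records (origin-wrapping reads on circular genomes) are
    emitted as one primary plus supplementary lines, one per block; the read
    sequence argument must then match the concatenated block lengths.
    """
    refs = sorted(target_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r, "LN": target_lengths[r]} for r in refs],
    }
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as sam:
        for rec, seq in records:
            offset = 0
            for i, (s, e) in enumerate(rec.aligned_blocks):
                a = pysam.AlignedSegment(sam.header)
                a.query_name = rec.read_id
                a.flag = 0 if i == 0 else 2048
                a.reference_id = refs.index(rec.target_id)
                a.reference_start = s
                piece = seq[offset : offset + (e - s)]
                offset += e - s
                a.query_sequence = piece
                a.cigartuples = [(0, e - s)]
                a.mapping_quality = 60
                # apportion mismatches to the first block
                a.set_tag("NM", rec.mismatches if i == 0 else 0)
                sam.write(a)
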