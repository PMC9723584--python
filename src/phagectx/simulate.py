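"""Synthetic genomes, CRISPR hosts, read alignments and two-group MSAs.

The generator emulates the statistical structure the downstream analyses
assume: ~30-34% GC circular phage genomes with ~93% coding density; a
conserved module in which the ribosomal-protein anchor gene (bS21) sits on
the reverse strand between two conserved hypothetical-protein genes, with
the core structural genes (large terminase, portal, prohead protease,
major capsid protein) within five genes; clades of related genomes made by
per-site substitution from a founder; host genomes carrying repeat-spacer
arrays whose spacers are phage substrings with a controlled number of
substitutions; DNA/RNA read alignments with gene-specific expression; and
phage/bacterial protein alignments with planted divergent columns.

All randomness flows from ``numpy.random.default_rng`` seeded from the
spec, so a fixed seed reproduces every emitted file byte for byte. The
mutation model is substitution-only (no indels), which keeps mismatch
counts exact against the spacer-matching rule and read-identity filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .divergence import GroupAlignment
from .records import AlignmentRecord, GeneAnnotation, GenomeRecord, reverse_complement

DNA = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: gene roles of the conserved module, as (role, offset from anchor, strand,
#: protein length in aa). The anchor is the only reverse-strand gene of the
#: module; structural roles all lie within five genes of it.
MODULE_LAYOUT: tuple[tuple[str, int, str, int], ...] = (
    ("TerL", -4, "+", 430),
    ("portal", -3, "+", 380),
    ("hyp_left", -1, "+", 120),
    ("bS21", 0, "-", 70),
    ("hyp_right", 1, "+", 150),
    ("prohead-protease", 2, "+", 250),
    ("MCP", 4, "+", 330),
)

#: default relative expression weights per gene role; structural genes and
#: the anchor are highly transcribed, mirroring late-stage replication.
DEFAULT_EXPRESSION = {
    "bS21": 20.0,
    "hyp_left": 8.0,
    "hyp_right": 8.0,
    "TerL": 10.0,
    "portal": 10.0,
    "prohead-protease": 10.0,
    "MCP": 30.0,
    "background": 1.0,
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic study conditions.

    ``genome_length`` defaults to 30 kb for tractable tests; 300 kb mirrors
    the real genomes' scale. GC and coding-density targets sit inside the
    ranges reported for complete genomes (31.0-33.7% GC, 91.1-94.9%
    coding density).
    """

    seed: int
    n_genomes: int = 12
    genome_length: int = 30_000
    gc_target: float = 0.32
    mean_gene_length: int = 800
    coding_density_target: float = 0.93
    n_clades: int = 3
    within_clade_divergence: float = 0.02
    clade_divergence: float = 0.06
    expression_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION)
    )
    read_length: int = 150
    depth: float = 20.0
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_clades < 1 or self.n_genomes < self.n_clades:
            raise ValueError("need n_genomes >= n_clades >= 1")
        if self.genome_length < 20 * self.mean_gene_length:
            raise ValueError(
                "genome_length too small to host the conserved module plus background genes"
            )


@dataclass
class GenomeTruth:
    """Planted structure of one synthetic phage genome."""

    genome_id: str
    clade: str
    module_genes: dict[str, str]          # role -> gene_id
    module_positions: dict[str, int]      # role -> offset from anchor
    gene_roles: dict[str, str]            # gene_id -> role
    expression_weight: dict[str, float]   # gene_id -> true relative weight


@dataclass
class SpacerTruth:
    spacer_id: str
    phage_id: str
    strand: str
    start: int
    length: int
    mismatches: int
    sequence: str


@dataclass
class HostTruth:
    genome_id: str
    array_start: int
    array_end: int
    repeat: str
    spacers: list[SpacerTruth]


@dataclass
class MsaTruth:
    divergent_columns: list[int]
    aromatic_column: int
    aromatic_counts: dict[str, int]


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(DNA, size=n, p=p))


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "M" + "".join(rng.choice(AA, size=n - 1))


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = DNA[DNA != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    idx = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in idx:
        choices = AA[AA != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def _substitute_exactly(seq: str, k: int, rng: np.random.Generator) -> str:
    """Apply exactly ``k`` substitutions at distinct random positions."""
    if k > len(seq):
        raise ValueError("more substitutions than positions")
    arr = np.array(list(seq))
    for i in rng.choice(len(arr), size=k, replace=False):
        choices = DNA[DNA != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def _ancestral_proteins(spec: SynthSpec) -> dict[str, str]:
    """Run-level ancestral module proteins, derived only from the seed."""
    rng = np.random.default_rng([spec.seed, 7])
    return {role: _random_protein(rng, aa) for role, _, _, aa in MODULE_LAYOUT}


# ---------------------------------------------------------------------------
# phage genomes
# ---------------------------------------------------------------------------

def _gene_layout(spec: SynthSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Tile the genome with gene intervals hitting the coding-density target."""
    d = spec.coding_density_target
    mean_gap0 = spec.mean_gene_length * (1 - d) / d
    # the tail past the last whole gene is wasted; shrink the gaps slightly
    # so realized density still lands on target
    exp_n_genes = spec.genome_length / (spec.mean_gene_length + mean_gap0)
    mean_gap = max(2, int(round(mean_gap0 - spec.mean_gene_length / exp_n_genes)))
    layout: list[tuple[int, int]] = []
    pos = int(rng.integers(1, 2 * mean_gap))
    while True:
        glen = int(
            np.clip(
                rng.normal(spec.mean_gene_length, 0.25 * spec.mean_gene_length),
                300,
                2.5 * spec.mean_gene_length,
            )
        )
        glen -= glen % 3
        if pos + glen > spec.genome_length - 1:
            break
        layout.append((pos, pos + glen))
        pos += glen + int(rng.integers(1, 2 * mean_gap))
    if len(layout) < len(MODULE_LAYOUT) + 6:
        raise ValueError("genome_length too small to host the conserved module")
    return layout


def generate_phage_genome(
    spec: SynthSpec,
    clade_seed: tuple[GenomeRecord, list[GeneAnnotation], GenomeTruth] | None = None,
    genome_id: str = "phage_1",
    clade: str = "clade_a",
    rng: np.random.Generator | None = None,
) -> tuple[GenomeRecord, list[GeneAnnotation], GenomeTruth]:
    """One synthetic phage genome with the conserved bS21 module planted.

    Without ``clade_seed`` a clade founder is built from scratch (module
    proteins derived from run-level ancestors at ``clade_divergence``).
    With a founder triple, a clade member is produced by per-site
    substitution of genome and proteins at ``within_clade_divergence``,
    preserving coordinates, roles and IDs modulo the new genome_id.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    if clade_seed is not None:
        f_genome, f_genes, f_truth = clade_seed
        seq = mutate_dna(f_genome.sequence, spec.within_clade_divergence, rng)
        genome = GenomeRecord(genome_id, seq, circular=True)
        genes = []
        id_map: dict[str, str] = {}
        for fg in f_genes:
            new_id = fg.gene_id.replace(f_truth.genome_id, genome_id, 1)
            id_map[fg.gene_id] = new_id
            prot = (
                mutate_protein(fg.protein, spec.within_clade_divergence, rng)
                if fg.protein
                else None
            )
            genes.append(
                GeneAnnotation(
                    new_id, genome_id, fg.start, fg.end, fg.strand,
                    fg.product_label, prot,
                )
            )
        jitter = np.exp(rng.normal(0.0, 0.5, size=len(genes)))
        truth = GenomeTruth(
            genome_id=genome_id,
            clade=clade,
            module_genes={r: id_map[g] for r, g in f_truth.module_genes.items()},
            module_positions=dict(f_truth.module_positions),
            gene_roles={id_map[g]: r for g, r in f_truth.gene_roles.items()},
            expression_weight={
                g.gene_id: spec.expression_profile.get(
                    f_truth.gene_roles[fg.gene_id], 1.0
                ) * float(j)
                for g, fg, j in zip(genes, f_genes, jitter)
            },
        )
        return genome, genes, truth

    layout = _gene_layout(spec, rng)
    anchor_idx = len(layout) // 2
    ancestors = _ancestral_proteins(spec)
    role_by_idx: dict[int, tuple[str, str, int]] = {}
    for role, off, strand, aa in MODULE_LAYOUT:
        role_by_idx[anchor_idx + off] = (role, strand, aa)

    genes: list[GeneAnnotation] = []
    gene_roles: dict[str, str] = {}
    module_genes: dict[str, str] = {}
    weights: dict[str, float] = {}
    seq_parts = np.array(list(_random_dna(rng, spec.genome_length, spec.gc_target)))
    for i, (s, e) in enumerate(layout):
        gid = f"{genome_id}_g{i + 1}"
        if i in role_by_idx:
            role, strand, aa = role_by_idx[i]
            prot = mutate_protein(ancestors[role], spec.clade_divergence, rng)
            label = "" if role.startswith("hyp") else role
        else:
            role, strand, label = "background", "+", ""
            prot = _random_protein(rng, max(50, (e - s) // 3 - 1))
        genes.append(GeneAnnotation(gid, genome_id, s, e, strand, label, prot))
        gene_roles[gid] = role
        if role != "background":
            module_genes[role] = gid
        weights[gid] = spec.expression_profile.get(role, 1.0) * float(
            np.exp(rng.normal(0.0, 0.5))
        )

    genome = GenomeRecord(genome_id, "".join(seq_parts), circular=True)
    truth = GenomeTruth(
        genome_id=genome_id,
        clade=clade,
        module_genes=module_genes,
        module_positions={role: off for role, off, _, _ in MODULE_LAYOUT},
        gene_roles=gene_roles,
        expression_weight=weights,
    )
    return genome, genes, truth


def generate_cohort(
    spec: SynthSpec,
) -> tuple[list[GenomeRecord], list[GeneAnnotation], dict[str, GenomeTruth]]:
    """``n_genomes`` split as evenly as possible over ``n_clades`` clades."""
    rng = np.random.default_rng(spec.seed)
    sizes = [
        spec.n_genomes // spec.n_clades + (1 if c < spec.n_genomes % spec.n_clades else 0)
        for c in range(spec.n_clades)
    ]
    genomes: list[GenomeRecord] = []
    genes: list[GeneAnnotation] = []
    truths: dict[str, GenomeTruth] = {}
    for c, size in enumerate(sizes):
        clade = f"clade_{chr(ord('a') + c)}"
        founder = generate_phage_genome(
            spec, None, genome_id=f"phage_{clade}_1", clade=clade, rng=rng
        )
        bundle = [founder]
        for j in range(1, size):
            bundle.append(
                generate_phage_genome(
                    spec, founder, genome_id=f"phage_{clade}_{j + 1}", clade=clade,
                    rng=rng,
                )
            )
        for g, gl, t in bundle:
            genomes.append(g)
            genes.extend(gl)
            truths[g.genome_id] = t
    return genomes, genes, truths


# ---------------------------------------------------------------------------
# CRISPR hosts
# ---------------------------------------------------------------------------

def generate_host_with_crispr(
    phages: list[GenomeRecord],
    n_spacers: int,
    mismatch_counts: list[int],
    spec: SynthSpec,
    spacer_lengths: list[int] | None = None,
    host_id: str = "host_1",
    host_length: int = 20_000,
    repeat_length: int = 30,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeRecord, HostTruth]:
    """A host genome carrying one repeat-spacer array sampling phage protospacers.

    Each spacer is a phage substring (either strand) carrying exactly the
    requested number of substitutions; repeats are exact copies. The array
    has ``n_spacers + 1`` repeat copies, so at least three when two or more
    spacers are requested.
    """
    if len(mismatch_counts) != n_spacers:
        raise ValueError("n_spacers must equal len(mismatch_counts)")
    if any(k < 0 for k in mismatch_counts):
        raise ValueError("mismatch counts must be non-negative")
    if rng is None:
        rng = np.random.default_rng([spec.seed, 11])

    repeat = _random_dna(rng, repeat_length, 0.45)
    spacers: list[SpacerTruth] = []
    parts = [repeat]
    for i in range(n_spacers):
        slen = (
            spacer_lengths[i]
            if spacer_lengths is not None
            else int(rng.integers(24, 37))
        )
        # resample until array boundaries are identifiable: if every spacer
        # started (or ended) with the same base, that base would be an exact
        # extension of the repeat and the planted boundary unrecoverable in
        # principle; forcing spacer 2 to differ from spacer 1 at both ends
        # breaks the ambiguity
        for _ in range(100):
            phage = phages[int(rng.integers(len(phages)))]
            if len(phage) < slen:
                raise ValueError(
                    f"phage {phage.genome_id!r} too short for a {slen} nt spacer"
                )
            start = int(rng.integers(0, len(phage) - slen + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            proto = phage.sequence[start : start + slen]
            if strand == "-":
                proto = reverse_complement(proto)
            spacer_seq = _substitute_exactly(proto, mismatch_counts[i], rng)
            if i != 1 or (
                spacer_seq[0] != spacers[0].sequence[0]
                and spacer_seq[-1] != spacers[0].sequence[-1]
            ):
                break
        sid = f"{host_id}_sp{i + 1}"
        spacers.append(
            SpacerTruth(sid, phage.genome_id, strand, start, slen,
                        mismatch_counts[i], spacer_seq)
        )
        parts.extend([spacer_seq, repeat])

    array = "".join(parts)
    flank = _random_dna(rng, host_length, 0.45)
    ins = int(rng.integers(1000, host_length - 1000))
    seq = flank[:ins] + array + flank[ins:]
    genome = GenomeRecord(host_id, seq)
    truth = HostTruth(host_id, ins, ins + len(array), repeat, spacers)
    return genome, truth


# ---------------------------------------------------------------------------
# read alignments
# ---------------------------------------------------------------------------

def simulate_alignments_with_seqs(
    genome: GenomeRecord,
    genes: list[GeneAnnotation],
    spec: SynthSpec,
    rna: bool,
    truth: GenomeTruth | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[AlignmentRecord, str]]:
    """Simulated reads as (record, read sequence) pairs.

    DNA mode draws start positions uniformly over the genome, wrapping the
    origin on circular genomes (emitted as two aligned blocks). RNA mode
    draws reads per gene with probability proportional to true expression
    weight x gene length and keeps each read wholly inside its source gene.
    Per-read mismatch counts are Binomial(read_length, error_rate) and are
    applied to the emitted sequence.
    """
    if spec.depth <= 0:
        raise ValueError("depth must be positive")
    if rng is None:
        rng = np.random.default_rng([spec.seed, 13])
    L = len(genome)
    rl = spec.read_length
    n_reads = int(round(spec.depth * L / rl))
    out: list[tuple[AlignmentRecord, str]] = []

    if rna:
        if truth is None:
            raise ValueError("RNA simulation needs the genome truth for weights")
        weights = np.array([truth.expression_weight[g.gene_id] * g.length for g in genes])
        probs = weights / weights.sum()
        counts = rng.multinomial(n_reads, probs)
        ridx = 0
        for g, cnt in zip(genes, counts):
            glen = g.length
            eff_rl = min(rl, glen)
            for _ in range(cnt):
                s = g.start + int(rng.integers(0, glen - eff_rl + 1))
                mm = int(rng.binomial(eff_rl, spec.error_rate))
                seq = _substitute_exactly(genome.sequence[s : s + eff_rl], mm, rng)
                ridx += 1
                out.append(
                    (
                        AlignmentRecord(
                            f"{genome.genome_id}_rna{ridx}", genome.genome_id,
                            s, [(s, s + eff_rl)], eff_rl, mm, is_rna=True,
                        ),
                        seq,
                    )
                )
        return out

    for i in range(n_reads):
        if genome.circular:
            s = int(rng.integers(0, L))
        else:
            s = int(rng.integers(0, max(1, L - rl + 1)))
        mm = int(rng.binomial(rl, spec.error_rate))
        if s + rl <= L:
            blocks = [(s, s + rl)]
            seq = genome.sequence[s : s + rl]
        else:  # wrap the origin: two blocks
            over = s + rl - L
            blocks = [(0, over), (s, L)]
            seq = genome.sequence[0:over] + genome.sequence[s:L]
        seq = _substitute_exactly(seq, mm, rng)
        out.append(
            (
                AlignmentRecord(
                    f"{genome.genome_id}_dna{i + 1}", genome.genome_id,
                    blocks[0][0], blocks, rl, mm, is_rna=False,
                ),
                seq,
            )
        )
    return out


def simulate_alignments(
    genome: GenomeRecord,
    genes: list[GeneAnnotation],
    spec: SynthSpec,
    rna: bool,
    truth: GenomeTruth | None = None,
    rng: np.random.Generator | None = None,
) -> list[AlignmentRecord]:
    return [rec for rec, _ in
            simulate_alignments_with_seqs(genome, genes, spec, rna, truth, rng)]


# ---------------------------------------------------------------------------
# two-group MSA
# ---------------------------------------------------------------------------

def generate_group_msa(
    n_phage: int,
    n_bact: int,
    length: int,
    divergent_columns: list[int],
    aromatic_column: int,
    seed: int,
    conservation: float = 0.95,
) -> tuple[GroupAlignment, MsaTruth]:
    """Two-group protein alignment with planted divergent columns.

    Background columns share one consensus residue across both groups; at
    each divergent column the two group consensuses differ and each group
    is at least 90% internally conserved (enforced by construction). At the
    aromatic column every sequence carries Y, H or F with Y predominant.
    """
    cols = set(divergent_columns)
    if len(cols) != len(divergent_columns):
        raise ValueError("duplicate divergent columns")
    if aromatic_column in cols:
        raise ValueError("aromatic column overlaps divergent columns")
    for c in list(cols) + [aromatic_column]:
        if not (0 <= c < length):
            raise ValueError(f"column {c} outside [0, {length})")

    rng = np.random.default_rng(seed)
    n = n_phage + n_bact
    mat = np.empty((n, length), dtype="<U1")

    def fill(col: int, rows: np.ndarray, consensus: str) -> None:
        draw = rng.random(len(rows)) < conservation
        others = AA[AA != consensus]
        residues = np.where(draw, consensus, "")
        for i in np.flatnonzero(~draw):
            residues[i] = rng.choice(others)
        # keep each group >= 90% conserved at planted columns by construction
        need = int(np.ceil(0.9 * len(rows)))
        have = int((residues == consensus).sum())
        if have < need:
            off = np.flatnonzero(residues != consensus)
            for i in rng.choice(off, size=need - have, replace=False):
                residues[i] = consensus
        mat[rows, col] = residues

    phage_rows = np.arange(n_phage)
    bact_rows = np.arange(n_phage, n)
    for col in range(length):
        if col == aromatic_column:
            mat[:, col] = rng.choice(
                np.array(["Y", "H", "F"]), size=n, p=[0.8, 0.15, 0.05]
            )
        elif col in cols:
            cons_a, cons_b = rng.choice(AA, size=2, replace=False)
            fill(col, phage_rows, str(cons_a))
            fill(col, bact_rows, str(cons_b))
        else:
            consensus = str(rng.choice(AA))
            fill(col, phage_rows, consensus)
            fill(col, bact_rows, consensus)

    group_a = ["".join(mat[i]) for i in range(n_phage)]
    group_b = ["".join(mat[i]) for i in range(n_phage, n)]
    ids_a = [f"phage_bs21_{i + 1}" for i in range(n_phage)]
    ids_b = [f"bact_bs21_{i + 1}" for i in range(n_bact)]
    msa = GroupAlignment(
        columns=length,
        group_a=group_a,
        group_b=group_b,
        ids_a=ids_a,
        ids_b=ids_b,
    )
    col = mat[:, aromatic_column]
    counts = {res: int((col == res).sum()) for res in ("Y", "H", "F") if (col == res).any()}
    truth = MsaTruth(sorted(cols), aromatic_column, counts)
    return msa, truth
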