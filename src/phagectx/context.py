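"""Anchor-gene genomic-neighborhood profiling.

This is the heart of the pipeline: gather the ±10 ORFs around each anchor
gene (the phage-encoded ribosomal protein bS21), cluster the neighbor
proteins into families by greedy centroid clustering under a mutual-
coverage constraint, assign each family a consensus annotation from
precomputed HMM/database hit tables, and summarize family occurrence as a
function of relative position to the anchor. Genomes can additionally be
clustered by family presence/absence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, to_tree
from scipy.spatial.distance import pdist

from ._align import global_identity, mutual_coverage
from .records import GeneAnnotation


@dataclass
class Neighborhood:
    """The anchor gene and up to ``radius`` genes on each side, in scaffold
    coordinate order. Positions are negative before the anchor (lower
    start coordinate), positive after; truncation at scaffold ends simply
    shortens the window."""

    anchor_gene_id: str
    genome_id: str
    neighbors: list[tuple[str, int, bool]]  # (gene_id, position, same_strand_as_anchor)


@dataclass
class ProteinFamily:
    family_id: str
    member_protein_ids: list[str]
    centroid_id: str
    consensus_label: str = "hyp"


@dataclass
class AnnotationHit:
    protein_id: str
    label: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


@dataclass
class PositionProfile:
    """Counts of genomes carrying a family member at each relative position,
    plus the per-family mean absolute distance to the anchor."""

    counts: pd.DataFrame            # long: family_id, position, count
    mean_abs_distance: dict[str, float]
    n_neighborhoods: int


def extract_neighborhood(
    genes: list[GeneAnnotation],
    anchor_id: str,
    radius: int = 10,
    reorient_marker_label: str | None = None,
) -> Neighborhood:
    """Window of up to ``radius`` genes each side of the anchor.

    ``genes`` must all belong to one genome and be sorted by start. With
    ``reorient_marker_label`` set (e.g. "MCP"), all position signs are
    flipped when every gene bearing that product label lies at negative
    positions, giving mirror-image genomes identical profiles.
    """
    idx = next((i for i, g in enumerate(genes) if g.gene_id == anchor_id), None)
    if idx is None:
        raise ValueError(f"anchor {anchor_id!r} not among the supplied genes")
    anchor = genes[idx]
    lo = max(0, idx - radius)
    hi = min(len(genes), idx + radius + 1)
    neighbors = [
        (g.gene_id, i - idx, g.strand == anchor.strand)
        for i, g in enumerate(genes[lo:hi], start=lo)
    ]
    if reorient_marker_label:
        marker_pos = [
            pos
            for (gid, pos, _), g in zip(neighbors, genes[lo:hi])
            if g.product_label == reorient_marker_label
        ]
        if marker_pos and all(p < 0 for p in marker_pos):
            neighbors = [(gid, -pos, s) for gid, pos, s in neighbors]
            neighbors.sort(key=lambda t: t[1])
    return Neighborhood(anchor_id, anchor.genome_id, neighbors)


def cluster_families(
    proteins: list[tuple[str, str]],
    identity_threshold: float = 0.30,
    coverage: float = 0.75,
) -> list[ProteinFamily]:
    """Greedy centroid clustering of proteins into families.

    Proteins are visited sorted by length descending then ID; each joins
    the first existing centroid it matches at >= ``identity_threshold``
    global identity with mutual alignment coverage >= ``coverage``, else
    founds a new family. The sort makes the partition independent of input
    order.
    """
    for pid, seq in proteins:
        if not seq:
            raise ValueError(f"protein {pid!r} has an empty sequence")
    ordered = sorted(proteins, key=lambda p: (-len(p[1]), p[0]))
    centroids: list[tuple[str, str]] = []
    members: dict[str, list[str]] = {}
    for pid, seq in ordered:
        placed = False
        for cid, cseq in centroids:
            if mutual_coverage(seq, cseq) >= coverage and (
                global_identity(seq, cseq) >= identity_threshold
            ):
                members[cid].append(pid)
                placed = True
                break
        if not placed:
            centroids.append((pid, seq))
            members[pid] = [pid]
    return [
        ProteinFamily(
            family_id=f"fam{i + 1}",
            member_protein_ids=sorted(members[cid]),
            centroid_id=cid,
        )
        for i, (cid, _) in enumerate(centroids)
    ]


def consensus_annotation(
    family: ProteinFamily,
    hits: list[AnnotationHit],
    e_max: float = 1e-5,
    min_frac: float = 0.05,
) -> str:
    """Most-supported label among sub-threshold hits, else "hyp".

    A label's support is the number of distinct member proteins it hits
    with e-value < ``e_max``; the winner must cover at least ``min_frac``
    of the family. Ties break lexicographically by label.
    """
    member_set = set(family.member_protein_ids)
    support: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.protein_id in member_set and h.e_value < e_max:
            support[h.label].add(h.protein_id)
    if not support:
        return "hyp"
    best = min(support, key=lambda lab: (-len(support[lab]), lab))
    if len(support[best]) >= min_frac * len(member_set):
        return best
    return "hyp"


def assign_families(
    families: list[ProteinFamily], hits: list[AnnotationHit] | None = None
) -> dict[str, str]:
    """protein/gene id -> family_id map; optionally fills consensus labels."""
    assignment: dict[str, str] = {}
    for fam in families:
        if hits is not None:
            fam.consensus_label = consensus_annotation(fam, hits)
        for pid in fam.member_protein_ids:
            assignment[pid] = fam.family_id
    return assignment


def position_profile(
    neighborhoods: list[Neighborhood],
    family_of: dict[str, str],
    top_k: int | None = None,
) -> PositionProfile:
    """Family x relative-position genome counts.

    Each genome contributes at most one count to a (family, position)
    cell, matching a per-phage (not per-gene) tally; a genome with several
    anchors still counts once per cell. ``top_k`` keeps only the families
    present in the most genomes overall.
    """
    cell_genomes: dict[tuple[str, int], set[str]] = defaultdict(set)
    fam_distances: dict[str, list[int]] = defaultdict(list)
    fam_genomes: dict[str, set[str]] = defaultdict(set)
    for nb in neighborhoods:
        for gid, pos, _ in nb.neighbors:
            fam = family_of.get(gid)
            if fam is None:
                raise ValueError(f"gene {gid!r} has no family assignment")
            cell_genomes[(fam, pos)].add(nb.genome_id)
            fam_distances[fam].append(abs(pos))
            fam_genomes[fam].add(nb.genome_id)
    if top_k is not None:
        keep = sorted(
            fam_genomes, key=lambda f: (-len(fam_genomes[f]), f)
        )[:top_k]
        keep_set = set(keep)
    else:
        keep_set = set(fam_genomes)
    rows = [
        {"family_id": fam, "position": pos, "count": len(gs)}
        for (fam, pos), gs in cell_genomes.items()
        if fam in keep_set
    ]
    counts = pd.DataFrame(rows, columns=["family_id", "position", "count"])
    counts = counts.sort_values(["family_id", "position"]).reset_index(drop=True)
    mean_abs = {
        fam: float(np.mean(d)) for fam, d in sorted(fam_distances.items())
        if fam in keep_set
    }
    return PositionProfile(counts, mean_abs, len(neighborhoods))


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6f},{right}:{dr:.6f})"


def presence_absence_clustering(
    genome_genes: dict[str, list[GeneAnnotation]],
    genome_lengths: dict[str, int],
    family_of: dict[str, str],
    min_genome_bp: int = 100_000,
) -> tuple[int, pd.DataFrame, str, dict[str, int]]:
    """Cluster genomes by protein-family presence/absence.

    Genomes shorter than ``min_genome_bp`` are dropped. Returns the number
    of families shared by *all* retained genomes, the Jaccard distance
    matrix (genome x genome, IDs sorted), an average-linkage dendrogram as
    a Newick string, and a genome -> cluster map cut at the number of
    flat clusters that maximizes separation (callers wanting k clusters
    can re-cut with :func:`cut_dendrogram`).
    """
    kept = sorted(
        gid for gid, L in genome_lengths.items() if L >= min_genome_bp
    )
    if len(kept) < 2:
        raise ValueError("need at least two genomes above the size filter")
    fam_sets = {
        gid: {family_of[g.gene_id] for g in genome_genes[gid] if g.gene_id in family_of}
        for gid in kept
    }
    all_fams = sorted(set().union(*fam_sets.values()))
    shared = [f for f in all_fams if all(f in fam_sets[g] for g in kept)]
    mat = np.array(
        [[1 if f in fam_sets[g] else 0 for f in all_fams] for g in kept], dtype=bool
    )
    dist = pdist(mat, metric="jaccard")
    dm = pd.DataFrame(
        np.zeros((len(kept), len(kept))), index=kept, columns=kept
    )
    k = 0
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            dm.iat[i, j] = dm.iat[j, i] = dist[k]
            k += 1
    linkage = average(dist)
    tree = to_tree(linkage)
    newick = _newick(tree, kept) + ";"
    # default flat cut at the largest merge-height gap
    heights = sorted(linkage[:, 2])
    if len(heights) > 1:
        gaps = np.diff([0.0] + heights)
        cut_idx = int(np.argmax(gaps))
        threshold = ([0.0] + heights)[cut_idx] + gaps[cut_idx] / 2
    else:
        threshold = heights[0] / 2 if heights else 0.0
    labels = fcluster(linkage, t=threshold, criterion="distance")
    clusters = {g: int(c) for g, c in zip(kept, labels)}
    return len(shared), dm, newick, clusters


def cut_dendrogram(
    genome_genes: dict[str, list[GeneAnnotation]],
    genome_lengths: dict[str, int],
    family_of: dict[str, str],
    n_clusters: int,
    min_genome_bp: int = 100_000,
) -> dict[str, int]:
    """Flat clustering at a requested number of clusters."""
    kept = sorted(gid for gid, L in genome_lengths.items() if L >= min_genome_bp)
    fam_sets = {
        gid: {family_of[g.gene_id] for g in genome_genes[gid] if g.gene_id in family_of}
        for gid in kept
    }
    all_fams = sorted(set().union(*fam_sets.values()))
    mat = np.array(
        [[1 if f in fam_sets[g] else 0 for f in all_fams] for g in kept], dtype=bool
    )
    linkage = average(pdist(mat, metric="jaccard"))
    labels = fcluster(linkage, t=n_clusters, criterion="maxclust")
    return {g: int(c) for g, c in zip(kept, labels)}
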