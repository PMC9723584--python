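"""CRISPR repeat-spacer array detection and spacer-to-protospacer matching.

Host prediction follows a dual threshold: an ungapped spacer-target match
counts if it spans at least 24 nt with at most one mismatch, or at least
30 nt with at most three mismatches. Matching is substitution-only
(Hamming); both target strands are searched exhaustively, so the final
filter — not a heuristic pre-search — defines the result.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from .records import CrisprArray, GenomeRecord, SpacerHit, reverse_complement

logger = logging.getLogger(__name__)

RULE_SHORT = "24nt_le1mm"
RULE_LONG = "30nt_le3mm"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def detect_arrays(
    genome: GenomeRecord,
    min_repeats: int = 3,
    repeat_len_range: tuple[int, int] = (21, 48),
    spacer_len_range: tuple[int, int] = (18, 72),
    max_repeat_mismatch: int = 2,
) -> list[CrisprArray]:
    """Find maximal runs of near-identical repeats separated by spacers.

    A seed of length ``repeat_len_range[0]`` anchors candidate repeat
    starts; runs of at least ``min_repeats`` copies whose start-to-start
    periods are compatible with the repeat/spacer length windows are then
    extended to the longest repeat length at which every copy stays within
    ``max_repeat_mismatch`` of the first and every gap is a legal spacer.
    Arrays are reported leftmost-first and never overlap. Copies whose
    leading seed itself is mutated are not found; exact-repeat arrays (the
    generator's default) are recovered exactly.
    """
    seq = genome.sequence
    k = repeat_len_range[0]
    rmin, rmax = repeat_len_range
    smin, smax = spacer_len_range
    if len(seq) < min_repeats * (rmin + smin):
        return []
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i : i + k]].append(i)

    arrays: list[CrisprArray] = []
    claimed_until = -1
    min_period, max_period = rmin + smin, rmax + smax
    for i in range(len(seq) - k + 1):
        if i <= claimed_until:
            continue
        occ = [p for p in positions[seq[i : i + k]] if p >= i]
        if len(occ) < min_repeats or occ[0] != i:
            continue
        # chain occurrences with legal periods
        chain = [i]
        for p in occ[1:]:
            gap = p - chain[-1]
            if min_period <= gap <= max_period:
                chain.append(p)
            elif gap > max_period:
                break
        if len(chain) < min_repeats:
            continue
        min_gap = min(b - a for a, b in zip(chain, chain[1:]))
        # extend repeat length while copies stay near-identical and the
        # inter-copy gaps remain legal spacers
        best_r = None
        for r in range(rmin, min(rmax, min_gap - smin) + 1):
            first = seq[i : i + r]
            if all(
                _hamming(seq[p : p + r], first) <= max_repeat_mismatch
                for p in chain[1:]
            ):
                best_r = r
            else:
                break
        if best_r is None:
            continue
        # trim the end back to columns unanimous across all copies: the
        # mismatch budget must not absorb the first bases of the spacers
        while best_r > rmin and len(
            {seq[p + best_r - 1] for p in chain}
        ) > 1:
            best_r -= 1
        r = best_r
        spacer_seqs = [
            seq[a + r : b] for a, b in zip(chain, chain[1:])
        ]
        if not all(smin <= len(s) <= smax for s in spacer_seqs):
            continue
        end = chain[-1] + r
        arrays.append(
            CrisprArray(
                genome_id=genome.genome_id,
                start=i,
                end=end,
                repeat_consensus=seq[i : i + r],
                spacers=[
                    (f"{genome.genome_id}_arr{len(arrays) + 1}_sp{j + 1}", s)
                    for j, s in enumerate(spacer_seqs)
                ],
            )
        )
        claimed_until = end - 1
    return arrays


def _scan_strand(
    sp_arr: np.ndarray, t_arr: np.ndarray
) -> list[tuple[int, int, int]]:
    """All (target_start, length, mismatches) qualifying ungapped windows of
    a spacer against one target strand, vectorized over every full-spacer
    alignment frame at once."""
    m, L = len(sp_arr), len(t_arr)
    if L < 24:
        return []
    span = min(m, L)
    frames = np.lib.stride_tricks.sliding_window_view(t_arr, span)
    eq = frames == sp_arr[:span]
    prefix = np.zeros((eq.shape[0], span + 1), dtype=np.int32)
    np.cumsum(~eq, axis=1, out=prefix[:, 1:])
    found: list[tuple[int, int, int]] = []
    for length in range(24, span + 1):
        limit = 3 if length >= 30 else 1
        for off in range(span - length + 1):
            mm = prefix[:, off + length] - prefix[:, off]
            for p in np.flatnonzero(mm <= limit):
                found.append((int(p) + off, length, int(mm[p])))
    return found


def _dedupe(hits: list[SpacerHit]) -> list[SpacerHit]:
    """Keep one hit per (spacer, target, strand, locus): scan candidates by
    length desc, mismatches asc, leftmost, greedily suppressing any later
    candidate overlapping an accepted one on the target."""
    by_key: dict[tuple[str, str, str], list[SpacerHit]] = defaultdict(list)
    for h in hits:
        by_key[(h.spacer_id, h.target_genome_id, h.strand)].append(h)
    kept: list[SpacerHit] = []
    for key in sorted(by_key):
        cands = sorted(
            by_key[key], key=lambda h: (-h.match_length, h.mismatches, h.target_start)
        )
        accepted: list[SpacerHit] = []
        for h in cands:
            hs, he = h.target_start, h.target_start + h.match_length
            if all(
                he <= a.target_start or hs >= a.target_start + a.match_length
                for a in accepted
            ):
                accepted.append(h)
        kept.extend(sorted(accepted, key=lambda h: h.target_start))
    return kept


def match_spacers(
    spacers: list[tuple[str, str]],
    targets: list[GenomeRecord],
    dedupe: bool = True,
) -> list[SpacerHit]:
    """Every spacer-target ungapped match satisfying the dual rule.

    Both strands are searched (coordinates reported on the target's forward
    strand). Overlapping qualifying windows at one locus reduce to the
    maximal-length, minimal-mismatch, leftmost one when ``dedupe`` is on.
    Spacers shorter than 24 nt are skipped with a warning.
    """
    hits: list[SpacerHit] = []
    for spacer_id, sp in spacers:
        sp = sp.upper()
        m = len(sp)
        if m < 24:
            logger.warning("spacer %s shorter than 24 nt: skipped", spacer_id)
            continue
        sp_arr = np.frombuffer(sp.encode(), dtype=np.uint8)
        for target in targets:
            for strand in "+-":
                tseq = target.sequence if strand == "+" else reverse_complement(
                    target.sequence
                )
                L = len(tseq)
                t_arr = np.frombuffer(tseq.encode(), dtype=np.uint8)
                for start, length, mm in _scan_strand(sp_arr, t_arr):
                    fstart = start if strand == "+" else L - (start + length)
                    hits.append(
                        SpacerHit(
                            spacer_id=spacer_id,
                            target_genome_id=target.genome_id,
                            target_start=fstart,
                            strand=strand,
                            match_length=length,
                            mismatches=mm,
                            rule=RULE_SHORT if mm <= 1 else RULE_LONG,
                        )
                    )
    if dedupe:
        hits = _dedupe(hits)
    hits.sort(
        key=lambda h: (h.spacer_id, h.target_genome_id, h.target_start, h.strand)
    )
    return hits


def predict_hosts(
    hits: list[SpacerHit],
    spacer_to_host: dict[str, str],
    host_taxonomy: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate spacer hits into a phage -> host prediction table.

    Columns: phage_genome, host_genome, taxonomy, n_hits. An empty hit
    list yields an empty table (a valid outcome: most spacer searches
    find nothing).
    """
    rows: dict[tuple[str, str], int] = defaultdict(int)
    for h in hits:
        if h.spacer_id not in spacer_to_host:
            raise ValueError(f"spacer {h.spacer_id!r} has no host mapping")
        rows[(h.target_genome_id, spacer_to_host[h.spacer_id])] += 1
    tax = host_taxonomy or {}
    table = pd.DataFrame(
        [
            {
                "phage_genome": phage,
                "host_genome": host,
                "taxonomy": tax.get(host, ""),
                "n_hits": n,
            }
            for (phage, host), n in sorted(rows.items())
        ],
        columns=["phage_genome", "host_genome", "taxonomy", "n_hits"],
    )
    return table
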