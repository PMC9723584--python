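"""Two-group protein-alignment analysis: per-column conservation and
divergence, consensus sequences, the aromatic-residue check, and reference
residue numbering.

The divergence statistic is an explicit modal-frequency rule: a column is
*divergent* when each group is internally conserved (modal non-gap
frequency at least ``tau_group`` in both) yet the two modal residues
differ; it is *conserved* when the pooled modal frequency reaches
``tau_cons``. This flags exactly the group-specific conserved differences
that distinguish phage from bacterial bS21 (e.g. the handful of divergent
N-terminal residues), with thresholds exposed rather than hidden inside an
external scorer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

GAP = "-"
AROMATIC = frozenset("FYWH")


@dataclass
class GroupAlignment:
    """A two-group MSA; group A = phage sequences, group B = bacterial."""

    columns: int
    group_a: list[str]
    group_b: list[str]
    ids_a: list[str]
    ids_b: list[str]

    def __post_init__(self) -> None:
        for seq in self.group_a + self.group_b:
            if len(seq) != self.columns:
                raise ValueError("alignment rows must all equal `columns` in length")
        if len(self.ids_a) != len(self.group_a) or len(self.ids_b) != len(self.group_b):
            raise ValueError("ids and sequences out of step")

    @property
    def all_ids(self) -> list[str]:
        return self.ids_a + self.ids_b

    @property
    def all_seqs(self) -> list[str]:
        return self.group_a + self.group_b

    def sequence(self, seq_id: str) -> str:
        for sid, seq in zip(self.all_ids, self.all_seqs):
            if sid == seq_id:
                return seq
        raise KeyError(f"sequence {seq_id!r} not in alignment")


@dataclass
class ColumnStat:
    column: int
    modal_residue_a: str
    modal_freq_a: float
    modal_residue_b: str
    modal_freq_b: float
    divergent: bool
    conserved: bool
    callable: bool
    ref_position: int | None = None


def _modal(residues: list[str]) -> tuple[str, float]:
    """Modal non-gap residue and its frequency among non-gap residues.

    Ties break alphabetically; an all-gap column reports ('-', 0.0).
    """
    non_gap = [r for r in residues if r != GAP]
    if not non_gap:
        return GAP, 0.0
    counts = Counter(non_gap)
    best = min(counts, key=lambda r: (-counts[r], r))
    return best, counts[best] / len(non_gap)


def column_stats(
    msa: GroupAlignment,
    tau_group: float = 0.7,
    tau_cons: float = 0.9,
    max_gap_frac: float = 0.5,
    ref_id: str | None = None,
) -> list[ColumnStat]:
    """Per-column modal residues, divergence and conservation calls.

    Columns whose overall gap fraction exceeds ``max_gap_frac`` are flagged
    uncallable and never divergent/conserved. When ``ref_id`` is given,
    each column also carries the 1-based residue number it maps to in that
    reference sequence (None at reference gaps).
    """
    if not msa.group_a or not msa.group_b:
        raise ValueError("both groups must be non-empty")
    ref_map = map_reference_numbering(msa, ref_id) if ref_id is not None else {}
    n_total = len(msa.group_a) + len(msa.group_b)
    stats: list[ColumnStat] = []
    for col in range(msa.columns):
        col_a = [s[col] for s in msa.group_a]
        col_b = [s[col] for s in msa.group_b]
        gap_frac = (col_a + col_b).count(GAP) / n_total
        mod_a, freq_a = _modal(col_a)
        mod_b, freq_b = _modal(col_b)
        mod_all, freq_all = _modal(col_a + col_b)
        ok = gap_frac <= max_gap_frac
        divergent = (
            ok
            and mod_a != GAP
            and mod_b != GAP
            and mod_a != mod_b
            and freq_a >= tau_group
            and freq_b >= tau_group
        )
        conserved = ok and mod_all != GAP and freq_all >= tau_cons
        stats.append(
            ColumnStat(
                column=col,
                modal_residue_a=mod_a,
                modal_freq_a=freq_a,
                modal_residue_b=mod_b,
                modal_freq_b=freq_b,
                divergent=divergent,
                conserved=conserved,
                callable=ok,
                ref_position=ref_map.get(col),
            )
        )
    return stats


def consensus_sequence(group: list[str], threshold: float = 0.5) -> str:
    """Majority consensus: modal non-gap residue when its non-gap frequency
    reaches ``threshold``, else 'x'; columns that are >50% gaps emit '-'."""
    if not group:
        raise ValueError("empty group")
    length = len(group[0])
    out = []
    for col in range(length):
        residues = [s[col] for s in group]
        if residues.count(GAP) / len(residues) > 0.5:
            out.append(GAP)
            continue
        mod, freq = _modal(residues)
        out.append(mod if freq >= threshold else "x")
    return "".join(out)


def map_reference_numbering(msa: GroupAlignment, ref_id: str) -> dict[int, int | None]:
    """Alignment column -> 1-based residue number in the reference sequence.

    Gap columns of the reference map to None; non-gap columns biject onto
    1..len(ungapped reference).
    """
    ref = msa.sequence(ref_id)
    mapping: dict[int, int | None] = {}
    residue = 0
    for col, ch in enumerate(ref):
        if ch == GAP:
            mapping[col] = None
        else:
            residue += 1
            mapping[col] = residue
    return mapping


def aromatic_check(
    msa: GroupAlignment, ref_id: str, ref_residue_number: int
) -> list[tuple[str, str, bool]]:
    """Residue carried by every sequence at a reference-numbered position.

    Returns (sequence_id, residue, is_aromatic) rows, where aromatic means
    membership in {F, Y, W, H}; a gap reports '-' and False. Mirrors the
    Tyr54-style check on the ASD-blocking position.
    """
    numbering = map_reference_numbering(msa, ref_id)
    col = next(
        (c for c, num in numbering.items() if num == ref_residue_number), None
    )
    if col is None:
        raise ValueError(
            f"residue {ref_residue_number} beyond the ungapped length of {ref_id!r}"
        )
    rows = []
    for sid, seq in zip(msa.all_ids, msa.all_seqs):
        res = seq[col]
        rows.append((sid, res, res in AROMATIC))
    return rows


def aromatic_summary(rows: list[tuple[str, str, bool]]) -> dict[str, int]:
    """Counts per residue observed at the checked position."""
    counts: Counter[str] = Counter(res for _, res, _ in rows)
    return dict(sorted(counts.items()))
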