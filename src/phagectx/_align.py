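"""Pairwise global identity used by protein-family and marker dereplication.

Identity between two sequences is defined from the global (Needleman-
Wunsch) edit distance d as ``1 - d / max(len_a, len_b)``; because the
alignment is global it spans both sequences entirely, so the mutual
alignment coverage is ``min(len_a, len_b) / max(len_a, len_b)``. Both are
conservative (an edit distance never undercounts differences) and exact for
the substitution-only sequences the synthetic generator emits.
"""

from __future__ import annotations

import edlib


def global_identity(a: str, b: str) -> float:
    if not a or not b:
        raise ValueError("empty sequence")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def mutual_coverage(a: str, b: str) -> float:
    if not a or not b:
        raise ValueError("empty sequence")
    return min(len(a), len(b)) / max(len(a), len(b))
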