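"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's code paths: alignment statistics come
from a plain scalar three-state Gotoh dynamic program over lexicographic
(score, matches, aligned-columns) tuples, interval unions from a per-base
bitmap, and chain selection from a naive per-base re-implementation of the
documented greedy rule.
"""

from __future__ import annotations

import numpy as np

_NEG = (-(10**9), 0, 0)


def oracle_align_stats(a: str, b: str) -> tuple[float, int, int]:
    """(score, matching columns, aligned columns) of the global alignment
    that maximizes score, then matches, then aligned columns.

    Scoring: match +1, mismatch 0, gap open -1, gap extend -0.5, end gaps
    penalized. Scores are doubled internally to stay integral.
    """
    n, m = len(a), len(b)
    Mp = [_NEG] * (m + 1)
    Pp = [_NEG] * (m + 1)  # gap in b (consumes a)
    Qp = [_NEG] * (m + 1)  # gap in a (consumes b)
    Mp[0] = (0, 0, 0)
    for j in range(1, m + 1):
        Qp[j] = (-2 - (j - 1), 0, 0)
    for i in range(1, n + 1):
        Mc = [_NEG] * (m + 1)
        Pc = [_NEG] * (m + 1)
        Qc = [_NEG] * (m + 1)
        Pc[0] = (-2 - (i - 1), 0, 0)
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = max(Mp[j - 1], Pp[j - 1], Qp[j - 1])
            if ai == b[j - 1]:
                Mc[j] = (diag[0] + 2, diag[1] + 1, diag[2] + 1)
            else:
                Mc[j] = (diag[0], diag[1], diag[2] + 1)
            up = max(Mp[j], Pp[j], Qp[j])
            Pc[j] = max((up[0] - 2, up[1], up[2]), (Pp[j][0] - 1, Pp[j][1], Pp[j][2]))
            left = max(Mc[j - 1], Pc[j - 1], Qc[j - 1])
            Qc[j] = max(
                (left[0] - 2, left[1], left[2]), (Qc[j - 1][0] - 1, Qc[j - 1][1], Qc[j - 1][2])
            )
        Mp, Pp, Qp = Mc, Pc, Qc
    s2, matches, aligned = max(Mp[m], Pp[m], Qp[m])
    return s2 / 2.0, matches, aligned


def oracle_identity(a: str, b: str) -> float:
    """Matching columns over the shorter sequence length."""
    _, matches, _ = oracle_align_stats(a, b)
    return matches / min(len(a), len(b))


def brute_force_greedy_cluster(
    seqs: list[tuple[str, str]], c: float = 0.9, s: float = 0.9
) -> list[list[str]]:
    """The same greedy clustering definition computed with the DP oracle.

    ``seqs`` is a list of (id, sequence); returns clusters as id lists with
    the representative (longest, lexicographic tie-break) first.
    """
    ordered = sorted(seqs, key=lambda x: (-len(x[1]), x[1], x[0]))
    clusters: list[list[tuple[str, str]]] = []
    for sid, seq in ordered:
        placed = False
        for cl in clusters:
            rep = cl[0][1]
            if len(seq) / len(rep) < s:
                continue
            if oracle_identity(rep, seq) >= c:
                cl.append((sid, seq))
                placed = True
                break
        if not placed:
            clusters.append([(sid, seq)])
    return [[sid for sid, _ in cl] for cl in clusters]


def bitmap_union_length(intervals: list[tuple[int, int]], length: int) -> int:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def naive_best_chains(alignments, mask_level: float = 0.9) -> list[bool]:
    """Per-base bitmap re-implementation of the documented greedy chain rule.

    Returns accept flags aligned with the input order.
    """
    order = sorted(
        range(len(alignments)),
        key=lambda i: (
            -alignments[i].n_matches,
            alignments[i].query_name,
            alignments[i].query_start,
            alignments[i].target_name,
            alignments[i].target_start,
        ),
    )
    masks: dict[str, np.ndarray] = {}
    accepted_ivs: dict[str, list[tuple[int, int]]] = {}
    flags = [False] * len(alignments)
    for idx in order:
        a = alignments[idx]
        mask = masks.setdefault(a.query_name, np.zeros(a.query_len, dtype=bool))
        span = a.query_end - a.query_start
        covered = int(mask[a.query_start : a.query_end].sum())
        if covered > mask_level * span:
            continue
        bad = False
        for s, e in accepted_ivs.get(a.query_name, []):
            ov = min(e, a.query_end) - max(s, a.query_start)
            if ov > mask_level * min(span, e - s):
                bad = True
                break
        if bad:
            continue
        flags[idx] = True
        mask[a.query_start : a.query_end] = True
        accepted_ivs.setdefault(a.query_name, []).append((a.query_start, a.query_end))
    return flags
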