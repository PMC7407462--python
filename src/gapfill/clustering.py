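"""CD-HIT-style greedy clustering of per-assembly fills into a non-redundant
call set, polymorphic-gap calling and cross-assembly sharing.

CD-HIT is emulated, not invoked: fills per gap are few, so its word-filter
heuristics are replaced by exact global alignment. Semantics preserved:
longest-first greedy clustering, identity = matching columns over the shorter
sequence length (``-c``), length-difference cutoff = shorter/longer length
ratio (``-s``), first-fit assignment in cluster-creation order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gap_closure import GapClosingSequence, fill_id
from .sequtils import revcomp

__all__ = [
    "SequenceCluster",
    "PolymorphicCall",
    "pairwise_identity",
    "greedy_cluster",
    "cluster_all",
    "call_polymorphic",
    "cross_assembly_sharing",
    "write_clusters_tsv",
]

logger = logging.getLogger(__name__)


# Global affine-gap alignment, match +1, mismatch 0, gap open -1, gap
# extend -0.5 (end gaps penalized). Scores, matching columns and aligned
# columns are packed into one int64 per DP cell — score doubled to stay
# integral, then two 17-bit fields — so that maximizing the packed value is
# the lexicographic maximization (score, then matches, then aligned
# columns). That makes the reported identity canonical: among all
# optimal-score alignments, the one with the most matching columns.
_FIELD = 1 << 17  # > maximum sequence length handled here
_DELTA_EXT = -(_FIELD * _FIELD)  # -0.5 gap score, doubled
_DELTA_OPEN = 2 * _DELTA_EXT  # -1 gap score, doubled
_DELTA_MATCH = (2 * _FIELD * _FIELD) + _FIELD + 1
_DELTA_MISMATCH = 1
_NEG = -(1 << 60)


def _align_counts(a: str, b: str) -> tuple[int, int]:
    """(matching columns, aligned columns) of the best global alignment.

    Row-vectorized Gotoh recurrences; only the previous row is kept, and the
    horizontal-gap state is solved per row with a prefix-maximum scan.
    """
    n, m = len(a), len(b)
    if max(n, m) >= _FIELD:
        raise ValueError(f"sequences longer than {_FIELD - 1} bp are not supported")
    av = np.frombuffer(a.encode(), dtype="S1")
    bv = np.frombuffer(b.encode(), dtype="S1")
    js = np.arange(1, m + 1, dtype=np.int64)
    M_prev = np.full(m + 1, _NEG, dtype=np.int64)
    P_prev = np.full(m + 1, _NEG, dtype=np.int64)
    Q_prev = np.full(m + 1, _NEG, dtype=np.int64)
    M_prev[0] = 0
    if m:
        Q_prev[1:] = _DELTA_OPEN + _DELTA_EXT * (js - 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M_prev, P_prev), Q_prev)
        delta = np.where(av[i - 1] == bv, _DELTA_MATCH, _DELTA_MISMATCH)
        M_cur = np.empty(m + 1, dtype=np.int64)
        M_cur[0] = _NEG
        M_cur[1:] = best_prev[:-1] + delta
        P_cur = np.maximum(best_prev + _DELTA_OPEN, P_prev + _DELTA_EXT)
        P_cur[0] = _DELTA_OPEN + _DELTA_EXT * (i - 1)
        Q_cur = np.empty(m + 1, dtype=np.int64)
        Q_cur[0] = _NEG
        if m:
            mpb = np.maximum(M_cur[:-1], P_cur[:-1])
            scan = np.maximum.accumulate(mpb + _DELTA_OPEN - _DELTA_EXT * js)
            Q_cur[1:] = scan + _DELTA_EXT * js
        M_prev, P_prev, Q_prev = M_cur, P_cur, Q_cur
    final = int(max(M_prev[m], P_prev[m], Q_prev[m]))
    aligned = final % _FIELD
    matches = ((final - aligned) // _FIELD) % _FIELD
    return matches, aligned


def pairwise_identity(a: str, b: str, *, try_revcomp: bool = False) -> float:
    """Global-alignment identity: matching columns / length of the shorter.

    Scoring: match +1, mismatch 0, affine gaps (open −1, extend −0.5).
    With ``try_revcomp`` the reverse complement of ``b`` is also tried and
    the better orientation used (safety net; fills are reference-oriented).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    ident, _ = _align_counts(a, b)
    best = ident / min(len(a), len(b))
    if try_revcomp:
        ident_rc, _ = _align_counts(a, revcomp(b))
        rc = ident_rc / min(len(a), len(b))
        if rc > best:
            logger.info("reverse-complement orientation scored higher (%.3f > %.3f)", rc, best)
            best = rc
    return min(best, 1.0)


@dataclass
class SequenceCluster:
    """A non-redundant representative (the longest member) and its members."""

    gap_id: str
    representative: GapClosingSequence
    members: list[GapClosingSequence] = field(default_factory=list)

    @property
    def n_supporting_assemblies(self) -> int:
        return len({m.assembly_id for m in self.members})


@dataclass(frozen=True)
class PolymorphicCall:
    gap_id: str
    n_alleles: int

    @property
    def is_polymorphic(self) -> bool:
        return self.n_alleles > 1


def greedy_cluster(
    fills: Sequence[GapClosingSequence],
    c: float = 0.9,
    s: float = 0.9,
    *,
    try_revcomp: bool = False,
) -> list[SequenceCluster]:
    """Cluster the fills of one gap, CD-HIT style.

    Fills are sorted by length descending (ties by sequence lexicographic);
    each joins the first cluster (creation order) whose representative
    satisfies identity >= ``c`` and shorter/longer length ratio >= ``s``,
    else founds a new cluster. Deterministic and order-insensitive.
    """
    gap_ids = {f.gap_id for f in fills}
    if len(gap_ids) > 1:
        raise ValueError(f"greedy_cluster expects fills of one gap, got {sorted(gap_ids)}")
    ordered = sorted(fills, key=lambda f: (-f.length, f.sequence, f.assembly_id))
    clusters: list[SequenceCluster] = []
    for f in ordered:
        placed = False
        for cl in clusters:
            rep = cl.representative
            if f.length / rep.length < s:
                continue
            if pairwise_identity(rep.sequence, f.sequence, try_revcomp=try_revcomp) >= c:
                cl.members.append(f)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(f.gap_id, representative=f, members=[f]))
    return clusters


def cluster_all(
    fills: Sequence[GapClosingSequence], c: float = 0.9, s: float = 0.9
) -> dict[str, list[SequenceCluster]]:
    """Cluster all fills grouped by gap; returns gap_id -> clusters."""
    by_gap: dict[str, list[GapClosingSequence]] = {}
    for f in fills:
        if f.length > 0:
            by_gap.setdefault(f.gap_id, []).append(f)
    return {g: greedy_cluster(fs, c, s) for g, fs in sorted(by_gap.items())}


def call_polymorphic(
    clusters_by_gap: Mapping[str, Sequence[SequenceCluster]],
) -> list[PolymorphicCall]:
    """One call per gap: polymorphic iff it carries more than one cluster."""
    return [
        PolymorphicCall(gap_id=g, n_alleles=len(cls))
        for g, cls in sorted(clusters_by_gap.items())
    ]


def polymorphic_fraction(calls: Sequence[PolymorphicCall]) -> float:
    if not calls:
        return 0.0
    return sum(c.is_polymorphic for c in calls) / len(calls)


def _match_stats(a: str, b: str) -> tuple[float, float]:
    """(identity over aligned columns, coverage of the shorter sequence)."""
    ident, aligned = _align_counts(a.upper(), b.upper())
    shorter = min(len(a), len(b))
    coverage = aligned / shorter if shorter else 0.0
    identity = ident / aligned if aligned else 0.0
    return identity, min(coverage, 1.0)


def cross_assembly_sharing(
    fills: Sequence[GapClosingSequence],
    identity: float = 0.9,
    coverage: float = 0.9,
    *,
    try_revcomp: bool = False,
) -> dict[str, bool]:
    """Label each fill shared/specific across assemblies.

    A fill is *shared* iff some fill at the same gap from a different
    assembly matches it at >= ``identity`` over >= ``coverage`` of the
    shorter sequence. Returns ``{fill_id: shared}``.
    """
    assemblies = {f.assembly_id for f in fills}
    if len(assemblies) < 2:
        warnings.warn("single assembly: all fills labeled specific")
        return {fill_id(f): False for f in fills}
    by_gap: dict[str, list[GapClosingSequence]] = {}
    for f in fills:
        by_gap.setdefault(f.gap_id, []).append(f)
    labels: dict[str, bool] = {}
    for gap_fills in by_gap.values():
        for i, f in enumerate(gap_fills):
            shared = False
            if f.length:
                for j, g in enumerate(gap_fills):
                    if i == j or g.assembly_id == f.assembly_id or not g.length:
                        continue
                    ident, cov = _match_stats(f.sequence, g.sequence)
                    if try_revcomp and not (ident >= identity and cov >= coverage):
                        ident_rc, cov_rc = _match_stats(f.sequence, revcomp(g.sequence))
                        if ident_rc >= identity and cov_rc >= coverage:
                            ident, cov = ident_rc, cov_rc
                    if ident >= identity and cov >= coverage:
                        shared = True
                        break
            labels[fill_id(f)] = shared
    return labels


def sharing_counts(
    fills: Sequence[GapClosingSequence], labels: Mapping[str, bool]
) -> dict[str, dict[str, int]]:
    """Per-assembly shared/specific counts (bar-chart input)."""
    out: dict[str, dict[str, int]] = {}
    for f in fills:
        d = out.setdefault(f.assembly_id, {"shared": 0, "specific": 0})
        d["shared" if labels[fill_id(f)] else "specific"] += 1
    return out


def write_clusters_tsv(clusters_by_gap: Mapping[str, Sequence[SequenceCluster]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gap_id\tcluster_idx\trepresentative\tmembers\tn_assemblies\n")
        for gap_id, clusters in sorted(clusters_by_gap.items()):
            for i, cl in enumerate(clusters):
                members = ",".join(fill_id(m) for m in cl.members)
                fh.write(
                    f"{gap_id}\t{i}\t{fill_id(cl.representative)}\t{members}\t"
                    f"{cl.n_supporting_assemblies}\n"
                )
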