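"""PAF alignment I/O, best-chain selection, and a toy anchor-based aligner.

The pipeline never shells out to minimap2/MUMmer/QUAST: production users supply
PAF (minimap2's native format, 12 mandatory columns) or MUMmer ``show-coords -T``
output via :func:`read_coords`; tests and the synthetic study use
:func:`anchor_align`, a deterministic unique-k-mer anchor aligner that emits
gapless-block alignments in the same PAF coordinate conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequtils import open_text, revcomp

__all__ = [
    "AlignmentRecord",
    "read_paf",
    "write_paf",
    "read_coords",
    "select_best_chains",
    "anchor_align",
    "align_fasta",
]

PAF_FIELDS = 12


@dataclass
class AlignmentRecord:
    """One PAF row. All coordinates 0-based half-open on the forward strand
    of the respective sequence; ``strand`` gives the relative orientation."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    mapq: int = 60
    tags: tuple[str, ...] = ()
    is_best_chain: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"invalid query interval {self.query_name}:"
                f"{self.query_start}-{self.query_end} (len {self.query_len})"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"invalid target interval {self.target_name}:"
                f"{self.target_start}-{self.target_end} (len {self.target_len})"
            )
        if not (0 <= self.n_matches <= self.block_len):
            raise ValueError(
                f"n_matches {self.n_matches} outside [0, block_len={self.block_len}]"
            )

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def read_paf(path) -> list[AlignmentRecord]:
    """Read PAF; returns records in file order with ``is_best_chain`` False.

    Optional tag columns (cg/cs/...) are preserved as opaque strings.
    """
    records: list[AlignmentRecord] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) < PAF_FIELDS:
                raise ValueError(
                    f"line {lineno}: PAF row has {len(f)} fields, expected >= {PAF_FIELDS}"
                )
            try:
                rec = AlignmentRecord(
                    query_name=f[0],
                    query_len=int(f[1]),
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    strand=f[4],
                    target_name=f[5],
                    target_len=int(f[6]),
                    target_start=int(f[7]),
                    target_end=int(f[8]),
                    n_matches=int(f[9]),
                    block_len=int(f[10]),
                    mapq=int(f[11]),
                    tags=tuple(f[PAF_FIELDS:]),
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            records.append(rec)
    return records


def write_paf(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.query_name,
                str(r.query_len),
                str(r.query_start),
                str(r.query_end),
                r.strand,
                r.target_name,
                str(r.target_len),
                str(r.target_start),
                str(r.target_end),
                str(r.n_matches),
                str(r.block_len),
                str(r.mapq),
                *r.tags,
            ]
            fh.write("\t".join(cols) + "\n")


def read_coords(path) -> list[AlignmentRecord]:
    """Convert MUMmer ``show-coords -T -r -c -l`` 13-column output to records.

    Columns: S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ COVR COVQ REF QRY, reference
    coordinates 1-based inclusive, query S2 > E2 on the minus strand. Per-base
    identity maps to ``n_matches = round(%IDY/100 * block_len)``.
    """
    records: list[AlignmentRecord] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 13:
                continue  # headers and separator lines of show-coords
            try:
                s1, e1, s2, e2 = (int(x) for x in f[:4])
                len1, len2 = int(f[4]), int(f[5])
                idy = float(f[6])
                lenr, lenq = int(f[7]), int(f[8])
                ref_name, qry_name = f[11], f[12]
            except ValueError:
                continue
            strand = "+" if s2 <= e2 else "-"
            qs, qe = (s2 - 1, e2) if strand == "+" else (e2 - 1, s2)
            block_len = max(len1, len2)
            records.append(
                AlignmentRecord(
                    query_name=qry_name,
                    query_len=lenq,
                    query_start=qs,
                    query_end=qe,
                    strand=strand,
                    target_name=ref_name,
                    target_len=lenr,
                    target_start=s1 - 1,
                    target_end=e1,
                    n_matches=round(idy / 100.0 * block_len),
                    block_len=block_len,
                    mapq=255,
                )
            )
    return records


def _overlap(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2))


def select_best_chains(
    alignments: Sequence[AlignmentRecord], mask_level: float = 0.9
) -> list[AlignmentRecord]:
    """Greedy non-overlapping best-chain selection, minimap2 mask-level style.

    Candidates are visited by descending ``n_matches`` (ties broken by
    (query_name, query_start) for determinism). A candidate is rejected when
    alignments of the same query already accepted cover more than
    ``mask_level`` of its query interval (union rule), or when any single
    accepted alignment of the same query overlaps it by more than
    ``mask_level`` of the smaller of the two query intervals. Accepted records
    get ``is_best_chain=True``; the input list is returned with flags set.
    """
    if not (0 < mask_level <= 1):
        raise ValueError(f"mask_level must be in (0, 1], got {mask_level}")
    order = sorted(
        alignments,
        key=lambda a: (-a.n_matches, a.query_name, a.query_start, a.target_name, a.target_start),
    )
    accepted: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        a.is_best_chain = False
    for cand in order:
        prior = accepted.get(cand.query_name, [])
        span = cand.query_span
        # union coverage of the candidate's query interval
        ivs = sorted(
            (max(cand.query_start, p.query_start), min(cand.query_end, p.query_end))
            for p in prior
            if _overlap(cand.query_start, cand.query_end, p.query_start, p.query_end) > 0
        )
        covered = 0
        cur_s = cur_e = None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        if covered > mask_level * span:
            continue
        pairwise_bad = any(
            _overlap(cand.query_start, cand.query_end, p.query_start, p.query_end)
            > mask_level * min(span, p.query_span)
            for p in prior
        )
        if pairwise_bad:
            continue
        cand.is_best_chain = True
        accepted.setdefault(cand.query_name, []).append(cand)
    return list(alignments)


# ---------------------------------------------------------------------------
# toy anchor aligner
# ---------------------------------------------------------------------------

_VALID = frozenset("ACGT")


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    """Positions of k-mers occurring exactly once (k-mers with non-ACGT skipped)."""
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        elif _VALID.issuperset(kmer):
            seen[kmer] = i
    return seen


def _blocks_one_strand(
    query: str,
    target: str,
    target_index: dict[str, int],
    k: int,
    max_anchor_gap: int,
) -> list[tuple[int, int, int, int, int]]:
    """Maximal same-diagonal anchor chains as (qs, qe, ts, te, n_matches)."""
    q_index = _unique_kmers(query, k)
    anchors: dict[int, list[int]] = {}
    for kmer, q in q_index.items():
        t = target_index.get(kmer)
        if t is not None:
            anchors.setdefault(t - q, []).append(q)
    blocks = []
    for diag, qs_list in anchors.items():
        qs_list.sort()
        run_start = qs_list[0]
        prev = qs_list[0]
        runs = []
        for q in qs_list[1:]:
            if q - (prev + k) > max_anchor_gap:
                runs.append((run_start, prev + k))
                run_start = q
            prev = q
        runs.append((run_start, prev + k))
        for qs, qe in runs:
            ts, te = qs + diag, qe + diag
            # exact extension outwards
            while qs > 0 and ts > 0 and query[qs - 1] == target[ts - 1] and query[qs - 1] in _VALID:
                qs -= 1
                ts -= 1
            while (
                qe < len(query)
                and te < len(target)
                and query[qe] == target[te]
                and query[qe] in _VALID
            ):
                qe += 1
                te += 1
            n_match = sum(
                1
                for a, b in zip(query[qs:qe], target[ts:te])
                if a == b and a in _VALID
            )
            blocks.append((qs, qe, ts, te, n_match))
    return blocks


def anchor_align(
    query: str,
    target: str,
    k: int = 31,
    *,
    query_name: str = "query",
    target_name: str = "target",
    max_anchor_gap: int = 100,
    min_block: int | None = None,
) -> list[AlignmentRecord]:
    """Align ``query`` to ``target`` by chaining unique exact k-mer anchors.

    Anchors are k-mers unique in both sequences; collinear anchors on one
    diagonal (separated by at most ``max_anchor_gap`` anchor-free bases) are
    merged and extended outwards by exact matching into a single gapless
    block, emitted as one :class:`AlignmentRecord`. Both orientations are
    searched; deterministic for fixed inputs. ``k`` larger than either
    sequence yields an empty list.
    """
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    query = query.upper()
    target = target.upper()
    if k > len(query) or k > len(target):
        return []
    if min_block is None:
        min_block = k
    t_index = _unique_kmers(target, k)
    records: list[AlignmentRecord] = []
    fwd = _blocks_one_strand(query, target, t_index, k, max_anchor_gap)
    for qs, qe, ts, te, nm in fwd:
        if qe - qs < min_block:
            continue
        records.append(
            AlignmentRecord(
                query_name=query_name,
                query_len=len(query),
                query_start=qs,
                query_end=qe,
                strand="+",
                target_name=target_name,
                target_len=len(target),
                target_start=ts,
                target_end=te,
                n_matches=nm,
                block_len=qe - qs,
            )
        )
    qrc = revcomp(query)
    rev = _blocks_one_strand(qrc, target, t_index, k, max_anchor_gap)
    for qs, qe, ts, te, nm in rev:
        if qe - qs < min_block:
            continue
        records.append(
            AlignmentRecord(
                query_name=query_name,
                query_len=len(query),
                query_start=len(query) - qe,
                query_end=len(query) - qs,
                strand="-",
                target_name=target_name,
                target_len=len(target),
                target_start=ts,
                target_end=te,
                n_matches=nm,
                block_len=qe - qs,
            )
        )
    records.sort(key=lambda r: (r.target_name, r.target_start, r.query_start, r.strand))
    return records


def align_fasta(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    k: int = 31,
    **kwargs,
) -> list[AlignmentRecord]:
    """:func:`anchor_align` every query against every target sequence.

    Target k-mer indexes are built once per target and reused across queries.
    """
    records: list[AlignmentRecord] = []
    for t_name, t_seq in targets.items():
        t_seq_u = t_seq.upper()
        if k > len(t_seq_u):
            continue
        t_index = _unique_kmers(t_seq_u, k)
        for q_name, q_seq in queries.items():
            q_seq_u = q_seq.upper()
            if k > len(q_seq_u):
                continue
            min_block = kwargs.get("min_block", k)
            max_gap = kwargs.get("max_anchor_gap", 100)
            for qs, qe, ts, te, nm in _blocks_one_strand(
                q_seq_u, t_seq_u, t_index, k, max_gap
            ):
                if qe - qs < min_block:
                    continue
                records.append(
                    AlignmentRecord(
                        query_name=q_name,
                        query_len=len(q_seq_u),
                        query_start=qs,
                        query_end=qe,
                        strand="+",
                        target_name=t_name,
                        target_len=len(t_seq_u),
                        target_start=ts,
                        target_end=te,
                        n_matches=nm,
                        block_len=qe - qs,
                    )
                )
            qrc = revcomp(q_seq_u)
            for qs, qe, ts, te, nm in _blocks_one_strand(
                qrc, t_seq_u, t_index, k, max_gap
            ):
                if qe - qs < min_block:
                    continue
                records.append(
                    AlignmentRecord(
                        query_name=q_name,
                        query_len=len(q_seq_u),
                        query_start=len(q_seq_u) - qe,
                        query_end=len(q_seq_u) - qs,
                        strand="-",
                        target_name=t_name,
                        target_len=len(t_seq_u),
                        target_start=ts,
                        target_end=te,
                        n_matches=nm,
                        block_len=qe - qs,
                    )
                )
    records.sort(
        key=lambda r: (r.query_name, r.target_name, r.target_start, r.query_start, r.strand)
    )
    return records
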