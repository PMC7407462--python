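"""Gap-closing sequence extraction from best-chain alignments.

Two evidence rules, tried in order per gap:

* **flank_pair** — two same-contig, same-strand best-chain alignments sit on
  either side of the gap, each ending within 100 bp of a gap edge; the contig
  sequence between the two alignments is the fill.
* **spanning** — a single best-chain alignment spans the whole gap; the
  reference flanks of the gap are re-anchored onto the contig and the contig
  interval strictly between the two flank anchors is the fill.

A zero-length fill (or overlapping flank alignments) is evidence that the
reference gap annotation is wrong and the gap is flagged *discrepant*.
Fills are always reported in reference orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alignment_io import AlignmentRecord, anchor_align
from .gap_catalog import GapRecord
from .sequtils import open_text, revcomp

__all__ = [
    "GapClosingSequence",
    "GapClosureReport",
    "FlankPair",
    "find_flank_pair",
    "extract_between",
    "resolve_spanning",
    "close_gaps",
    "closure_summary",
    "fill_id",
    "write_fills_fasta",
    "read_fills_fasta",
    "write_report_tsv",
]


@dataclass
class GapClosingSequence:
    """One extracted fill for a (gap, assembly) pair.

    ``contig_start``/``contig_end`` are 0-based half-open on the contig's
    forward strand; ``sequence`` is already in reference orientation.
    A zero-length sequence records discrepant evidence; ``overlap_bp`` then
    holds the magnitude of the flank overlap (0 for an exact butt joint).
    """

    gap_id: str
    assembly_id: str
    contig_name: str = ""
    contig_start: int = 0
    contig_end: int = 0
    sequence: str = ""
    rule: str = "flank_pair"
    strand_relative_to_ref: str = "+"
    left_edge_distance: int = 0
    right_edge_distance: int = 0
    overlap_bp: int = 0
    has_n: bool = False

    def __post_init__(self) -> None:
        if self.contig_end < self.contig_start:
            raise ValueError("contig_end < contig_start")
        if len(self.sequence) != self.contig_end - self.contig_start:
            raise ValueError("sequence length must equal the contig interval length")
        if self.rule == "flank_pair" and not (
            self.left_edge_distance < 100 and self.right_edge_distance < 100
        ):
            raise ValueError("flank_pair fills must record edge distances < 100 bp")
        self.has_n = "N" in self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GapClosureReport:
    gap_id: str
    status: str  # closed | discrepant | open
    sequences: list[GapClosingSequence] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.status == "closed" and not any(s.length > 0 for s in self.sequences):
            raise ValueError("closed status requires a sequence of length > 0")


@dataclass
class FlankPair:
    """A validated left/right flank alignment pair for one gap."""

    gap: GapRecord
    left: AlignmentRecord
    right: AlignmentRecord
    left_edge_distance: int
    right_edge_distance: int

    @property
    def strand(self) -> str:
        return self.left.strand

    @property
    def contig(self) -> str:
        return self.left.query_name

    @property
    def combined_block_len(self) -> int:
        return self.left.block_len + self.right.block_len


def _candidate_pairs(
    gap: GapRecord,
    alignments: Sequence[AlignmentRecord],
    max_edge_dist: int = 100,
    slack: int = 10,
    inclusive: bool = False,
) -> tuple[list[FlankPair], bool]:
    """All orientation-consistent flank pairs, best-per-contig, sorted by
    combined flank alignment length (descending). Second return value flags
    whether inverted-orientation (mixed-strand) candidates were seen."""

    def edge_ok(d: int) -> bool:
        return d <= max_edge_dist if inclusive else d < max_edge_dist

    lefts = [
        a
        for a in alignments
        if a.is_best_chain
        and a.target_name == gap.chrom
        and a.target_end <= gap.start + slack
        and a.target_start < gap.start
        and edge_ok(max(0, gap.start - a.target_end))
    ]
    rights = [
        a
        for a in alignments
        if a.is_best_chain
        and a.target_name == gap.chrom
        and a.target_start >= gap.end - slack
        and a.target_end > gap.end
        and edge_ok(max(0, a.target_start - gap.end))
    ]
    per_contig: dict[str, FlankPair] = {}
    inverted_seen = False
    for L in lefts:
        for R in rights:
            if L.query_name != R.query_name:
                continue
            if L.strand != R.strand:
                inverted_seen = True
                continue
            if L.strand == "+" and not L.query_start < R.query_start:
                continue
            if L.strand == "-" and not R.query_start < L.query_start:
                continue
            pair = FlankPair(
                gap=gap,
                left=L,
                right=R,
                left_edge_distance=max(0, gap.start - L.target_end),
                right_edge_distance=max(0, R.target_start - gap.end),
            )
            cur = per_contig.get(pair.contig)
            if cur is None or _pair_rank(pair) < _pair_rank(cur):
                per_contig[pair.contig] = pair
    pairs = sorted(
        per_contig.values(),
        key=lambda p: (-p.combined_block_len, p.contig, p.left.query_start),
    )
    return pairs, inverted_seen


def _pair_rank(p: FlankPair) -> tuple:
    # minimal total edge distance wins within a contig; ties broken by
    # larger combined alignment, then by contig coordinate for determinism
    return (
        p.left_edge_distance + p.right_edge_distance,
        -p.combined_block_len,
        p.left.query_start,
    )


def find_flank_pair(
    gap: GapRecord,
    alignments: Sequence[AlignmentRecord],
    max_edge_dist: int = 100,
    *,
    slack: int = 10,
    inclusive: bool = False,
) -> FlankPair | None:
    """Best flank-alignment pair for ``gap`` among best-chain alignments.

    Requires same contig, consistent orientation, both alignment edges within
    ``max_edge_dist`` of the gap edges (strict ``<`` by default). Among valid
    pairs the pair minimizing total edge distance wins within each contig;
    across contigs the pair with the largest combined flank alignment length
    wins. Returns None when no valid pair exists.
    """
    pairs, _ = _candidate_pairs(gap, alignments, max_edge_dist, slack, inclusive)
    return pairs[0] if pairs else None


def extract_between(
    pair: FlankPair, contig_sequence: str, assembly_id: str = ""
) -> GapClosingSequence:
    """Extract the fill between the two flank alignments of ``pair``.

    For strand '+' the fill is ``contig[L.query_end : R.query_start]``; for
    strand '-' it is the reverse complement of
    ``contig[R.query_end : L.query_start]``. Alignments overhanging up to
    ``slack`` bases into the gap (sloppy clipping at N boundaries) are trimmed
    back to the gap edge. Overlapping flank alignments yield a zero-length
    fill with the overlap magnitude recorded.
    """
    gap = pair.gap
    L, R = pair.left, pair.right
    d_left = max(0, L.target_end - gap.start)  # overhang into the gap
    d_right = max(0, gap.end - R.target_start)
    contig_sequence = contig_sequence.upper()
    if pair.strand == "+":
        fs = L.query_end - d_left
        fe = R.query_start + d_right
    else:
        fs = R.query_end - d_right
        fe = L.query_start + d_left
    fs = max(0, min(fs, len(contig_sequence)))
    fe = max(0, min(fe, len(contig_sequence)))
    if fs > fe:
        overlap = fs - fe
        fs = fe
    else:
        overlap = 0
    raw = contig_sequence[fs:fe]
    seq = raw if pair.strand == "+" else revcomp(raw)
    return GapClosingSequence(
        gap_id=gap.gap_id,
        assembly_id=assembly_id,
        contig_name=pair.contig,
        contig_start=fs,
        contig_end=fe,
        sequence=seq,
        rule="flank_pair",
        strand_relative_to_ref=pair.strand,
        left_edge_distance=pair.left_edge_distance,
        right_edge_distance=pair.right_edge_distance,
        overlap_bp=overlap,
    )


def _n_free_flank(ref_seq: str, gap: GapRecord, flank_bp: int, side: str) -> str:
    if side == "left":
        s = max(0, gap.start - flank_bp)
        if s == 0 and gap.start < flank_bp:
            warnings.warn(f"{gap.gap_id}: left flank truncated at chromosome start")
        flank = ref_seq[s : gap.start]
        n_pos = flank.rfind("N")
        return flank[n_pos + 1 :] if n_pos >= 0 else flank
    e = min(len(ref_seq), gap.end + flank_bp)
    if e == len(ref_seq) and len(ref_seq) - gap.end < flank_bp:
        warnings.warn(f"{gap.gap_id}: right flank truncated at chromosome end")
    flank = ref_seq[gap.end : e]
    n_pos = flank.find("N")
    return flank[:n_pos] if n_pos >= 0 else flank


def _unique_anchor(
    flank: str, contig: str, k: int, min_cov: float = 0.9
) -> AlignmentRecord | None:
    """Single unambiguous alignment of a reference flank onto the contig."""
    if len(flank) < k:
        return None
    hits = [
        a
        for a in anchor_align(flank, contig, k=k)
        if a.query_span >= min_cov * len(flank)
    ]
    return hits[0] if len(hits) == 1 else None


def resolve_spanning(
    gap: GapRecord,
    spanning_alignment: AlignmentRecord,
    ref_sequence: str,
    contig_sequence: str,
    flank_bp: int = 5000,
    *,
    k: int = 31,
    assembly_id: str = "",
) -> GapClosingSequence | None:
    """Resolve a gap inside a single spanning alignment.

    The N-free reference flanks of the gap are anchored onto the contig with
    the toy aligner; the contig interval strictly between the two anchors is
    the fill. Requires each flank to anchor uniquely with its gap-adjacent
    edge fully aligned; returns None otherwise.
    """
    if not (
        spanning_alignment.target_start < gap.start
        and spanning_alignment.target_end > gap.end
    ):
        raise ValueError("alignment does not span the gap")
    contig_sequence = contig_sequence.upper()
    left = _n_free_flank(ref_sequence.upper(), gap, flank_bp, "left")
    right = _n_free_flank(ref_sequence.upper(), gap, flank_bp, "right")
    la = _unique_anchor(left, contig_sequence, k)
    ra = _unique_anchor(right, contig_sequence, k)
    if la is None or ra is None or la.strand != ra.strand:
        return None
    # the gap-adjacent flank edge must be part of the anchor, else the
    # contig boundary of the fill is unknown
    if la.query_end != len(left) or ra.query_start != 0:
        return None
    if la.strand == "+":
        fs, fe = la.target_end, ra.target_start
    else:
        fs, fe = ra.target_end, la.target_start
    if fs > fe:
        overlap = fs - fe
        fs = fe
    else:
        overlap = 0
    raw = contig_sequence[fs:fe]
    seq = raw if la.strand == "+" else revcomp(raw)
    return GapClosingSequence(
        gap_id=gap.gap_id,
        assembly_id=assembly_id,
        contig_name=spanning_alignment.query_name,
        contig_start=fs,
        contig_end=fe,
        sequence=seq,
        rule="spanning",
        strand_relative_to_ref=la.strand,
        overlap_bp=overlap,
    )


def close_gaps(
    assembly_id: str,
    gaps: Sequence[GapRecord],
    alignments: Sequence[AlignmentRecord],
    assembly_fasta: Mapping[str, str],
    ref_fasta: Mapping[str, str],
    *,
    max_edge_dist: int = 100,
    slack: int = 10,
    spanning_flank_bp: int = 5000,
    k: int = 31,
) -> list[GapClosureReport]:
    """Attempt to close every gap with one assembly's best-chain alignments.

    Per gap the flank_pair rule is tried first, then the spanning rule; at
    most one :class:`GapClosingSequence` is emitted per (gap, assembly).
    Zero-length fills / overlapping flanks report status ``discrepant``; a
    fill consisting entirely of N (the assembly still carries the gap)
    reports ``open``; no usable evidence reports ``open``.
    """
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        if a.is_best_chain:
            by_chrom.setdefault(a.target_name, []).append(a)
    reports: list[GapClosureReport] = []
    for gap in gaps:
        chrom_alns = by_chrom.get(gap.chrom, [])
        pairs, inverted = _candidate_pairs(gap, chrom_alns, max_edge_dist, slack)
        notes: list[str] = []
        if inverted:
            notes.append("inverted-orientation flank candidates present")
        seq: GapClosingSequence | None = None
        if pairs:
            best = pairs[0]
            if len(pairs) > 1:
                others = ",".join(p.contig for p in pairs[1:])
                notes.append(f"alternative closing contigs: {others}")
            contig_seq = assembly_fasta.get(best.contig)
            if contig_seq is None:
                raise KeyError(
                    f"contig {best.contig!r} absent from assembly {assembly_id}"
                )
            seq = extract_between(best, contig_seq, assembly_id=assembly_id)
        else:
            spanning = [
                a
                for a in chrom_alns
                if a.target_start < gap.start and a.target_end > gap.end
            ]
            if spanning:
                span = max(spanning, key=lambda a: (a.n_matches, a.query_name))
                contig_seq = assembly_fasta.get(span.query_name)
                if contig_seq is None:
                    raise KeyError(
                        f"contig {span.query_name!r} absent from assembly {assembly_id}"
                    )
                seq = resolve_spanning(
                    gap,
                    span,
                    ref_fasta[gap.chrom],
                    contig_seq,
                    spanning_flank_bp,
                    k=k,
                    assembly_id=assembly_id,
                )
                if seq is None:
                    notes.append("spanning alignment present but flanks failed to anchor")
        if seq is None:
            reports.append(
                GapClosureReport(gap.gap_id, "open", [], note="; ".join(notes))
            )
        elif seq.length == 0:
            notes.append(f"flank overlap {seq.overlap_bp} bp" if seq.overlap_bp else "zero-length fill")
            reports.append(
                GapClosureReport(gap.gap_id, "discrepant", [seq], note="; ".join(notes))
            )
        elif set(seq.sequence) <= {"N"}:
            notes.append("fill is entirely N: assembly does not resolve the gap")
            reports.append(
                GapClosureReport(gap.gap_id, "open", [], note="; ".join(notes))
            )
        else:
            if seq.has_n:
                notes.append("fill contains N bases")
            reports.append(
                GapClosureReport(gap.gap_id, "closed", [seq], note="; ".join(notes))
            )
    return reports


def closure_summary(reports: Sequence[GapClosureReport]) -> dict[str, int]:
    out = {"closed": 0, "discrepant": 0, "open": 0}
    for r in reports:
        out[r.status] += 1
    return out


def fill_id(fill: GapClosingSequence) -> str:
    return f"{fill.gap_id}|{fill.assembly_id}"


def write_fills_fasta(fills: Sequence[GapClosingSequence], path) -> None:
    """Write fills with structured headers
    ``>gap_id|assembly_id|contig:start-end|rule|strand``."""
    with open(path, "w") as fh:
        for f in fills:
            header = (
                f"{f.gap_id}|{f.assembly_id}|{f.contig_name}:"
                f"{f.contig_start}-{f.contig_end}|{f.rule}|{f.strand_relative_to_ref}"
            )
            fh.write(f">{header}\n")
            for i in range(0, len(f.sequence), 80):
                fh.write(f.sequence[i : i + 80] + "\n")


def read_fills_fasta(path) -> list[GapClosingSequence]:
    fills: list[GapClosingSequence] = []
    header = None
    chunks: list[str] = []

    def emit() -> None:
        if header is None:
            return
        parts = header.split("|")
        if len(parts) != 5:
            raise ValueError(f"malformed fill header: {header!r}")
        contig, interval = parts[2].rsplit(":", 1)
        cs, ce = (int(x) for x in interval.split("-"))
        fills.append(
            GapClosingSequence(
                gap_id=parts[0],
                assembly_id=parts[1],
                contig_name=contig,
                contig_start=cs,
                contig_end=ce,
                sequence="".join(chunks),
                rule=parts[3],
                strand_relative_to_ref=parts[4],
            )
        )

    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                emit()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line.upper())
        emit()
    return fills


def write_report_tsv(reports: Sequence[GapClosureReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("gap_id\tstatus\tlength\trule\tleft_edge_dist\tright_edge_dist\tnote\n")
        for r in reports:
            if r.sequences:
                s = r.sequences[0]
                fh.write(
                    f"{r.gap_id}\t{r.status}\t{s.length}\t{s.rule}\t"
                    f"{s.left_edge_distance}\t{s.right_edge_distance}\t{r.note}\n"
                )
            else:
                fh.write(f"{r.gap_id}\t{r.status}\t\t\t\t\t{r.note}\n")
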