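"""Flank-pair and spanning extraction rules, and whole-assembly closure."""

import numpy as np
import pytest

from gapfill.alignment_io import AlignmentRecord, align_fasta, anchor_align, select_best_chains
from gapfill.gap_catalog import GapRecord, GapType
from gapfill.gap_closure import (
    close_gaps,
    extract_between,
    find_flank_pair,
    read_fills_fasta,
    resolve_spanning,
    write_fills_fasta,
)
from gapfill.sequtils import revcomp

from conftest import rand_seq

TLEN = 100_000


def _gap(start=1000, end=1100, gap_id="gap_x"):
    return GapRecord(chrom="chrT", start=start, end=end,
                     gap_type=GapType.WITHIN_SCAFFOLD, gap_id=gap_id)


def _aln(qs, qe, ts, te, *, qname="ctg1", qlen=2000, strand="+", nm=None):
    return AlignmentRecord(
        query_name=qname, query_len=qlen, query_start=qs, query_end=qe, strand=strand,
        target_name="chrT", target_len=TLEN, target_start=ts, target_end=te,
        n_matches=(te - ts) if nm is None else nm, block_len=te - ts,
        is_best_chain=True,
    )


class TestFindFlankPair:
    def test_pair_accepted_with_edge_distances(self):
        gap = _gap()
        left = _aln(0, 995, 0, 995)
        right = _aln(1290, 2000, 1102, 1812)
        pair = find_flank_pair(gap, [left, right])
        assert pair is not None
        assert (pair.left_edge_distance, pair.right_edge_distance) == (5, 2)
        assert pair.strand == "+"

    def test_inconsistent_orientation_rejected(self):
        gap = _gap()
        left = _aln(0, 995, 0, 995)
        right = _aln(1290, 2000, 1102, 1812, strand="-")
        assert find_flank_pair(gap, [left, right]) is None

    def test_edge_distance_over_100_rejected(self):
        gap = _gap()
        left = _aln(0, 850, 0, 850)  # 150 bp from the gap edge
        right = _aln(1290, 2000, 1102, 1812)
        assert find_flank_pair(gap, [left, right]) is None

    def test_minimal_edge_distance_pair_wins(self):
        gap = _gap()
        left_far = _aln(0, 950, 0, 950)
        left_near = _aln(0, 998, 2, 1000, qname="ctg2")
        right = _aln(1290, 2000, 1102, 1812)
        right2 = _aln(1290, 2000, 1102, 1812, qname="ctg2")
        pair = find_flank_pair(gap, [left_far, left_near, right, right2])
        assert pair.contig == "ctg2" and pair.left_edge_distance == 0

    def test_different_contigs_never_paired(self):
        gap = _gap()
        assert find_flank_pair(gap, [_aln(0, 995, 0, 995, qname="a"),
                                     _aln(1290, 2000, 1102, 1812, qname="b")]) is None


class TestExtractBetween:
    def test_plus_strand_fill(self):
        gap = _gap()
        contig = rand_seq(np.random.default_rng(0), 2000)
        pair = find_flank_pair(gap, [_aln(0, 500, 500, 1000), _aln(720, 2000, 1100, 2380)])
        fill = extract_between(pair, contig, assembly_id="asmX")
        assert fill.sequence == contig[500:720]
        assert fill.length == 220 and fill.strand_relative_to_ref == "+"

    def test_strand_symmetry_round_trip(self):
        # the same locus presented on the reverse-complemented contig must
        # yield the identical reference-oriented fill
        gap = _gap()
        rng = np.random.default_rng(1)
        contig = rand_seq(rng, 2000)
        pair_fwd = find_flank_pair(
            gap, [_aln(0, 500, 500, 1000), _aln(720, 2000, 1100, 2380)]
        )
        fill_fwd = extract_between(pair_fwd, contig)
        contig_rc = revcomp(contig)
        # on the rc contig, the left-of-gap alignment occupies the far end
        pair_rev = find_flank_pair(
            gap,
            [
                _aln(1500, 2000, 500, 1000, strand="-"),
                _aln(0, 1280, 1100, 2380, strand="-"),
            ],
        )
        fill_rev = extract_between(pair_rev, contig_rc)
        assert fill_rev.strand_relative_to_ref == "-"
        assert fill_rev.sequence == fill_fwd.sequence

    def test_overlapping_flanks_zero_length(self):
        gap = _gap()
        contig = "A" * 2000
        pair = find_flank_pair(gap, [_aln(0, 700, 300, 1000), _aln(650, 2000, 1100, 2450)])
        fill = extract_between(pair, contig)
        assert fill.length == 0 and fill.overlap_bp == 50

    def test_overhang_into_gap_is_trimmed(self):
        gap = _gap()
        rng = np.random.default_rng(2)
        contig = rand_seq(rng, 2000)
        # left alignment runs 8 bp past the gap start (sloppy N boundary)
        pair = find_flank_pair(gap, [_aln(0, 508, 500, 1008), _aln(720, 2000, 1100, 2380)])
        fill = extract_between(pair, contig)
        assert fill.sequence == contig[500:720]


def _spanning_locus(seed=3, fill_len=300, gap_len=300):
    rng = np.random.default_rng(seed)
    left_flank = rand_seq(rng, 6000)
    right_flank = rand_seq(rng, 6000)
    ref = left_flank + "N" * gap_len + right_flank
    fill = rand_seq(rng, fill_len)
    contig = left_flank + fill + right_flank
    gap = _gap(start=6000, end=6000 + gap_len)
    span = AlignmentRecord(
        query_name="ctg1", query_len=len(contig), query_start=0, query_end=len(contig),
        strand="+", target_name="chrT", target_len=len(ref), target_start=0,
        target_end=len(ref), n_matches=12_000, block_len=len(contig), is_best_chain=True,
    )
    return ref, contig, fill, gap, span


class TestResolveSpanning:
    def test_recovers_planted_fill_exactly(self):
        ref, contig, fill, gap, span = _spanning_locus()
        got = resolve_spanning(gap, span, ref, contig)
        assert got is not None and got.sequence == fill
        assert got.rule == "spanning"

    def test_adjacent_flanks_give_discrepant_evidence(self):
        ref, contig, fill, gap, span = _spanning_locus(fill_len=0)
        got = resolve_spanning(gap, span, ref, contig)
        assert got is not None and got.length == 0

    def test_reverse_complement_contig(self):
        ref, contig, fill, gap, span = _spanning_locus(seed=4)
        got = resolve_spanning(gap, span, ref, revcomp(contig))
        assert got is not None and got.sequence == fill
        assert got.strand_relative_to_ref == "-"

    def test_agrees_with_flank_pair_rule(self):
        # when the aligner splits the alignment at the gap, the flank_pair
        # route must recover the same fill as the spanning route
        ref, contig, fill, gap, span = _spanning_locus(seed=5)
        alns = anchor_align(contig, ref, query_name="ctg1", target_name="chrT")
        select_best_chains(alns)
        pair = find_flank_pair(gap, alns)
        assert pair is not None
        via_pair = extract_between(pair, contig)
        via_span = resolve_spanning(gap, span, ref, contig)
        assert via_pair.sequence == via_span.sequence == fill

    def test_requires_true_spanning(self):
        ref, contig, fill, gap, span = _spanning_locus()
        short = AlignmentRecord(
            query_name="ctg1", query_len=len(contig), query_start=0, query_end=5000,
            strand="+", target_name="chrT", target_len=len(ref), target_start=0,
            target_end=5000, n_matches=5000, block_len=5000,
        )
        with pytest.raises(ValueError):
            resolve_spanning(gap, short, ref, contig)


class TestCloseGaps:
    def test_recovers_all_recoverable_fills_exactly(self, small_bundle):
        truth = small_bundle.truth.by_id()
        for asm_id, contigs in small_bundle.assemblies.items():
            alns = align_fasta(contigs, small_bundle.ref)
            select_best_chains(alns)
            reports = close_gaps(asm_id, small_bundle.gaps, alns, contigs, small_bundle.ref)
            by_gap = {r.gap_id: r for r in reports}
            for g in small_bundle.truth.gaps:
                r = by_gap[g.gap_id]
                if g.category == "filled" and g.recoverable.get(asm_id):
                    assert r.status == "closed", (asm_id, g.gap_id, r.note)
                    expected = g.alleles[g.assembly_allele[asm_id]]
                    assert r.sequences[0].sequence == expected
                    assert r.sequences[0].left_edge_distance < 100
                    assert r.sequences[0].right_edge_distance < 100
                elif g.category == "discrepant":
                    assert r.status == "discrepant"
                elif g.category == "unfilled":
                    assert r.status == "open"

    def test_no_alignments_near_gap_is_open(self):
        gap = _gap()
        reports = close_gaps("asm", [gap], [], {}, {"chrT": "A" * 2000})
        assert reports[0].status == "open" and reports[0].sequences == []

    def test_strand_symmetry_of_donor_contig(self, small_bundle):
        # reverse-complementing a donor contig flips the recorded strand but
        # not the emitted fill sequence
        truth = small_bundle.truth.by_id()
        asm_id = sorted(small_bundle.assemblies)[0]
        target = None
        for g in small_bundle.truth.gaps:
            if g.category == "filled" and g.recoverable.get(asm_id):
                target = g
                break
        assert target is not None
        contig_name = target.contig_location[asm_id][0]
        contigs = dict(small_bundle.assemblies[asm_id])
        contigs[contig_name] = revcomp(contigs[contig_name])
        alns = align_fasta(contigs, small_bundle.ref)
        select_best_chains(alns)
        reports = {r.gap_id: r for r in close_gaps(asm_id, small_bundle.gaps, alns, contigs, small_bundle.ref)}
        r = reports[target.gap_id]
        assert r.status == "closed"
        assert r.sequences[0].sequence == target.alleles[target.assembly_allele[asm_id]]
        assert r.sequences[0].strand_relative_to_ref == "-"


def test_fills_fasta_round_trip(tmp_path, small_bundle):
    asm_id = sorted(small_bundle.assemblies)[0]
    contigs = small_bundle.assemblies[asm_id]
    alns = align_fasta(contigs, small_bundle.ref)
    select_best_chains(alns)
    reports = close_gaps(asm_id, small_bundle.gaps, alns, contigs, small_bundle.ref)
    fills = [s for r in reports if r.status == "closed" for s in r.sequences]
    assert fills
    path = tmp_path / "fills.fa"
    write_fills_fasta(fills, path)
    back = read_fills_fasta(path)
    assert [(f.gap_id, f.sequence) for f in back] == [(f.gap_id, f.sequence) for f in fills]
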