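"""Padding, per-base depth, breadth/depth summaries, combined gap depth,
depth ratios and the Fisher population-specificity test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gapfill.coverage_validation import (
    CoverageProfile,
    PaddedReference,
    breadth_summary_by_sex,
    combined_gap_depth,
    coverage_matrix,
    depth_from_sam,
    depth_from_tsv,
    depth_ratio,
    mean_depth_matrix,
    pad_references,
    population_specificity,
    read_sample_meta,
    validated_sample_matrix,
)
from gapfill.gap_catalog import GapRecord, GapType
from gapfill.gap_closure import GapClosingSequence
from gapfill.synthetic_data import Read, reads_to_depth, simulate_reads, write_depth_tsv, write_sam

from conftest import rand_seq


def _fill(seq, gap="gap_1", asm="asm1"):
    return GapClosingSequence(gap_id=gap, assembly_id=asm, contig_name="c",
                              contig_start=0, contig_end=len(seq), sequence=seq)


def _gap(chrom, start, end, gap_id):
    return GapRecord(chrom=chrom, start=start, end=end,
                     gap_type=GapType.WITHIN_SCAFFOLD, gap_id=gap_id)


class TestPadReferences:
    def test_184bp_fill_pads_to_382(self):
        rng = np.random.default_rng(0)
        ref = {"chr20": rand_seq(rng, 1000) + "N" * 60 + rand_seq(rng, 1000)}
        gap = _gap("chr20", 1000, 1060, "gap_564")
        fill = _fill(rand_seq(rng, 184), gap="gap_564")
        (p,) = pad_references([fill], {"gap_564": gap}, ref, pad_bp=99)
        assert len(p.sequence) == 184 + 2 * 99 == 382
        assert p.sequence[99:-99] == fill.sequence
        assert p.sequence[:99] == ref["chr20"][901:1000]

    def test_truncation_at_chromosome_start_and_at_n(self):
        rng = np.random.default_rng(1)
        ref = {"chr1": rand_seq(rng, 20) + "N" * 50 + rand_seq(rng, 30) + "N" * 10 + rand_seq(rng, 500)}
        gap = _gap("chr1", 100, 110, "g")  # left flank: 30 N-free bp, then an N run
        (p,) = pad_references([_fill(rand_seq(rng, 40), gap="g")], {"g": gap}, ref, pad_bp=99)
        assert p.pad_left == 30 and p.pad_right == 99

    def test_zero_padding_is_identity(self):
        rng = np.random.default_rng(2)
        ref = {"chr1": rand_seq(rng, 300)}
        gap = _gap("chr1", 100, 150, "g")
        fill = _fill(rand_seq(rng, 60), gap="g")
        (p,) = pad_references([fill], {"g": gap}, ref, pad_bp=0)
        assert p.sequence == fill.sequence and p.pad_left == p.pad_right == 0


def _padded(seq_id, fill_len, pad=10, rng=None):
    rng = rng or np.random.default_rng(0)
    return PaddedReference(seq_id, rand_seq(rng, fill_len + 2 * pad), pad, pad)


class TestDepth:
    def test_tiling_reads_arithmetic(self):
        ref = _padded("s1", 200, pad=0)
        reads = [Read("s1", s, s + 100, ref.sequence[s : s + 100])
                 for s in (0, 100, 0, 100)]
        depths = reads_to_depth(reads, {"s1": 200})
        prof = CoverageProfile("s1", "samp", depths["s1"], 0, 0)
        assert prof.mean_depth == 2.0 and prof.breadth_at_1x == 1.0

    def test_no_reads(self):
        prof = CoverageProfile("s1", "samp", np.zeros(100, dtype=int), 10, 10)
        assert prof.mean_depth == 0.0 and prof.breadth_at_1x == 0.0

    def test_sam_route_with_clips_deletions_and_flags(self, tmp_path):
        ref = _padded("s1", 180, pad=10)
        sam = tmp_path / "samp.sam"
        lines = [
            "@HD\tVN:1.6",
            f"@SQ\tSN:s1\tLN:{len(ref.sequence)}",
            # spans [0,100)
            "r1\t0\ts1\t1\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*",
            # soft clip: reference span [100,195): clipped bases excluded
            "r2\t0\ts1\t101\t60\t5S95M\t*\t0\t0\t" + "A" * 100 + "\t*",
            # deletion counts as covered: span [0,100)
            "r3\t0\ts1\t1\t60\t45M10D45M\t*\t0\t0\t" + "A" * 90 + "\t*",
            # secondary alignment ignored
            "r4\t256\ts1\t1\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*",
            # unmapped ignored
            "r5\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 50 + "\t*",
        ]
        sam.write_text("\n".join(lines) + "\n")
        (prof,) = depth_from_sam(sam, {"s1": ref}, "samp")
        d = prof.depth
        assert d[0] == 2 and d[50] == 2  # r1 + r3 (deletion covered)
        assert d[99] == 2 and d[100] == 1 and d[194] == 1 and d[195] == 0

    def test_sam_unknown_reference_rejected(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:mystery\tLN:100\n")
        with pytest.raises(KeyError, match="mystery"):
            depth_from_sam(sam, {"s1": _padded("s1", 80)}, "samp")

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        ref = _padded("s1", 150, pad=20, rng=rng)
        reads = simulate_reads({"s1": ref.sequence}, 4.0, 50, rng, embedded=True)
        depths = reads_to_depth(reads, {"s1": len(ref.sequence)})
        path = tmp_path / "samp.tsv"
        write_depth_tsv(depths, path)
        (prof,) = depth_from_tsv(path, {"s1": ref}, "samp")
        assert np.array_equal(prof.depth, depths["s1"])

    def test_depth_conservation_against_naive_loop(self):
        rng = np.random.default_rng(4)
        seqs = {f"s{i}": rand_seq(rng, 400) for i in range(3)}
        reads = simulate_reads(seqs, 3.0, 60, rng, embedded=True)
        depths = reads_to_depth(reads, {k: len(v) for k, v in seqs.items()})
        total = sum(int(d.sum()) for d in depths.values())
        naive = sum(r.end - r.start for r in reads)
        assert total == naive

    def test_padding_exclusion(self):
        rng = np.random.default_rng(5)
        depth = np.ones(120, dtype=int)
        prof = CoverageProfile("s1", "samp", depth.copy(), 10, 10)
        perturbed = depth.copy()
        perturbed[:10] = 99
        perturbed[-10:] = 0
        prof2 = CoverageProfile("s1", "samp", perturbed, 10, 10)
        assert prof.mean_depth == prof2.mean_depth
        assert prof.breadth_at_1x == prof2.breadth_at_1x

    def test_uniform_simulation_recovers_depth(self):
        # Poisson coverage model: pooled mean depth within 3 SE of target
        rng = np.random.default_rng(6)
        target = 4.0
        refs = {f"s{i}": rand_seq(rng, 2000) for i in range(10)}
        reads = simulate_reads(refs, target, 100, rng, embedded=True)
        depths = reads_to_depth(reads, {k: len(v) for k, v in refs.items()})
        total_bases = sum(d.sum() for d in depths.values())
        n_reads = len(reads)
        est = total_bases / sum(len(v) for v in refs.values())
        se = target / np.sqrt(n_reads)
        assert abs(est - target) < 3 * se + 0.05  # small edge-clipping allowance


class TestMatrices:
    def _profiles(self):
        out = []
        for sid, samp, breadth in [("a", "s1", 0.95), ("a", "s2", 0.5),
                                   ("b", "s1", 0.80), ("b", "s2", 0.80)]:
            depth = np.zeros(100, dtype=int)
            depth[: int(breadth * 100)] = 2
            out.append(CoverageProfile(sid, samp, depth, 0, 0))
        return out

    def test_strict_cutoff(self):
        breadth, validated = coverage_matrix(self._profiles(), breadth_cutoff=0.8)
        assert bool(validated["a"]) is True
        assert bool(validated["b"]) is False  # exactly 0.80 everywhere: strict >
        vmat = validated_sample_matrix(breadth)
        assert vmat.loc["a", "s1"] and not vmat.loc["a", "s2"]

    def test_all_planted_fills_validated(self, study_results):
        assert bool(study_results.validated.all())

    def test_combined_depth_formula(self):
        mean_depths = pd.DataFrame({"samp": [3.0, 2.0]}, index=["a", "b"])
        combined = combined_gap_depth(
            mean_depths, {"a": "g1", "b": "g1"}, {"a": 500, "b": 500}
        )
        assert combined.loc["g1", "samp"] == pytest.approx(5.0)
        single = combined_gap_depth(
            mean_depths.loc[["a"]], {"a": "g1"}, {"a": 500}
        )
        assert single.loc["g1", "samp"] == pytest.approx(3.0)
        literal = combined_gap_depth(
            mean_depths, {"a": "g1", "b": "g1"}, {"a": 500, "b": 250}, literal=True
        )
        # the literal reading divides the plain sum of mean depths by the
        # longest allele length
        assert literal.loc["g1", "samp"] == pytest.approx(5.0 / 500)
        weighted = combined_gap_depth(
            mean_depths, {"a": "g1", "b": "g1"}, {"a": 500, "b": 250}
        )
        assert weighted.loc["g1", "samp"] == pytest.approx((3 * 500 + 2 * 250) / 500)

    def test_biallelic_combined_depth_recovers_sample_depth(self):
        # two alleles, each carried by half the samples at depth d: per-allele
        # mean across samples ~ d/2, combined per carrier ~ d * len/maxlen
        rng = np.random.default_rng(7)
        d = 6.0
        a = _padded("a", 1500, pad=0, rng=rng)
        b = _padded("b", 1500, pad=0, rng=rng)
        profiles = []
        for i, samp in enumerate([f"s{j}" for j in range(10)]):
            carried, other = (a, b) if i % 2 else (b, a)
            reads = simulate_reads({carried.sequence_id: carried.sequence}, d, 100, rng,
                                   embedded=True)
            depth = reads_to_depth(reads, {carried.sequence_id: 1500})[carried.sequence_id]
            profiles.append(CoverageProfile(carried.sequence_id, samp, depth, 0, 0))
            profiles.append(CoverageProfile(other.sequence_id, samp, np.zeros(1500, dtype=int), 0, 0))
        mat = mean_depth_matrix(profiles)
        assert mat.mean(axis=1).mean() == pytest.approx(d / 2, rel=0.15)
        combined = combined_gap_depth(mat, {"a": "g", "b": "g"}, {"a": 1500, "b": 1500})
        assert combined.loc["g"].mean() == pytest.approx(d, rel=0.15)


class TestDepthRatio:
    def test_simple_ratio(self):
        mat = pd.DataFrame({"s1": [1.0]}, index=["a"])
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "sex": ["F"], "population": ["P"], "genome_depth": [4.0]}
        )
        out = depth_ratio(mat, meta)
        assert out["mean"] == pytest.approx(0.25)

    def test_missing_genome_depth_skipped(self):
        mat = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["a"])
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "sex": ["F"], "population": ["P"], "genome_depth": [2.0]}
        )
        with pytest.warns(UserWarning, match="s2"):
            out = depth_ratio(mat, meta)
        assert len(out["ratios"]) == 1

    def test_half_recovery_halves_the_ratio(self):
        # only half the reads over a fill recoverable -> mean ratio ~ 0.5
        rng = np.random.default_rng(8)
        refs = {f"s{i}": rand_seq(rng, 3000) for i in range(5)}
        genome_depth = 6.0
        profiles = []
        for samp in ["x1", "x2"]:
            reads = simulate_reads(refs, genome_depth * 0.5, 100, rng, embedded=True)
            depths = reads_to_depth(reads, {k: len(v) for k, v in refs.items()})
            profiles += [CoverageProfile(k, samp, depths[k], 0, 0) for k in refs]
        mat = mean_depth_matrix(profiles)
        meta = pd.DataFrame(
            {"sample_id": ["x1", "x2"], "sex": ["F", "M"], "population": ["P", "P"],
             "genome_depth": [genome_depth] * 2}
        )
        out = depth_ratio(mat, meta)
        assert out["mean"] == pytest.approx(0.5, abs=0.05)

    def test_meta_validation(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample_id\tsex\tpopulation\tgenome_depth\ns1\tF\tP\t0\n")
        with pytest.raises(ValueError, match="genome_depth"):
            read_sample_meta(p)
        p.write_text("sample_id\tsex\tpopulation\ns1\tF\tP\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_sample_meta(p)


class TestPopulationSpecificity:
    @staticmethod
    def _meta(n_a=20, n_b=40):
        rows = [{"sample_id": f"a{i}", "sex": "F", "population": "A", "genome_depth": 4.0}
                for i in range(n_a)]
        rows += [{"sample_id": f"b{i}", "sex": "M", "population": "B", "genome_depth": 4.0}
                 for i in range(n_b)]
        return pd.DataFrame(rows)

    def test_private_sequence_flagged(self):
        meta = self._meta()
        samples = list(meta["sample_id"])
        validated = pd.DataFrame(
            [[s.startswith("a") for s in samples]], index=["seq1"], columns=samples
        )
        out = population_specificity(validated, meta)
        # hypergeometric closed form: 1 / C(60, 20), Bonferroni x2 populations
        from math import comb

        assert out.loc["seq1", "min_p"] == pytest.approx(2 / comb(60, 20), rel=1e-6)
        assert bool(out.loc["seq1", "flagged"])

    def test_uniform_sequence_not_flagged(self):
        meta = self._meta()
        samples = list(meta["sample_id"])
        validated = pd.DataFrame([[True] * len(samples)], index=["seq1"], columns=samples)
        out = population_specificity(validated, meta)
        assert out.loc["seq1", "min_p"] == pytest.approx(1.0)
        assert not bool(out.loc["seq1", "flagged"])

    def test_single_population_rejected(self):
        meta = self._meta(n_a=10, n_b=0)
        validated = pd.DataFrame([[True] * 10], index=["s"], columns=list(meta["sample_id"]))
        with pytest.raises(ValueError):
            population_specificity(validated, meta)


def test_breadth_summary_by_sex():
    breadth = pd.DataFrame({"s1": [1.0], "s2": [0.2]}, index=["seqY"])
    meta = pd.DataFrame(
        {"sample_id": ["s1", "s2"], "sex": ["M", "F"], "population": ["P", "P"],
         "genome_depth": [4.0, 4.0]}
    )
    out = breadth_summary_by_sex(breadth, meta)
    assert out.loc["seqY", "M"] == 1.0 and out.loc["seqY", "F"] == 0.2
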