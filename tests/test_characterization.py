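"""GC composition, reference-window sampling, RepeatMasker parsing and
repeat-class enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gapfill.characterization import (
    RepeatAnnotation,
    gc_content,
    gc_comparison,
    masked_gc,
    parse_repeatmasker_out,
    repeat_enrichment,
    sample_reference_windows,
    write_repeatmasker_out,
)
from gapfill.sequtils import revcomp
from gapfill.synthetic_data import emit_repeat_fixture

from conftest import rand_seq


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", 0.5), ("GGCC", 1.0), ("ANGT", 1 / 3), ("acgt", 0.5)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1).filter(lambda s: set(s) != {"N"}))
    def test_reverse_complement_invariance(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(revcomp(seq)))


@pytest.fixture(scope="module")
def ref():
    rng = np.random.default_rng(0)
    return {
        "chr1": rand_seq(rng, 40_000) + "N" * 500 + rand_seq(rng, 40_000),
        "chr2": rand_seq(rng, 30_000),
    }


class TestSampleReferenceWindows:

    def test_deterministic_and_n_free(self, ref):
        lengths = [100, 250, 800]
        a = sample_reference_windows(ref, lengths, 50, seed=11)
        b = sample_reference_windows(ref, lengths, 50, seed=11)
        assert a == b
        assert all("N" not in seq for _, seq in a)
        assert all(len(seq) in lengths for _, seq in a)

    def test_length_distribution_matches_source(self, ref):
        rng = np.random.default_rng(1)
        lengths = [int(x) for x in rng.integers(80, 1200, size=300)]
        windows = sample_reference_windows(ref, lengths, 1000, seed=2)
        got = [len(seq) for _, seq in windows]
        assert stats.ks_2samp(got, lengths).pvalue > 0.01

    def test_input_validation(self, ref):
        with pytest.raises(ValueError):
            sample_reference_windows(ref, [100], 0, seed=1)
        with pytest.raises(ValueError):
            sample_reference_windows(ref, [], 5, seed=1)

    def test_unsatisfiable_length_errors(self):
        ref = {"chr1": "ACGT" * 10 + "N" + "ACGT" * 10}
        with pytest.raises(RuntimeError):
            sample_reference_windows(ref, [60], 1, seed=3, max_tries=20)


class TestGcComparison:
    def test_identical_groups_high_p(self):
        rng = np.random.default_rng(2)
        values = list(rng.uniform(0.3, 0.6, size=200))
        report = gc_comparison({"euchromatic": values}, values)
        assert report["classes"]["euchromatic"]["ks_p"] > 0.9

    def test_disjoint_uniforms_detected(self):
        rng = np.random.default_rng(3)
        low = rng.uniform(0.2, 0.4, size=200)
        high = rng.uniform(0.4, 0.6, size=200)
        report = gc_comparison({"euchromatic": list(low)}, list(high))
        assert report["classes"]["euchromatic"]["ks_p"] < 0.01

    def test_wilcoxon_detects_shift_direction(self):
        rng = np.random.default_rng(4)
        eu = rng.uniform(0.45, 0.6, size=150)
        ne = rng.uniform(0.25, 0.4, size=150)
        report = gc_comparison(
            {"euchromatic": list(eu), "non_euchromatic": list(ne)},
            list(rng.uniform(0.3, 0.6, size=150)),
        )
        assert report["wilcoxon_eu_vs_noneu_p"] < 0.01
        assert report["eu_minus_noneu_mean"] > 0


class TestRepeatMaskerParsing:
    def test_single_hit_fraction(self, tmp_path):
        path = tmp_path / "rm.out"
        write_repeatmasker_out([("seq1", 200, [(25, 175, "Satellite")])], path)
        ann = parse_repeatmasker_out(path, {"seq1": 200})["seq1"]
        assert ann.class_fraction("Satellite") == pytest.approx(0.75)

    def test_empty_annotation(self, tmp_path):
        path = tmp_path / "rm.out"
        write_repeatmasker_out([], path)
        ann = parse_repeatmasker_out(path, {"seq1": 200})["seq1"]
        assert all(v == 0 for v in ann.per_class_fraction.values())

    def test_overlapping_hits_merged(self, tmp_path):
        path = tmp_path / "rm.out"
        write_repeatmasker_out(
            [("seq1", 200, [(0, 100, "Simple_repeat"), (50, 150, "Simple_repeat")])], path
        )
        ann = parse_repeatmasker_out(path, {"seq1": 200})["seq1"]
        assert ann.class_fraction("Simple_repeat") == pytest.approx(0.75)

    def test_class_family_prefix_and_other(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            "header\nheader\n\n"
            "  463 1.3 0.6 1.7 seq1 1 100 (100) + ALR/Alpha Satellite/centr 1 100 (0) 1\n"
            "  463 1.3 0.6 1.7 seq1 101 150 (50) + WeirdRep Retroposon/SVA 1 50 (0) 2\n"
        )
        ann = parse_repeatmasker_out(path, {"seq1": 200})["seq1"]
        assert ann.class_fraction("Satellite") == pytest.approx(0.5)
        assert ann.class_fraction("Other") == pytest.approx(0.25)

    def test_truth_round_trip(self, small_bundle, tmp_path):
        path = tmp_path / "fills.out"
        emit_repeat_fixture(small_bundle.truth, path)
        lengths = {
            f"{g.gap_id}|a{ai}": len(seq)
            for g in small_bundle.truth.gaps
            for ai, seq in enumerate(g.alleles)
        }
        annots = parse_repeatmasker_out(path, lengths)
        for g in small_bundle.truth.gaps:
            for ai, planted in enumerate(g.allele_repeats):
                ann = annots[f"{g.gap_id}|a{ai}"]
                for s, e, cls in planted:
                    assert ann.class_fraction(cls) == pytest.approx((e - s) / ann.length)


class TestRepeatEnrichment:
    def _annot(self, sid, length, frac, cls):
        intervals = [(0, int(frac * length), cls)] if frac > 0 else []
        return RepeatAnnotation(sid, length, intervals)

    def test_planted_satellite_enrichment(self):
        rng = np.random.default_rng(5)
        fills = {
            f"f{i}": self._annot(f"f{i}", 500, float(rng.uniform(0.7, 0.9)), "Satellite")
            for i in range(50)
        }
        sampled = {
            f"s{i}": self._annot(f"s{i}", 500, float(rng.uniform(0.0, 0.05)), "Satellite")
            for i in range(50)
        }
        out = repeat_enrichment(fills, sampled)
        assert out.loc["Satellite", "p"] < 0.001
        assert out.loc["Satellite", "direction"] == "enriched"

    def test_identical_composition_null(self):
        fills = {f"f{i}": self._annot(f"f{i}", 500, 0.5, "LINE") for i in range(30)}
        sampled = {f"s{i}": self._annot(f"s{i}", 500, 0.5, "LINE") for i in range(30)}
        out = repeat_enrichment(fills, sampled)
        assert out.loc["LINE", "p"] > 0.9

    def test_permuted_labels_control_false_positives(self):
        # pool one composition, relabel randomly: detection rate at alpha ~ alpha
        rng = np.random.default_rng(6)
        pool = [float(x) for x in rng.uniform(0, 0.6, size=60)]
        hits = 0
        n_perm = 200
        alpha = 0.05
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            fills = {f"f{i}": self._annot(f"f{i}", 400, perm[i], "DNA") for i in range(30)}
            sampled = {
                f"s{i}": self._annot(f"s{i}", 400, perm[30 + i], "DNA") for i in range(30)
            }
            out = repeat_enrichment(fills, sampled, classes=("DNA",))
            hits += out.loc["DNA", "p"] < alpha
        rate = hits / n_perm
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_perm)


class TestMaskedGc:
    def test_fully_masked_dropped(self):
        seqs = {"a": "ATAT" * 50}
        annots = {"a": RepeatAnnotation("a", 200, [(0, 200, "Satellite")])}
        out, dropped = masked_gc(seqs, annots)
        assert out == {} and dropped == 1

    def test_no_repeats_identity(self):
        rng = np.random.default_rng(7)
        seq = rand_seq(rng, 300)
        out, dropped = masked_gc({"a": seq}, {"a": RepeatAnnotation("a", 300)})
        assert dropped == 0 and out["a"] == pytest.approx(gc_content(seq))

    def test_masking_shifts_gc_toward_reference(self):
        # fills built as AT-rich satellite plus a reference-like core: masked
        # GC moves toward the reference composition
        rng = np.random.default_rng(8)
        masked_vals, unmasked_vals = [], []
        for i in range(40):
            sat = "".join(rng.choice(list("AATT"), size=300))
            core = rand_seq(rng, 300)
            seq = sat + core
            ann = RepeatAnnotation(f"f{i}", 600, [(0, 300, "Satellite")])
            unmasked_vals.append(gc_content(seq))
            masked_vals.append(masked_gc({f"f{i}": seq}, {f"f{i}": ann})[0][f"f{i}"])
        assert np.mean(unmasked_vals) < 0.4
        assert abs(np.mean(masked_vals) - 0.5) < 0.05
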