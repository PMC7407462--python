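"""Characterization of gap-closing sequences: GC composition against
length-matched reference samples (Kolmogorov-Smirnov, Wilcoxon rank-sum),
repeat-class composition from RepeatMasker ``.out`` files, and repeat-masked
GC. RepeatMasker itself is consumed, never invoked."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequtils import open_text

__all__ = [
    "REPEAT_CLASSES",
    "RepeatAnnotation",
    "gc_content",
    "sample_reference_windows",
    "gc_comparison",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "repeat_enrichment",
    "masked_gc",
]

REPEAT_CLASSES = (
    "SINE",
    "LINE",
    "LTR",
    "DNA",
    "Simple_repeat",
    "Satellite",
    "Low_complexity",
    "Other",
)

_CANONICAL = {c.lower(): c for c in REPEAT_CLASSES}


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T), case-insensitive; N and ambiguity codes excluded."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / acgt


def _merge(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s > out[-1][1]:
            out.append([s, e])
        else:
            out[-1][1] = max(out[-1][1], e)
    return [(s, e) for s, e in out]


@dataclass
class RepeatAnnotation:
    """Repeat intervals over one sequence, 0-based half-open."""

    sequence_id: str
    length: int
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def class_fraction(self, repeat_class: str) -> float:
        merged = _merge([(s, e) for s, e, c in self.intervals if c == repeat_class])
        return sum(e - s for s, e in merged) / self.length if self.length else 0.0

    @property
    def per_class_fraction(self) -> dict[str, float]:
        return {c: self.class_fraction(c) for c in REPEAT_CLASSES}

    @property
    def masked_union(self) -> list[tuple[int, int]]:
        return _merge([(s, e) for s, e, _ in self.intervals])


def sample_reference_windows(
    ref_fasta: Mapping[str, str],
    lengths: Sequence[int],
    n: int,
    seed: int | np.random.Generator,
    *,
    max_tries: int = 200,
) -> list[tuple[str, str]]:
    """Draw ``n`` N-free windows from the reference, lengths resampled with
    replacement from the fills' empirical length distribution.

    Chromosomes are chosen with probability proportional to length and start
    positions uniformly; windows containing N are redrawn (bounded retries).
    Fully reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not lengths:
        raise ValueError("empty length distribution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(ref_fasta)
    sizes = np.array([len(ref_fasta[c]) for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    lengths = list(lengths)
    out: list[tuple[str, str]] = []
    for i in range(n):
        for attempt in range(max_tries):
            length = int(lengths[rng.integers(len(lengths))])
            ci = rng.choice(len(chroms), p=probs)
            chrom_seq = ref_fasta[chroms[ci]]
            if length >= len(chrom_seq):
                continue
            start = int(rng.integers(0, len(chrom_seq) - length))
            window = chrom_seq[start : start + length].upper()
            if "N" not in window:
                out.append((f"sample_{i + 1}", window))
                break
        else:
            raise RuntimeError(
                f"could not draw an N-free window of a requested length after {max_tries} tries"
            )
    return out


def gc_comparison(
    gc_by_class: Mapping[str, Sequence[float]],
    sampled_gc: Sequence[float],
) -> dict:
    """KS test of each fill class against the reference sample; Wilcoxon
    rank-sum between euchromatic and non-euchromatic fills.

    Returns per-class mean / KS statistic / p-value, the reference-sample
    mean, and the between-class Wilcoxon p where both classes are present.
    """
    sampled = np.asarray(sampled_gc, dtype=float)
    report: dict = {"sampled_mean": float(sampled.mean()), "classes": {}}
    for name, values in gc_by_class.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            continue
        ks = stats.ks_2samp(values, sampled)
        report["classes"][name] = {
            "n": int(values.size),
            "mean": float(values.mean()),
            "ks_stat": float(ks.statistic),
            "ks_p": float(ks.pvalue),
        }
    eu = np.asarray(gc_by_class.get("euchromatic", []), dtype=float)
    ne = np.asarray(gc_by_class.get("non_euchromatic", []), dtype=float)
    if eu.size >= 2 and ne.size >= 2:
        w = stats.mannwhitneyu(eu, ne, alternative="two-sided")
        report["wilcoxon_eu_vs_noneu_p"] = float(w.pvalue)
        report["eu_minus_noneu_mean"] = float(eu.mean() - ne.mean())
    return report


def _normalize_class(raw: str) -> str:
    prefix = raw.split("/")[0].strip().rstrip("?")
    return _CANONICAL.get(prefix.lower(), "Other")


def parse_repeatmasker_out(
    path, seq_lengths: Mapping[str, int]
) -> dict[str, RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file into per-sequence annotations.

    Standard layout: two whitespace-aligned header lines plus a blank line,
    then one row per hit; query coordinates are 1-based inclusive. Repeat
    class is the class/family column's prefix before "/". Sequences in
    ``seq_lengths`` without hits get empty annotations.
    """
    annots = {
        sid: RepeatAnnotation(sid, length) for sid, length in seq_lengths.items()
    }
    with open_text(path) as fh:
        lines = fh.readlines()
    if lines and not lines[0].split()[:1] == ["SW"] and not lines[0].strip().startswith("SW"):
        if lines[0].strip() and lines[0].split()[0].replace(".", "").isdigit():
            raise ValueError("malformed RepeatMasker header: data row on line 1")
    for line in lines[3:]:
        f = line.split()
        if not f:
            continue
        if len(f) < 11:
            raise ValueError(f"malformed RepeatMasker row: {line!r}")
        sid = f[4]
        start = int(f[5]) - 1
        end = int(f[6])
        repeat_class = _normalize_class(f[10])
        ann = annots.get(sid)
        if ann is not None:
            ann.intervals.append((start, end, repeat_class))
    return annots


def write_repeatmasker_out(
    entries: Sequence[tuple[str, int, Sequence[tuple[int, int, str]]]], path
) -> None:
    """Write annotations in the RepeatMasker ``.out`` dialect.

    ``entries`` holds (sequence_id, sequence_length, [(start, end, class)])
    with 0-based half-open intervals; coordinates are written 1-based
    inclusive as RepeatMasker does.
    """
    header = (
        "   SW   perc perc perc  query     position in query     matching"
        "  repeat         position in repeat\n"
        "score   div. del. ins.  sequence  begin  end    (left)  repeat"
        "  class/family   begin  end  (left)  ID\n"
        "\n"
    )
    class_to_name = {
        "Satellite": ("SYNSAT", "Satellite/centr"),
        "Simple_repeat": ("(CA)n", "Simple_repeat"),
        "LINE": ("L1SYN", "LINE/L1"),
        "SINE": ("AluSYN", "SINE/Alu"),
        "LTR": ("LTRSYN", "LTR/ERVL"),
        "DNA": ("DNASYN", "DNA/hAT"),
        "Low_complexity": ("A-rich", "Low_complexity"),
        "Other": ("UNKSYN", "Unknown"),
    }
    with open(path, "w") as fh:
        fh.write(header)
        hit_id = 0
        for sid, length, intervals in entries:
            for s, e, cls in intervals:
                hit_id += 1
                name, family = class_to_name.get(cls, ("UNKSYN", "Unknown"))
                fh.write(
                    f"  500   5.0  0.0  0.0  {sid}  {s + 1}  {e}  ({length - e})  +"
                    f"  {name}  {family}  1  {e - s}  (0)  {hit_id}\n"
                )


def repeat_enrichment(
    fill_annotations: Mapping[str, RepeatAnnotation],
    sampled_annotations: Mapping[str, RepeatAnnotation],
    classes: Sequence[str] = REPEAT_CLASSES,
) -> pd.DataFrame:
    """Per-class two-sided Wilcoxon rank-sum on per-sequence repeat fractions,
    fills vs length-matched reference samples. Reports the effect direction
    (difference of means) and p-value per class."""
    rows = []
    for cls in classes:
        fills = np.array([a.class_fraction(cls) for a in fill_annotations.values()])
        sampled = np.array([a.class_fraction(cls) for a in sampled_annotations.values()])
        if fills.size < 2 or sampled.size < 2:
            continue
        if np.all(fills == fills[0]) and np.all(sampled == fills[0]):
            p = 1.0  # identical constant composition
        else:
            p = float(
                stats.mannwhitneyu(fills, sampled, alternative="two-sided").pvalue
            )
        rows.append(
            {
                "repeat_class": cls,
                "fill_mean": float(fills.mean()),
                "sampled_mean": float(sampled.mean()),
                "direction": "enriched" if fills.mean() > sampled.mean() else "depleted",
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("repeat_class")


def masked_gc(
    sequences: Mapping[str, str],
    annotations: Mapping[str, RepeatAnnotation],
) -> tuple[dict[str, float], int]:
    """GC over non-repeat bases only.

    Repeat-masked bases leave both numerator and denominator; sequences that
    are fully masked (or have no unambiguous unmasked base) are dropped and
    counted. Returns ({sequence_id: gc}, n_dropped).
    """
    out: dict[str, float] = {}
    dropped = 0
    for sid, seq in sequences.items():
        ann = annotations.get(sid)
        if ann is None:
            out[sid] = gc_content(seq)
            continue
        masked = np.zeros(len(seq), dtype=bool)
        for s, e in ann.masked_union:
            masked[s:e] = True
        kept = "".join(ch for ch, m in zip(seq, masked) if not m)
        try:
            out[sid] = gc_content(kept) if kept else _raise_empty()
        except ValueError:
            dropped += 1
    return out, dropped


def _raise_empty() -> float:
    raise ValueError("empty")
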