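"""Read-coverage validation of non-redundant fills.

Fills are emitted with reference flank padding (99 bp by default, mirroring a
read length minus one so a read overlapping the first fill base can map), and
remapped-read depth is summarized as breadth of coverage (fraction of fill
bases covered at a given depth) and depth of coverage (mean reads per fill
base). Padding bases are excluded from both summaries. Read mapping itself is
out of scope: the module consumes SAM/BAM against the padded references, or a
3-column per-base depth TSV (sequence_id, pos, depth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .gap_catalog import GapRecord
from .gap_closure import GapClosingSequence, fill_id
from .sequtils import open_text

__all__ = [
    "PaddedReference",
    "CoverageProfile",
    "pad_references",
    "depth_from_sam",
    "depth_from_tsv",
    "depth_from_alignments",
    "coverage_matrix",
    "validated_sample_matrix",
    "combined_gap_depth",
    "depth_ratio",
    "population_specificity",
    "read_sample_meta",
    "breadth_summary_by_sex",
]


@dataclass
class PaddedReference:
    """A fill plus its reference flank padding."""

    sequence_id: str
    sequence: str
    pad_left: int
    pad_right: int
    gap_id: str = ""

    @property
    def fill_len(self) -> int:
        return len(self.sequence) - self.pad_left - self.pad_right


@dataclass
class CoverageProfile:
    """Per-base depth over one padded reference for one sample."""

    sequence_id: str
    sample_id: str
    depth: np.ndarray
    pad_left: int
    pad_right: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def fill_depth(self) -> np.ndarray:
        end = len(self.depth) - self.pad_right
        return self.depth[self.pad_left : end]

    def breadth_at(self, min_depth: int = 1) -> float:
        fd = self.fill_depth
        return float((fd >= min_depth).mean()) if fd.size else 0.0

    @property
    def breadth_at_1x(self) -> float:
        return self.breadth_at(1)

    @property
    def mean_depth(self) -> float:
        fd = self.fill_depth
        return float(fd.mean()) if fd.size else 0.0


def pad_references(
    fills: Sequence[GapClosingSequence],
    gaps_by_id: Mapping[str, GapRecord],
    ref_fasta: Mapping[str, str],
    pad_bp: int = 99,
) -> list[PaddedReference]:
    """Emit each fill with up to ``pad_bp`` N-free reference bases per side.

    Padding is taken from the reference immediately flanking the fill's gap;
    it is truncated at chromosome ends and at N runs, and the realized pad
    lengths are recorded per sequence.
    """
    out: list[PaddedReference] = []
    for f in fills:
        gap = gaps_by_id[f.gap_id]
        ref = ref_fasta[gap.chrom].upper()
        left = ref[max(0, gap.start - pad_bp) : gap.start]
        n_pos = left.rfind("N")
        if n_pos >= 0:
            left = left[n_pos + 1 :]
        right = ref[gap.end : gap.end + pad_bp]
        n_pos = right.find("N")
        if n_pos >= 0:
            right = right[:n_pos]
        out.append(
            PaddedReference(
                sequence_id=fill_id(f),
                sequence=left + f.sequence + right,
                pad_left=len(left),
                pad_right=len(right),
                gap_id=f.gap_id,
            )
        )
    return out


def _check_ids(ids, refs: Mapping[str, PaddedReference]) -> None:
    unmatched = sorted(set(ids) - set(refs))
    if unmatched:
        raise KeyError(
            "alignment reference ids not among padded references: "
            + ", ".join(unmatched)
        )


def depth_from_sam(
    path, refs: Mapping[str, PaddedReference], sample_id: str
) -> list[CoverageProfile]:
    """Per-base depth from a SAM/BAM of reads mapped to the padded references.

    Depth at base i counts primary aligned reads whose reference span
    (including deletions, excluding soft clips) covers i.
    """
    depths = {rid: np.zeros(len(r.sequence), dtype=np.int64) for rid, r in refs.items()}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        _check_ids(sam.references, refs)
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            d = depths[read.reference_name]
            s = max(0, read.reference_start)
            e = min(len(d), read.reference_end)
            if e > s:
                d[s:e] += 1
    return [
        CoverageProfile(rid, sample_id, depths[rid], refs[rid].pad_left, refs[rid].pad_right)
        for rid in refs
    ]


def depth_from_tsv(
    path, refs: Mapping[str, PaddedReference], sample_id: str
) -> list[CoverageProfile]:
    """Per-base depth from a TSV with columns sequence_id, pos (0-based), depth."""
    depths = {rid: np.zeros(len(r.sequence), dtype=np.int64) for rid, r in refs.items()}
    seen_ids = set()
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("sequence_id"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"line {lineno}: malformed depth row: {line!r}")
            seen_ids.add(f[0])
            if f[0] in depths:
                depths[f[0]][int(f[1])] = int(f[2])
    _check_ids(seen_ids, refs)
    return [
        CoverageProfile(rid, sample_id, depths[rid], refs[rid].pad_left, refs[rid].pad_right)
        for rid in refs
    ]


def depth_from_alignments(
    path, refs: Mapping[str, PaddedReference], sample_id: str
) -> list[CoverageProfile]:
    """Dispatch on file extension: .sam/.bam via pysam, anything else as TSV."""
    suffix = Path(str(path)).suffix.lower()
    if suffix in {".sam", ".bam"}:
        return depth_from_sam(path, refs, sample_id)
    return depth_from_tsv(path, refs, sample_id)


def coverage_matrix(
    profiles: Sequence[CoverageProfile],
    breadth_cutoff: float = 0.8,
    min_depth: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Breadth matrix (sequences x samples) and per-sequence validated flags.

    A sequence is validated iff some sample covers strictly more than
    ``breadth_cutoff`` of its fill bases at >= ``min_depth`` reads.
    """
    records = {}
    for p in profiles:
        records[(p.sequence_id, p.sample_id)] = p.breadth_at(min_depth)
    seqs = sorted({s for s, _ in records})
    samples = sorted({s for _, s in records})
    mat = pd.DataFrame(0.0, index=seqs, columns=samples)
    for (sid, samp), b in records.items():
        mat.at[sid, samp] = b
    validated = (mat > breadth_cutoff).any(axis=1)
    validated.name = "validated"
    return mat, validated


def validated_sample_matrix(
    breadth: pd.DataFrame, breadth_cutoff: float = 0.8
) -> pd.DataFrame:
    """Boolean sequences x samples matrix: breadth strictly above cutoff."""
    return breadth > breadth_cutoff


def combined_gap_depth(
    mean_depths: pd.DataFrame,
    seq_to_gap: Mapping[str, str],
    lengths: Mapping[str, int],
    *,
    literal: bool = False,
) -> pd.DataFrame:
    """Combine per-allele depth into per-gap depth (gaps x samples).

    Default: total aligned fill bases over the longest allele,
    ``sum_i(depth_i * len_i) / max_i(len_i)``; for a single allele this
    collapses to its mean depth. ``literal=True`` instead divides the plain
    sum of mean depths by the maximum length (dimensionally odd; kept for
    comparison).
    """
    rows = {}
    by_gap: dict[str, list[str]] = {}
    for sid in mean_depths.index:
        by_gap.setdefault(seq_to_gap[sid], []).append(sid)
    for gap_id, sids in sorted(by_gap.items()):
        lens = np.array([lengths[s] for s in sids], dtype=float)
        sub = mean_depths.loc[sids]
        if literal:
            rows[gap_id] = sub.sum(axis=0) / lens.max()
        else:
            rows[gap_id] = (sub.mul(lens, axis=0)).sum(axis=0) / lens.max()
    return pd.DataFrame(rows).T


def mean_depth_matrix(profiles: Sequence[CoverageProfile]) -> pd.DataFrame:
    records = {}
    for p in profiles:
        records[(p.sequence_id, p.sample_id)] = p.mean_depth
    seqs = sorted({s for s, _ in records})
    samples = sorted({s for _, s in records})
    mat = pd.DataFrame(0.0, index=seqs, columns=samples)
    for (sid, samp), d in records.items():
        mat.at[sid, samp] = d
    return mat


def depth_ratio(
    depth_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    carrier_mask: pd.DataFrame | None = None,
) -> dict[str, float | pd.Series]:
    """Per-sample ratio of sequence depth to genome-wide depth.

    ``depth_matrix`` holds mean depth per (sequence-or-gap) x sample; samples
    without a known genome depth are skipped with a warning. When
    ``carrier_mask`` is given (same shape, boolean), only carrier cells enter
    the summary — zero cells of samples that do not carry an allele say
    nothing about read recovery. Returns the flattened ratio values and their
    mean/sd.
    """
    gdepth = meta.set_index("sample_id")["genome_depth"]
    values = []
    for sample in depth_matrix.columns:
        if sample not in gdepth.index or not gdepth[sample] > 0:
            warnings.warn(f"sample {sample}: genome depth missing, skipped")
            continue
        col = depth_matrix[sample] / gdepth[sample]
        if carrier_mask is not None:
            col = col[carrier_mask[sample]]
        values.append(col)
    ratios = pd.concat(values) if values else pd.Series(dtype=float)
    return {
        "ratios": ratios,
        "mean": float(ratios.mean()) if len(ratios) else float("nan"),
        "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else float("nan"),
    }


def population_specificity(
    validated: pd.DataFrame, meta: pd.DataFrame, alpha: float = 0.001
) -> pd.DataFrame:
    """Two-sided Fisher's exact test of validation against population labels.

    For every sequence and population, a 2x2 table (validated vs not x
    in-population vs rest) is tested; p-values are Bonferroni-corrected
    across populations per sequence, and the minimum corrected p across
    populations is reported. Sequences with p < ``alpha`` are flagged.
    """
    pops = meta.set_index("sample_id")["population"]
    pop_names = sorted(pops.unique())
    if len(pop_names) < 2:
        raise ValueError("population_specificity requires >= 2 populations")
    samples = [s for s in validated.columns if s in pops.index]
    rows = []
    for sid in validated.index:
        v = validated.loc[sid, samples].to_numpy(dtype=bool)
        best_p, best_pop = 1.0, ""
        for pop in pop_names:
            in_pop = np.array([pops[s] == pop for s in samples])
            table = [
                [int((v & in_pop).sum()), int((v & ~in_pop).sum())],
                [int((~v & in_pop).sum()), int((~v & ~in_pop).sum())],
            ]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            p = min(1.0, p * len(pop_names))  # Bonferroni across populations
            if p < best_p:
                best_p, best_pop = p, pop
        rows.append({"sequence_id": sid, "min_p": best_p, "population": best_pop})
    out = pd.DataFrame(rows).set_index("sequence_id")
    out["flagged"] = out["min_p"] < alpha
    return out


def read_sample_meta(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, sex, population, genome_depth."""
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "sex", "population", "genome_depth"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    bad = meta[~(meta["genome_depth"] > 0)]
    if len(bad):
        raise ValueError(
            f"non-positive genome_depth for samples: {list(bad['sample_id'])}"
        )
    return meta


def breadth_summary_by_sex(breadth: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean breadth per sequence stratified by the sex field (chrY signal)."""
    sex = meta.set_index("sample_id")["sex"]
    groups = {}
    for s in sorted(sex.unique()):
        cols = [c for c in breadth.columns if sex.get(c) == s]
        if cols:
            groups[s] = breadth[cols].mean(axis=1)
    return pd.DataFrame(groups)
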