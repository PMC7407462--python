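"""Seeded synthetic data: a small reference with planted N-gaps of the five
annotated types, donor assemblies carrying known (possibly polymorphic,
repeat-rich or zero-length "discrepant") gap fills, contig fragmentation,
uniform-coverage error-free reads, RepeatMasker-style fixtures, and a truth
table — so every pipeline stage is testable without downloads.

Design notes. Gap flanks are drawn from the random background, which makes
them k-mer-unique genome-wide with overwhelming probability, so the toy
aligner anchors unambiguously ("hard mode" reuses one shared flank sequence
across gaps to exercise ambiguous anchoring). Donors are the reference with
each gap's N-run replaced by the assigned allele (or by nothing for
discrepant gaps, or kept for unfilled gaps, where the donor is split like a
real assembly would be); contigs arise from Poisson breakpoints that avoid
the flanks of fills meant to be recoverable. Tandem-repeat fills always
receive at least two point substitutions so that they contain unique anchor
k-mers. All randomness flows from one integer-seeded generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .characterization import write_repeatmasker_out
from .gap_catalog import GapClass, GapRecord, GapType, ModeledRegion, CytoBand
from .sequtils import write_fasta

__all__ = [
    "SimulationConfig",
    "GapTruth",
    "SampleTruth",
    "TruthTable",
    "SimBundle",
    "build_reference_and_donors",
    "simulate_reads",
    "reads_to_depth",
    "write_depth_tsv",
    "write_sam",
    "write_fastq",
    "emit_repeat_fixture",
    "write_bundle",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_AT_PROBS = np.array([0.35, 0.15, 0.15, 0.35])  # A C G T


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the scale reported for the real cohort at desk size:
    fill lengths log-normal with median ~300 bp (range capped at 20 kb),
    about a third of closed gaps polymorphic, roughly one gap in nine
    discrepant, error-free 100 bp reads at 4x depth.
    """

    seed: int
    n_chromosomes: int = 2
    chrom_length_bp: int = 200_000
    n_gaps: dict[str, int] = field(
        default_factory=lambda: {
            "within_scaffold": 22,
            "between_scaffolds": 8,
            "telomere": 4,
            "heterochromatin": 3,
            "short_arm": 3,
        }
    )
    gap_n_run: tuple[int, int] = (200, 1200)
    fill_length_median: float = 300.0
    fill_length_sigma: float = 1.0
    fill_length_max: int = 20_000
    fill_length_min: int = 80
    polymorphic_fraction: float = 0.33
    discrepant_fraction: float = 0.11
    unfilled_fraction: float = 0.12
    n_assemblies: int = 5
    contig_break_rate: float = 1.0 / 80_000
    break_fill_fraction: float = 0.1
    satellite_fraction: float = 0.3
    simple_repeat_fraction: float = 0.2
    satellite_monomer_bp: int = 171
    satellite_divergence: float = 0.05
    read_length: int = 100
    read_depth: float = 4.0
    n_samples: int = 30
    populations: dict[str, int] = field(
        default_factory=lambda: {"POP1": 10, "POP2": 10, "POP3": 10}
    )
    population_private_fraction: float = 0.25
    alt_fraction: float = 0.15
    chimp_fraction: float = 0.15
    gorilla_fraction: float = 0.08
    nrs_fraction: float = 0.25
    unique_flanks: bool = True
    flank_guard_bp: int = 400

    def __post_init__(self) -> None:
        for name in (
            "polymorphic_fraction",
            "discrepant_fraction",
            "unfilled_fraction",
            "break_fill_fraction",
            "satellite_fraction",
            "simple_repeat_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fill_length_max >= self.chrom_length_bp:
            raise ValueError("fill_length_max must be smaller than chrom_length_bp")
        if sum(self.populations.values()) != self.n_samples:
            raise ValueError("population sizes must sum to n_samples")


@dataclass
class GapTruth:
    chrom: str
    start: int
    end: int
    gap_type: str
    expected_class: str
    category: str  # filled | discrepant | unfilled
    alleles: list[str] = field(default_factory=list)
    allele_repeats: list[list[tuple[int, int, str]]] = field(default_factory=list)
    gap_id: str = ""
    assembly_allele: dict[str, int] = field(default_factory=dict)
    recoverable: dict[str, bool] = field(default_factory=dict)
    contig_location: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    population_private: str | None = None

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def expected_polymorphic(self) -> bool:
        return self.category == "filled" and self.n_alleles > 1


@dataclass
class SampleTruth:
    sample_id: str
    sex: str
    population: str
    genome_depth: float
    genotype: dict[str, int] = field(default_factory=dict)  # gap_id -> allele idx


@dataclass
class TruthTable:
    gaps: list[GapTruth]
    samples: list[SampleTruth]

    def by_id(self) -> dict[str, GapTruth]:
        return {g.gap_id: g for g in self.gaps}

    @property
    def expected_closed(self) -> set[str]:
        return {
            g.gap_id
            for g in self.gaps
            if g.category == "filled" and any(g.recoverable.values())
        }

    @property
    def expected_discrepant(self) -> set[str]:
        return {g.gap_id for g in self.gaps if g.category == "discrepant"}

    @property
    def expected_polymorphic(self) -> set[str]:
        return {g.gap_id for g in self.gaps if g.expected_polymorphic}


@dataclass
class SimBundle:
    config: SimulationConfig
    ref: dict[str, str]
    gaps: list[GapRecord]
    modeled: list[ModeledRegion]
    bands: list[CytoBand]
    assemblies: dict[str, dict[str, str]]
    truth: TruthTable
    datasets: dict[str, dict[str, str]]
    dataset_members: dict[str, set[tuple[str, int]]]


# ---------------------------------------------------------------------------
# sequence generation helpers
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int, probs=None) -> str:
    if n <= 0:
        return ""
    idx = rng.choice(4, size=n, p=probs)
    return _BASES[idx].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    arr = list(seq)
    for p in positions:
        old = arr[p]
        choices = [b for b in "ACGT" if b != old]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def _make_fill(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    length: int | None = None,
    kind: str | None = None,
) -> tuple[str, list[tuple[int, int, str]]]:
    """One fill allele with its planted repeat intervals."""
    if length is None:
        length = int(
            round(rng.lognormal(math.log(cfg.fill_length_median), cfg.fill_length_sigma))
        )
        length = int(np.clip(length, cfg.fill_length_min, cfg.fill_length_max))
    u = {"satellite": 0.0, "simple": cfg.satellite_fraction, "random": 1.0}.get(
        kind, rng.random()
    )
    if u < cfg.satellite_fraction:
        monomer = _rand_seq(rng, cfg.satellite_monomer_bp, _AT_PROBS)
        copies = []
        for _ in range(math.ceil(length / cfg.satellite_monomer_bp)):
            n_mut = rng.binomial(len(monomer), cfg.satellite_divergence)
            pos = rng.choice(len(monomer), size=n_mut, replace=False) if n_mut else []
            copies.append(_mutate(rng, monomer, pos))
        seq = "".join(copies)[:length]
        repeats = [(0, length, "Satellite")]
    elif u < cfg.satellite_fraction + cfg.simple_repeat_fraction:
        unit = _rand_seq(rng, int(rng.integers(2, 7)))
        seq = (unit * math.ceil(length / len(unit)))[:length]
        n_mut = max(0, rng.binomial(length, 0.02))
        if n_mut:
            pos = rng.choice(length, size=n_mut, replace=False)
            seq = _mutate(rng, seq, pos)
        repeats = [(0, length, "Simple_repeat")]
    else:
        seq = _rand_seq(rng, length)
        repeats = []
    if repeats and length >= 9:
        # guarantee unique anchor k-mers inside tandem arrays
        seq = _mutate(rng, seq, [length // 3, 2 * length // 3])
    return seq, repeats


# ---------------------------------------------------------------------------
# reference + donors
# ---------------------------------------------------------------------------


class _ChromBuilder:
    def __init__(self, rng: np.random.Generator, name: str, shared_flank: str | None):
        self.rng = rng
        self.name = name
        self.pieces: list[str] = []
        self.cursor = 0
        self.gaps: list[GapTruth] = []
        self.modeled: list[ModeledRegion] = []
        self.special_bands: list[tuple[int, int, str]] = []
        self.shared_flank = shared_flank

    def bg(self, n: int) -> None:
        self.pieces.append(_rand_seq(self.rng, n))
        self.cursor += n

    def spacing(self) -> None:
        self.bg(7000 + int(self.rng.integers(0, 2000)))

    def gap(self, gap_type: str, truth_kw: dict) -> GapTruth:
        if self.shared_flank is not None:
            self.pieces.append(self.shared_flank)
            self.cursor += len(self.shared_flank)
        n_run = int(self.rng.integers(*truth_kw.pop("n_run_range")))
        start = self.cursor
        self.pieces.append("N" * n_run)
        self.cursor += n_run
        if self.shared_flank is not None:
            self.pieces.append(self.shared_flank)
            self.cursor += len(self.shared_flank)
        g = GapTruth(
            chrom=self.name, start=start, end=start + n_run, gap_type=gap_type, **truth_kw
        )
        self.gaps.append(g)
        return g

    def sequence(self) -> str:
        return "".join(self.pieces)


def _draw_category(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    u = rng.random()
    if u < cfg.discrepant_fraction:
        return "discrepant"
    if u < cfg.discrepant_fraction + cfg.unfilled_fraction:
        return "unfilled"
    return "filled"


def _make_alleles(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[list[str], list[list[tuple[int, int, str]]]]:
    seq1, rep1 = _make_fill(rng, cfg)
    if rng.random() < cfg.polymorphic_fraction:
        # the minor allele is made clearly distinct: non-repetitive content
        # (independent repeat arrays can exceed 90% mutual identity) at
        # <= 0.7x the major allele's length, so both the 90% identity and the
        # 90% length-ratio rules separate the two alleles
        len2 = max(cfg.fill_length_min // 2 + 10, int(len(seq1) * rng.uniform(0.3, 0.7)))
        seq2, rep2 = _make_fill(rng, cfg, length=len2, kind="random")
        return [seq1, seq2], [rep1, rep2]
    return [seq1], [rep1]


def build_reference_and_donors(config: SimulationConfig) -> SimBundle:
    """Build the full synthetic bundle: reference with N-gaps, annotation
    fixtures, donor assemblies, presence datasets, samples and truth.

    Deterministic per seed (single PCG64 generator, fixed iteration order).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shared_flank = None if cfg.unique_flanks else _rand_seq(rng, 200)

    # distribute gap slots across chromosomes round-robin
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    slots: dict[str, dict[str, int]] = {c: {} for c in chrom_names}
    for gtype, count in cfg.n_gaps.items():
        for i in range(count):
            c = chrom_names[i % cfg.n_chromosomes]
            slots[c][gtype] = slots[c].get(gtype, 0) + 1

    confounders = ["in_modeled", "near_modeled", "in_acen", "near_special"]
    builders: list[_ChromBuilder] = []
    for ci, chrom in enumerate(chrom_names):
        b = _ChromBuilder(rng, chrom, shared_flank)
        s = slots[chrom]
        n_tel = min(2, s.get("telomere", 0))
        n_sa = s.get("short_arm", 0)
        n_het = s.get("heterochromatin", 0)
        n_within = s.get("within_scaffold", 0)
        n_between = s.get("between_scaffolds", 0)
        my_confounders = []
        if ci == 0:
            for kind in confounders:
                if kind == "near_special" and n_het == 0:
                    continue
                if n_within - len(my_confounders) <= 0:
                    break
                my_confounders.append(kind)
        n_within_clean = n_within - len(my_confounders)

        def within_kw(expected: str) -> dict:
            return dict(
                expected_class=expected,
                category=_draw_category(rng, cfg),
                n_run_range=cfg.gap_n_run,
            )

        if n_tel >= 1:
            b.gap("telomere", dict(expected_class="non_euchromatic", category="unfilled", n_run_range=cfg.gap_n_run))
        b.spacing()
        for _ in range(n_sa):
            sa_start = b.cursor - 500
            b.gap("short_arm", dict(expected_class="non_euchromatic", category=_draw_category(rng, cfg), n_run_range=cfg.gap_n_run))
            b.special_bands.append((max(0, sa_start), b.cursor + 500, "stalk"))
            b.spacing()
        for hi in range(n_het):
            het_start = b.cursor - 500
            b.gap("heterochromatin", dict(expected_class="non_euchromatic", category=_draw_category(rng, cfg), n_run_range=cfg.gap_n_run))
            b.special_bands.append((max(0, het_start), b.cursor + 500, "gvar"))
            if hi == 0 and "near_special" in my_confounders:
                b.bg(3000)  # < 5 kb from the heterochromatin gap
                b.gap("within_scaffold", within_kw("non_euchromatic"))
            b.spacing()
        # acen band
        acen_start = b.cursor
        b.bg(2500)
        if "in_acen" in my_confounders:
            b.gap("within_scaffold", within_kw("non_euchromatic"))
        b.bg(2500)
        b.special_bands.append((acen_start, b.cursor, "acen"))
        b.spacing()
        # modeled region
        m_start = b.cursor
        b.bg(2500)
        if "in_modeled" in my_confounders:
            b.gap("within_scaffold", within_kw("non_euchromatic"))
        b.bg(2500)
        b.modeled.append(ModeledRegion(chrom=chrom, start=m_start, end=b.cursor, name=f"{chrom}_model"))
        if "near_modeled" in my_confounders:
            b.bg(3000)  # < 5 kb from the modeled region
            b.gap("within_scaffold", within_kw("non_euchromatic"))
        b.spacing()
        for _ in range(n_within_clean):
            b.gap("within_scaffold", within_kw("euchromatic"))
            b.spacing()
        for _ in range(n_between):
            b.gap("between_scaffolds", within_kw("euchromatic"))
            b.spacing()
        if n_tel >= 2:
            b.gap("telomere", dict(expected_class="non_euchromatic", category="unfilled", n_run_range=cfg.gap_n_run))
        if b.cursor < cfg.chrom_length_bp:
            b.bg(cfg.chrom_length_bp - b.cursor)
        builders.append(b)

    ref = {b.name: b.sequence() for b in builders}
    gap_truths: list[GapTruth] = [g for b in builders for g in b.gaps]
    modeled = [m for b in builders for m in b.modeled]

    # cytobands: tile each chromosome, special bands carved out
    bands: list[CytoBand] = []
    for b in builders:
        length = len(ref[b.name])
        cuts = sorted({0, length, *(s for s, _, _ in b.special_bands), *(e for _, e, _ in b.special_bands)})
        specials = {(s, e): stain for s, e, stain in b.special_bands}
        idx = 1
        for s, e in zip(cuts[:-1], cuts[1:]):
            if e <= s:
                continue
            stain = specials.get((s, e), "gneg" if idx % 2 else "gpos50")
            bands.append(CytoBand(b.name, s, e, f"{b.name.replace('chr', '')}q{idx}", stain))
            idx += 1

    # alleles + gap ids (coordinate order, matching the parser convention)
    gap_truths.sort(key=lambda g: (g.chrom, g.start))
    for i, g in enumerate(gap_truths, start=1):
        g.gap_id = f"gap_{i}"
        if g.category == "filled":
            g.alleles, g.allele_repeats = _make_alleles(rng, cfg)

    # population-private minor alleles among polymorphic gaps
    pop_names = sorted(cfg.populations)
    polymorphic = [g for g in gap_truths if g.expected_polymorphic]
    n_private = max(1, round(cfg.population_private_fraction * len(polymorphic))) if polymorphic else 0
    for i, g in enumerate(polymorphic[:n_private]):
        g.population_private = pop_names[i % len(pop_names)]

    # assembly allele assignment + broken-fill designation
    asm_names = [f"asm{i + 1}" for i in range(cfg.n_assemblies)]
    for g in gap_truths:
        if g.category != "filled":
            continue
        for i, asm in enumerate(asm_names):
            g.assembly_allele[asm] = i % g.n_alleles if g.n_alleles > 1 else 0
            g.recoverable[asm] = bool(rng.random() >= cfg.break_fill_fraction)
        for allele in range(g.n_alleles):
            carriers = [a for a in asm_names if g.assembly_allele[a] == allele]
            if carriers and not any(g.recoverable[a] for a in carriers):
                g.recoverable[carriers[0]] = True

    # donors
    assemblies: dict[str, dict[str, str]] = {}
    guard = cfg.flank_guard_bp
    for asm in asm_names:
        contigs: dict[str, str] = {}
        for chrom in chrom_names:
            ref_seq = ref[chrom]
            chrom_gaps = [g for g in gap_truths if g.chrom == chrom]
            parts: list[str] = []
            cursor = 0
            pos = 0
            events: list[tuple[int, int]] = []  # removed donor intervals
            forced_breaks: list[int] = []
            fill_locs: dict[str, tuple[int, int]] = {}
            forbidden: list[tuple[int, int]] = []
            for g in chrom_gaps:
                parts.append(ref_seq[pos : g.start])
                cursor += g.start - pos
                if g.category == "filled":
                    allele = g.alleles[g.assembly_allele[asm]]
                    fill_locs[g.gap_id] = (cursor, cursor + len(allele))
                    if g.recoverable[asm]:
                        forbidden.append((cursor - guard, cursor + len(allele) + guard))
                    else:
                        forced_breaks.append(cursor + len(allele) // 2)
                    parts.append(allele)
                    cursor += len(allele)
                elif g.category == "discrepant":
                    fill_locs[g.gap_id] = (cursor, cursor)
                    forbidden.append((cursor - guard, cursor + guard))
                else:  # unfilled: donor still carries the gap; split there
                    events.append((cursor, cursor + g.length_bp()))
                    parts.append("N" * g.length_bp())
                    cursor += g.length_bp()
                pos = g.end
            parts.append(ref_seq[pos:])
            cursor += len(ref_seq) - pos
            donor = "".join(parts)
            # random background breakpoints outside forbidden zones
            n_breaks = rng.poisson(cfg.contig_break_rate * len(donor))
            for p in sorted(int(x) for x in rng.integers(0, len(donor), size=n_breaks)):
                if any(s <= p < e for s, e in forbidden):
                    continue
                if any(s <= p < e for s, e in events):
                    continue
                forced_breaks.append(p)
            cut_points = sorted(set(forced_breaks))
            cuts = sorted(events + [(p, p) for p in cut_points])
            segments: list[tuple[int, int]] = []
            seg_start = 0
            for s, e in cuts:
                if s > seg_start:
                    segments.append((seg_start, s))
                seg_start = max(seg_start, e)
            if len(donor) > seg_start:
                segments.append((seg_start, len(donor)))
            for si, (s, e) in enumerate(segments):
                contigs[f"{asm}_{chrom}_c{si + 1}"] = donor[s:e]
            # truth: map fills onto contigs
            for g in chrom_gaps:
                loc = fill_locs.get(g.gap_id)
                if loc is None:
                    continue
                fs, fe = loc
                placed = False
                for si, (s, e) in enumerate(segments):
                    if s <= fs and fe <= e and (fe > fs or s < fs < e):
                        g.contig_location[asm] = (f"{asm}_{chrom}_c{si + 1}", fs - s, fe - s)
                        placed = True
                        break
                if g.category == "filled":
                    g.recoverable[asm] = bool(placed and g.recoverable.get(asm, False))
        assemblies[asm] = contigs

    # samples
    samples: list[SampleTruth] = []
    i = 0
    for pop in pop_names:
        for _ in range(cfg.populations[pop]):
            i += 1
            samples.append(
                SampleTruth(
                    sample_id=f"S{i:03d}",
                    sex="F" if rng.random() < 0.5 else "M",
                    population=pop,
                    genome_depth=float(cfg.read_depth * rng.uniform(0.8, 1.25)),
                )
            )
    for g in gap_truths:
        if g.category != "filled":
            continue
        for s in samples:
            if g.n_alleles == 1:
                s.genotype[g.gap_id] = 0
            elif g.population_private is not None:
                s.genotype[g.gap_id] = 1 if s.population == g.population_private else 0
            else:
                s.genotype[g.gap_id] = int(rng.integers(g.n_alleles))

    # presence datasets: ALT, two primates, one published NRS set
    dataset_members: dict[str, set[tuple[str, int]]] = {
        "ALT": set(),
        "chimp": set(),
        "gorilla": set(),
        "NRS_other": set(),
    }
    fractions = {
        "ALT": cfg.alt_fraction,
        "chimp": cfg.chimp_fraction,
        "gorilla": cfg.gorilla_fraction,
        "NRS_other": cfg.nrs_fraction,
    }
    for g in gap_truths:
        for ai in range(g.n_alleles):
            for name in sorted(dataset_members):
                if rng.random() < fractions[name]:
                    dataset_members[name].add((g.gap_id, ai))
    truth_by_id = {g.gap_id: g for g in gap_truths}
    datasets: dict[str, dict[str, str]] = {}
    for name in sorted(dataset_members):
        pieces = [_rand_seq(rng, 500)]
        for gap_id, ai in sorted(dataset_members[name]):
            pieces.append(truth_by_id[gap_id].alleles[ai])
            pieces.append(_rand_seq(rng, 500))
        datasets[name] = {f"{name}_seq1": "".join(pieces)}

    gap_records = [
        GapRecord(
            chrom=g.chrom,
            start=g.start,
            end=g.end,
            gap_type=GapType(g.gap_type),
            gap_id=g.gap_id,
        )
        for g in gap_truths
    ]
    return SimBundle(
        config=cfg,
        ref=ref,
        gaps=gap_records,
        modeled=modeled,
        bands=bands,
        assemblies=assemblies,
        truth=TruthTable(gaps=gap_truths, samples=samples),
        datasets=datasets,
        dataset_members=dataset_members,
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Read:
    ref_id: str
    start: int
    end: int
    sequence: str


def simulate_reads(
    seqs: Mapping[str, str],
    depth: float,
    read_length: int,
    seed: int | np.random.Generator,
    *,
    error_rate: float = 0.0,
    embedded: bool = False,
) -> list[Read]:
    """Uniform error-free (by default) reads over each sequence.

    The read count per sequence is Poisson with mean ``depth * len /
    read_length``. With ``embedded=False`` reads lie fully inside the
    sequence (FASTQ-ready exact substrings); with ``embedded=True`` the
    sequence is treated as embedded in a larger genome, start positions may
    hang off either end and reads are clipped, which makes the expected
    per-base depth uniform across the whole sequence including its edges.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[Read] = []
    for rid in sorted(seqs):
        seq = seqs[rid].upper()
        n = int(rng.poisson(depth * len(seq) / read_length))
        if embedded:
            starts = rng.integers(-(read_length - 1), len(seq), size=n)
        else:
            if len(seq) < read_length:
                continue
            starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        for s in sorted(int(x) for x in starts):
            e = min(len(seq), s + read_length)
            s = max(0, s)
            if e <= s:
                continue
            sub = seq[s:e]
            if error_rate > 0:
                n_err = rng.binomial(len(sub), error_rate)
                if n_err:
                    pos = rng.choice(len(sub), size=n_err, replace=False)
                    sub = _mutate(rng, sub, pos)
            reads.append(Read(rid, s, e, sub))
    return reads


def reads_to_depth(
    reads: Sequence[Read], seq_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    depths = {rid: np.zeros(n, dtype=np.int64) for rid, n in seq_lengths.items()}
    for r in reads:
        depths[r.ref_id][r.start : r.end] += 1
    return depths


def write_depth_tsv(depths: Mapping[str, np.ndarray], path) -> None:
    """Write per-base depth as (sequence_id, pos, depth); zero rows omitted."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tpos\tdepth\n")
        for rid in sorted(depths):
            d = depths[rid]
            for pos in np.nonzero(d)[0]:
                fh.write(f"{rid}\t{pos}\t{d[pos]}\n")


def write_fastq(reads: Sequence[Read], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f"@read_{i} {r.ref_id}:{r.start}-{r.end}\n{r.sequence}\n+\n")
            fh.write("I" * len(r.sequence) + "\n")


def write_sam(reads: Sequence[Read], seq_lengths: Mapping[str, int], path) -> None:
    """Minimal SAM of perfectly mapped reads (CIGAR ``<len>M``)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rid in sorted(seq_lengths):
            fh.write(f"@SQ\tSN:{rid}\tLN:{seq_lengths[rid]}\n")
        for i, r in enumerate(reads, start=1):
            fh.write(
                f"read_{i}\t0\t{r.ref_id}\t{r.start + 1}\t60\t{len(r.sequence)}M\t*\t0\t0\t"
                f"{r.sequence}\t*\n"
            )


def emit_repeat_fixture(
    truth: TruthTable, path, id_map: Mapping[tuple[str, int], str] | None = None
) -> None:
    """Write the planted repeat composition of every fill allele as a
    RepeatMasker-style ``.out`` file.

    ``id_map`` renames (gap_id, allele_idx) keys; the default id is
    ``<gap_id>|a<idx>``.
    """
    entries = []
    for g in truth.gaps:
        for ai, (seq, reps) in enumerate(zip(g.alleles, g.allele_repeats)):
            sid = (id_map or {}).get((g.gap_id, ai), f"{g.gap_id}|a{ai}")
            entries.append((sid, len(seq), reps))
    write_repeatmasker_out(entries, path)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write the bundle as plain-text fixtures: reference FASTA, BED-dialect
    gap table, NCBI-dialect modeled regions, UCSC-dialect cytobands, donor
    FASTAs, sample metadata TSV and a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.ref, out / "reference.fa")
    with open(out / "gaps.bed", "w") as fh:
        for g in bundle.gaps:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gap_type.value}\n")
    with open(out / "modeled_regions.tsv", "w") as fh:
        fh.write("#region_name\tchromosome\tstart\tstop\n")
        for m in bundle.modeled:
            fh.write(f"{m.name}\t{m.chrom}\t{m.start + 1}\t{m.end}\n")
    with open(out / "cytoband.txt", "w") as fh:
        for b in bundle.bands:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.band_name}\t{b.stain}\n")
    asm_dir = out / "assemblies"
    asm_dir.mkdir(exist_ok=True)
    for asm, contigs in bundle.assemblies.items():
        write_fasta(contigs, asm_dir / f"{asm}.fa")
    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample_id\tsex\tpopulation\tgenome_depth\n")
        for s in bundle.truth.samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.population}\t{s.genome_depth:.3f}\n")
    truth = {
        "gaps": [asdict(g) for g in bundle.truth.gaps],
        "samples": [asdict(s) for s in bundle.truth.samples],
        "dataset_members": {
            k: sorted(list(v)) for k, v in bundle.dataset_members.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
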