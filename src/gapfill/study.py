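"""End-to-end synthetic study: generate a cohort, classify gaps, close them
with every donor assembly, cluster the fills, validate by read coverage,
test population specificity, decide presence in external datasets and
characterize the non-redundant set.

The numbered drivers under ``analysis/`` and the acceptance script both run
through these functions; tests compare the intermediate products against the
generator's truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import (
    alignment_io,
    characterization,
    clustering,
    coverage_validation as cov,
    gap_catalog,
    gap_closure,
    presence,
    synthetic_data,
)
from .gap_closure import GapClosingSequence, GapClosureReport, fill_id
from .synthetic_data import SimBundle, SimulationConfig

__all__ = ["StudyResults", "default_config", "run_closure", "run_study"]


@dataclass
class StudyResults:
    bundle: SimBundle
    classified_gaps: list
    reports: dict[str, list[GapClosureReport]]
    fills: list[GapClosingSequence]
    clusters_by_gap: Mapping[str, list]
    polymorphic_calls: list
    sharing: Mapping[str, bool]
    representatives: list[GapClosingSequence]
    rep_allele: dict[str, tuple[str, int]]  # rep fill id -> (gap_id, allele idx)
    breadth: pd.DataFrame
    validated: pd.Series
    validated_samples: pd.DataFrame
    mean_depths: pd.DataFrame
    combined_depth: pd.DataFrame
    ratio_before: dict
    ratio_after: dict
    fisher: pd.DataFrame
    meta: pd.DataFrame
    presence_matrix: pd.DataFrame
    novel: tuple[int, int, list[str]]
    gc_report: dict
    enrichment: pd.DataFrame

    @property
    def closed_gaps(self) -> set[str]:
        return {f.gap_id for f in self.fills}

    @property
    def discrepant_gaps(self) -> set[str]:
        out = set()
        closed = self.closed_gaps
        for reports in self.reports.values():
            for r in reports:
                if r.status == "discrepant" and r.gap_id not in closed:
                    out.add(r.gap_id)
        return out


def default_config(seed: int) -> SimulationConfig:
    """The study conditions: 40 gaps over two chromosomes, 5 donor
    assemblies, 30 samples in three populations, 4x error-free reads."""
    return SimulationConfig(seed=seed)


def run_closure(
    bundle: SimBundle, *, k: int = 31, mask_level: float = 0.9
) -> tuple[dict[str, list[GapClosureReport]], list[GapClosingSequence]]:
    """Align every donor to the reference, select best chains, close gaps."""
    reports: dict[str, list[GapClosureReport]] = {}
    fills: list[GapClosingSequence] = []
    for asm_id in sorted(bundle.assemblies):
        contigs = bundle.assemblies[asm_id]
        alns = alignment_io.align_fasta(contigs, bundle.ref, k=k)
        alignment_io.select_best_chains(alns, mask_level=mask_level)
        asm_reports = gap_closure.close_gaps(
            asm_id, bundle.gaps, alns, contigs, bundle.ref, k=k
        )
        reports[asm_id] = asm_reports
        for r in asm_reports:
            if r.status == "closed":
                fills.extend(r.sequences)
    return reports, fills


def _representatives(
    clusters_by_gap: Mapping[str, list], bundle: SimBundle
) -> tuple[list[GapClosingSequence], dict[str, tuple[str, int]]]:
    """Cluster representatives plus their (gap, planted-allele) identity."""
    truth = bundle.truth.by_id()
    reps: list[GapClosingSequence] = []
    rep_allele: dict[str, tuple[str, int]] = {}
    for gap_id, clusters in clusters_by_gap.items():
        g = truth.get(gap_id)
        for cl in clusters:
            rep = cl.representative
            reps.append(rep)
            allele_idx = -1
            if g is not None:
                for ai, allele in enumerate(g.alleles):
                    if allele == rep.sequence:
                        allele_idx = ai
                        break
            rep_allele[fill_id(rep)] = (gap_id, allele_idx)
    return reps, rep_allele


def run_study(
    config: SimulationConfig,
    *,
    recovery_fraction: float = 1.0,
    k: int = 31,
) -> StudyResults:
    """Run the whole pipeline on one synthetic cohort.

    ``recovery_fraction`` thins the reads recovered over fills, emulating the
    loss incurred when only reads left unmapped by the reference can be
    remapped to the fills.
    """
    bundle = synthetic_data.build_reference_and_donors(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    classified = gap_catalog.classify_gaps(bundle.gaps, bundle.modeled, bundle.bands)
    reports, fills = run_closure(bundle, k=k)

    clusters_by_gap = clustering.cluster_all(fills)
    poly_calls = clustering.call_polymorphic(clusters_by_gap)
    sharing = clustering.cross_assembly_sharing(fills)
    reps, rep_allele = _representatives(clusters_by_gap, bundle)

    # --- coverage validation -------------------------------------------------
    gaps_by_id = {g.gap_id: g for g in bundle.gaps}
    padded = cov.pad_references(reps, gaps_by_id, bundle.ref, pad_bp=99)
    padded_by_id = {p.sequence_id: p for p in padded}
    profiles = []
    for sample in bundle.truth.samples:
        carried = {
            p.sequence_id: p.sequence
            for p in padded
            if rep_allele[p.sequence_id][1]
            == sample.genotype.get(rep_allele[p.sequence_id][0], None)
        }
        reads = synthetic_data.simulate_reads(
            carried,
            sample.genome_depth * recovery_fraction,
            config.read_length,
            rng,
            embedded=True,
        )
        depths = synthetic_data.reads_to_depth(
            reads, {sid: len(seq) for sid, seq in carried.items()}
        )
        for p in padded:
            d = depths.get(p.sequence_id)
            if d is None:
                d = np.zeros(len(p.sequence), dtype=np.int64)
            profiles.append(
                cov.CoverageProfile(p.sequence_id, sample.sample_id, d, p.pad_left, p.pad_right)
            )
    breadth, validated = cov.coverage_matrix(profiles)
    validated_samples = cov.validated_sample_matrix(breadth)
    mean_depths = cov.mean_depth_matrix(profiles)
    seq_to_gap = {sid: gap for sid, (gap, _) in rep_allele.items()}
    lengths = {fill_id(r): r.length for r in reps}
    combined = cov.combined_gap_depth(mean_depths, seq_to_gap, lengths)
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "sex": s.sex,
                "population": s.population,
                "genome_depth": s.genome_depth,
            }
            for s in bundle.truth.samples
        ]
    )
    # ratios over all samples, carriers or not — non-carriers dilute the
    # per-allele ratio, combining alleles per gap recovers it
    ratio_before = cov.depth_ratio(mean_depths, meta)
    ratio_after = cov.depth_ratio(combined, meta)
    fisher = cov.population_specificity(validated_samples, meta)

    # --- presence ------------------------------------------------------------
    rep_seqs = {fill_id(r): r.sequence for r in reps}
    dataset_alns: dict[str, list] = {}
    targets = {"Primary": bundle.ref}
    targets.update(bundle.datasets)
    for name, seqs in targets.items():
        dataset_alns[name] = alignment_io.align_fasta(rep_seqs, seqs, k=k)
    pres = presence.presence_matrix(sorted(rep_seqs), dataset_alns)
    novel = presence.novel_nrs_length(pres, lengths, reference_datasets=("Primary", "ALT"))

    # --- characterization ----------------------------------------------------
    gap_class = {g.gap_id: g.gap_class.value for g in classified}
    gc_by_class: dict[str, list[float]] = {"euchromatic": [], "non_euchromatic": []}
    for r in reps:
        gc_by_class[gap_class[r.gap_id]].append(characterization.gc_content(r.sequence))
    sampled = characterization.sample_reference_windows(
        bundle.ref,
        [r.length for r in reps],
        n=max(60, 2 * len(reps)),
        seed=np.random.default_rng(np.random.SeedSequence([config.seed, 11])),
    )
    sampled_gc = [characterization.gc_content(s) for _, s in sampled]
    gc_report = characterization.gc_comparison(gc_by_class, sampled_gc)
    truth_by_id = bundle.truth.by_id()
    fill_entries = []
    for r in reps:
        gap_id, ai = rep_allele[fill_id(r)]
        reps_iv = truth_by_id[gap_id].allele_repeats[ai] if ai >= 0 else []
        fill_entries.append(
            characterization.RepeatAnnotation(fill_id(r), r.length, list(reps_iv))
        )
    fill_annots = {a.sequence_id: a for a in fill_entries}
    sampled_annots = {
        sid: characterization.RepeatAnnotation(sid, len(seq)) for sid, seq in sampled
    }
    enrichment = characterization.repeat_enrichment(fill_annots, sampled_annots)

    return StudyResults(
        bundle=bundle,
        classified_gaps=classified,
        reports=reports,
        fills=fills,
        clusters_by_gap=clusters_by_gap,
        polymorphic_calls=poly_calls,
        sharing=sharing,
        representatives=reps,
        rep_allele=rep_allele,
        breadth=breadth,
        validated=validated,
        validated_samples=validated_samples,
        mean_depths=mean_depths,
        combined_depth=combined,
        ratio_before=ratio_before,
        ratio_after=ratio_after,
        fisher=fisher,
        meta=meta,
        presence_matrix=pres,
        novel=novel,
        gc_report=gc_report,
        enrichment=enrichment,
    )
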