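"""Presence/absence of non-redundant fills in arbitrary target sequence sets.

A fill is *present* in a dataset when its alignments there reach >= 95%
identity over >= 80% query coverage (inclusive thresholds). Coverage is
computed on the union of merged query blocks; identity is block-length
weighted across the contributing alignments (a strictest-single-hit mode is
available). Alignments may come from any aligner normalized to PAF, or from
the bundled toy aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .alignment_io import AlignmentRecord

__all__ = [
    "PresenceHit",
    "merge_query_blocks",
    "evaluate_presence",
    "presence_matrix",
    "intersection_counts",
    "novel_nrs_length",
    "filter_self_hits",
]

MIN_IDENTITY = 0.95
MIN_COVERAGE = 0.80


@dataclass(frozen=True)
class PresenceHit:
    sequence_id: str
    dataset_id: str
    covered_fraction: float
    weighted_identity: float

    @property
    def present(self) -> bool:
        return (
            self.weighted_identity >= MIN_IDENTITY
            and self.covered_fraction >= MIN_COVERAGE
        )


def merge_query_blocks(
    alignments: Sequence[AlignmentRecord],
) -> tuple[float, float]:
    """(covered_fraction, weighted_identity) of one query against one dataset.

    Query intervals are merged into their union; covered_fraction is the
    union length over the query length, weighted_identity is
    ``sum(n_matches) / sum(block_len)``. Empty input yields (0, 0).
    """
    if not alignments:
        return 0.0, 0.0
    names = {a.query_name for a in alignments}
    if len(names) > 1:
        raise ValueError(f"alignments reference multiple queries: {sorted(names)}")
    qlen = alignments[0].query_len
    ivs = sorted((a.query_start, a.query_end) for a in alignments)
    union = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            union += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    union += cur_e - cur_s
    total_block = sum(a.block_len for a in alignments)
    total_match = sum(a.n_matches for a in alignments)
    identity = total_match / total_block if total_block else 0.0
    return union / qlen, identity


def evaluate_presence(
    sequence_id: str,
    dataset_id: str,
    alignments: Sequence[AlignmentRecord],
    *,
    single_best: bool = False,
) -> PresenceHit:
    """Presence decision for one (fill, dataset) pair.

    ``single_best=True`` uses only the alignment with the most matches
    (strictest-single-hit mode) instead of the merged union.
    """
    if single_best and alignments:
        best = max(alignments, key=lambda a: a.n_matches)
        alignments = [best]
    cov, ident = merge_query_blocks(alignments)
    return PresenceHit(sequence_id, dataset_id, cov, ident)


def presence_matrix(
    sequence_ids: Sequence[str],
    datasets: Mapping[str, Sequence[AlignmentRecord] | None],
    *,
    single_best: bool = False,
) -> pd.DataFrame:
    """Boolean sequences x datasets matrix of presence calls.

    ``datasets`` maps dataset name to that dataset's alignments of all fills
    (grouped here by query name). A ``None`` value marks a missing dataset
    file: it is skipped with a warning.
    """
    cols = {}
    for name, alns in datasets.items():
        if alns is None:
            warnings.warn(f"dataset {name}: alignment file missing, skipped")
            continue
        by_query: dict[str, list[AlignmentRecord]] = {}
        for a in alns:
            by_query.setdefault(a.query_name, []).append(a)
        cols[name] = {
            sid: evaluate_presence(
                sid, name, by_query.get(sid, []), single_best=single_best
            ).present
            for sid in sequence_ids
        }
    return pd.DataFrame(cols, index=list(sequence_ids)).fillna(False).astype(bool)


def intersection_counts(matrix: pd.DataFrame) -> pd.Series:
    """Upset-style intersection counts, keyed by the sorted member tuple.

    The empty tuple counts fills absent from every dataset (the novel set).
    """
    keys = [
        tuple(c for c in matrix.columns if row[c]) for _, row in matrix.iterrows()
    ]
    return pd.Series(keys).value_counts().sort_index()


def novel_nrs_length(
    matrix: pd.DataFrame,
    lengths: Mapping[str, int],
    reference_datasets: Sequence[str] = ("Primary", "ALT"),
) -> tuple[int, int, list[str]]:
    """Fills absent from every reference dataset: (count, total bp, ids)."""
    cols = [c for c in reference_datasets if c in matrix.columns]
    novel = matrix.index[~matrix[cols].any(axis=1)] if cols else matrix.index
    ids = list(novel)
    return len(ids), sum(lengths[i] for i in ids), ids


def filter_self_hits(
    alignments: Sequence[AlignmentRecord],
    source_loci: Mapping[str, tuple[str, int, int]],
) -> list[AlignmentRecord]:
    """Drop alignments of a fill back onto its own gap locus.

    ``source_loci`` maps query name to (chrom, start, end) of the fill's gap
    context on the source reference; alignments overlapping that interval on
    that chromosome are excluded.
    """
    out = []
    for a in alignments:
        locus = source_loci.get(a.query_name)
        if locus is not None:
            chrom, s, e = locus
            if a.target_name == chrom and a.target_start < e and a.target_end > s:
                continue
        out.append(a)
    return out
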