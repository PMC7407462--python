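"""Reference-gap catalog: parsing of gap/modeled-region/cytoband annotations and
euchromatic vs non-euchromatic classification.

A reference assembly annotates each run of Ns with a gap type. Only
``within_scaffold`` and ``between_scaffolds`` gaps can be euchromatic, and only
when they sit away from modeled regions (centromere models and the like), away
from telomeric / heterochromatic / short-arm context, and outside acen, gvar and
stalk cytogenetic bands. Everything else is non-euchromatic.

All internal coordinates are 0-based half-open (BED convention); parsers for
1-based dialects (NCBI gaps table, NCBI modeled-regions TSV) convert at the
boundary.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .sequtils import open_text

__all__ = [
    "GapType",
    "GapClass",
    "GapRecord",
    "ModeledRegion",
    "CytoBand",
    "parse_gap_table",
    "parse_modeled_regions",
    "parse_cytoband",
    "classify_gaps",
    "class_counts",
    "gap_length_summary",
    "write_classified_bed",
    "read_classified_bed",
]


class GapType(str, Enum):
    WITHIN_SCAFFOLD = "within_scaffold"
    BETWEEN_SCAFFOLDS = "between_scaffolds"
    HETEROCHROMATIN = "heterochromatin"
    SHORT_ARM = "short_arm"
    TELOMERE = "telomere"


class GapClass(str, Enum):
    EUCHROMATIC = "euchromatic"
    NON_EUCHROMATIC = "non_euchromatic"
    UNCLASSIFIED = "unclassified"


#: gap types that can never be euchromatic and exclude nearby gaps too
SPECIAL_TYPES = frozenset(
    {GapType.HETEROCHROMATIN, GapType.SHORT_ARM, GapType.TELOMERE}
)

#: cytoband stains that exclude overlapping gaps from the euchromatic set
EXCLUDED_STAINS = frozenset({"acen", "gvar", "stalk"})


@dataclass(frozen=True)
class GapRecord:
    """One reference N-gap. Coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    gap_type: GapType
    gap_id: str = ""
    gap_class: GapClass = GapClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid gap interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ModeledRegion:
    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid modeled region {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class CytoBand:
    chrom: str
    start: int
    end: int
    band_name: str
    stain: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid cytoband {self.chrom}:{self.start}-{self.end}")


def _normalize_gap_type(raw: str, lineno: int) -> GapType:
    key = raw.strip().lower()
    try:
        return GapType(key)
    except ValueError:
        allowed = ", ".join(t.value for t in GapType)
        raise ValueError(
            f"line {lineno}: unknown gap_type {raw!r}; allowed values: {allowed}"
        ) from None


def parse_gap_table(path) -> list[GapRecord]:
    """Parse a gap annotation table into sorted :class:`GapRecord` objects.

    Two dialects are accepted (gzip-transparent):

    * NCBI ``*_genomic.gaps`` — header line starting with ``#`` naming a
      ``gap_type`` column; coordinates 1-based inclusive.
    * BED-like — no header; columns chrom, start, end, gap_type; coordinates
      0-based half-open.

    Records are sorted by (chrom, start) and gap_ids assigned ``gap_1``,
    ``gap_2``, ... in that order.
    """
    records: list[tuple[str, int, int, GapType]] = []
    colmap: dict[str, int] | None = None
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = [c.strip().lower() for c in line.lstrip("#").split("\t")]
                if "gap_type" in header:
                    colmap = {name: i for i, name in enumerate(header)}
                continue
            fields = line.split("\t")
            try:
                if colmap is not None:
                    chrom = fields[colmap.get("accession.version", colmap.get("chrom", 0))]
                    start = int(fields[colmap["start"]]) - 1  # 1-based inclusive
                    end = int(fields[colmap["stop"]]) if "stop" in colmap else int(
                        fields[colmap["end"]]
                    )
                    gtype = _normalize_gap_type(fields[colmap["gap_type"]], lineno)
                else:
                    if len(fields) < 4:
                        raise IndexError
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gtype = _normalize_gap_type(fields[3], lineno)
            except (IndexError, KeyError):
                raise ValueError(
                    f"line {lineno}: malformed gap row (need chrom/start/end/type): {line!r}"
                ) from None
            except ValueError as exc:
                if "unknown gap_type" in str(exc):
                    raise
                raise ValueError(f"line {lineno}: malformed gap row: {line!r}") from None
            if not (0 <= start < end):
                raise ValueError(
                    f"line {lineno}: invalid gap interval {chrom}:{start}-{end}"
                )
            records.append((chrom, start, end, gtype))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    return [
        GapRecord(chrom=c, start=s, end=e, gap_type=t, gap_id=f"gap_{i}")
        for i, (c, s, e, t) in enumerate(records, start=1)
    ]


def parse_modeled_regions(path) -> list[ModeledRegion]:
    """Parse the NCBI modeled-regions TSV (1-based, ``#`` header) or a BED file."""
    out: list[ModeledRegion] = []
    one_based = False
    colmap: dict[str, int] | None = None
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = [c.strip().lower() for c in line.lstrip("#").split("\t")]
                if "stop" in header or "region_name" in header:
                    one_based = True
                    colmap = {name: i for i, name in enumerate(header)}
                continue
            f = line.split("\t")
            try:
                if colmap is not None:
                    name = f[colmap.get("region_name", 0)]
                    chrom = f[colmap.get("chromosome", 1)]
                    start = int(f[colmap["start"]]) - 1
                    end = int(f[colmap["stop"]])
                else:
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    if one_based:
                        start -= 1
                    name = f[3] if len(f) > 3 else ""
            except (IndexError, KeyError, ValueError):
                raise ValueError(f"line {lineno}: malformed modeled-region row: {line!r}") from None
            out.append(ModeledRegion(chrom=chrom, start=start, end=end, name=name))
    return out


def parse_cytoband(path) -> list[CytoBand]:
    """Parse a UCSC cytoBand table (chrom, start, end, name, gieStain; 0-based)."""
    out: list[CytoBand] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"line {lineno}: malformed cytoband row: {line!r}")
            out.append(
                CytoBand(chrom=f[0], start=int(f[1]), end=int(f[2]), band_name=f[3], stain=f[4])
            )
    return out


def _interval_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    """Edge-to-edge distance of two half-open intervals; 0 when they overlap/touch."""
    return max(s2 - e1, s1 - e2, 0)


def _warn_unknown_chroms(gaps: Sequence[GapRecord], others: Iterable[str], label: str) -> None:
    gap_chroms = {g.chrom for g in gaps}
    unknown = sorted(set(others) - gap_chroms)
    if unknown and gap_chroms:
        warnings.warn(
            f"{label} chromosomes absent from the gap table: {', '.join(unknown)}",
            stacklevel=3,
        )


def classify_gaps(
    gaps: Sequence[GapRecord],
    modeled: Sequence[ModeledRegion],
    bands: Sequence[CytoBand],
    flank_bp: int = 5000,
    *,
    flank_applies_to_modeled: bool = True,
    flank_applies_to_special: bool = True,
) -> list[GapRecord]:
    """Classify every gap as euchromatic or non-euchromatic.

    A gap is euchromatic iff all of the following hold:

    a. its type is within_scaffold or between_scaffolds;
    b. it does not overlap a modeled region;
    c. it is at distance >= ``flank_bp`` from every modeled region (when
       ``flank_applies_to_modeled``) and from every gap typed telomere /
       heterochromatin / short_arm (when ``flank_applies_to_special``);
       overlap counts as distance 0;
    d. it does not overlap a band with stain acen, gvar or stalk.

    Returns a new list in the input order with ``gap_class`` set on every
    record (the partition is total).
    """
    if flank_bp < 0:
        raise ValueError(f"flank_bp must be >= 0, got {flank_bp}")
    _warn_unknown_chroms(gaps, (m.chrom for m in modeled), "modeled-region")
    _warn_unknown_chroms(gaps, (b.chrom for b in bands), "cytoband")

    modeled_by_chrom: dict[str, list[ModeledRegion]] = {}
    for m in modeled:
        modeled_by_chrom.setdefault(m.chrom, []).append(m)
    special_by_chrom: dict[str, list[GapRecord]] = {}
    for g in gaps:
        if g.gap_type in SPECIAL_TYPES:
            special_by_chrom.setdefault(g.chrom, []).append(g)
    bad_bands_by_chrom: dict[str, list[CytoBand]] = {}
    for b in bands:
        if b.stain in EXCLUDED_STAINS:
            bad_bands_by_chrom.setdefault(b.chrom, []).append(b)

    out: list[GapRecord] = []
    for g in gaps:
        cls = GapClass.EUCHROMATIC
        if g.gap_type not in (GapType.WITHIN_SCAFFOLD, GapType.BETWEEN_SCAFFOLDS):
            cls = GapClass.NON_EUCHROMATIC
        if cls is GapClass.EUCHROMATIC:
            for m in modeled_by_chrom.get(g.chrom, ()):
                d = _interval_distance(g.start, g.end, m.start, m.end)
                if d == 0 and not (g.end <= m.start or m.end <= g.start):
                    cls = GapClass.NON_EUCHROMATIC  # overlap
                    break
                if flank_applies_to_modeled and d < flank_bp:
                    cls = GapClass.NON_EUCHROMATIC
                    break
        if cls is GapClass.EUCHROMATIC and flank_applies_to_special:
            for s in special_by_chrom.get(g.chrom, ()):
                if _interval_distance(g.start, g.end, s.start, s.end) < flank_bp:
                    cls = GapClass.NON_EUCHROMATIC
                    break
        if cls is GapClass.EUCHROMATIC:
            for b in bad_bands_by_chrom.get(g.chrom, ()):
                if not (g.end <= b.start or b.end <= g.start):
                    cls = GapClass.NON_EUCHROMATIC
                    break
        out.append(replace(g, gap_class=cls))
    return out


def class_counts(gaps: Sequence[GapRecord]) -> dict[str, int]:
    counts = {c.value: 0 for c in GapClass}
    for g in gaps:
        counts[g.gap_class.value] += 1
    return counts


def gap_length_summary(gaps: Sequence[GapRecord]) -> dict[str, float]:
    """Count / total / mean / median of gap lengths.

    Median uses the average-of-two-middles convention for even counts.
    """
    if not gaps:
        raise ValueError("gap_length_summary requires a non-empty gap list")
    lengths = [g.length for g in gaps]
    return {
        "count": len(lengths),
        "total_bp": sum(lengths),
        "mean_bp": sum(lengths) / len(lengths),
        "median_bp": float(statistics.median(lengths)),
    }


def write_classified_bed(gaps: Sequence[GapRecord], path) -> None:
    """Write a BED+ table: chrom, start, end, gap_id, gap_type, gap_class."""
    with open(path, "w") as fh:
        for g in gaps:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gap_id}\t"
                f"{g.gap_type.value}\t{g.gap_class.value}\n"
            )


def read_classified_bed(path) -> list[GapRecord]:
    out: list[GapRecord] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"line {lineno}: malformed classified-gap row: {line!r}")
            out.append(
                GapRecord(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    gap_id=f[3],
                    gap_type=GapType(f[4]),
                    gap_class=GapClass(f[5]),
                )
            )
    return out
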