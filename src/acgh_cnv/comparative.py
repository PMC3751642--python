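"""Overlap of external (e.g. inter-specific) CNV sets with a CNVR catalog.

Used to ask what fraction of CNVs found between bird species (turkey/
chicken, duck/chicken, zebra finch/chicken cross-species CGH) fall into
regions that are copy-number variable within chicken.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .regions import CnvRegion

__all__ = ["ExternalCnvSet", "OverlapResult", "overlap_fraction"]


@dataclass
class ExternalCnvSet:
    """A labelled list of external CNV intervals (1-based inclusive)."""

    label: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"external set {self.label!r} is empty")
        for chrom, start, end in self.intervals:
            if end < start:
                raise ValueError(f"{self.label}: reversed interval {chrom}:{start}-{end}")


@dataclass
class OverlapResult:
    label: str
    n_overlapping: int
    n_total: int
    fraction: float
    excluded_chromosomes: list[str] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def percent(self) -> float:
        return round(100.0 * self.fraction, 1)


def _canonical_chrom(name: str, aliases: dict[str, str] | None = None) -> str:
    """Strip chr/GGA-style prefixes and apply a user alias table."""
    key = str(name).strip()
    if aliases:
        lowered = {k.lower(): v for k, v in aliases.items()}
        if key.lower() in lowered:
            return lowered[key.lower()]
    return re.sub(r"^(chr(omosome)?|GGA)", "", key, flags=re.IGNORECASE).upper()


def overlap_fraction(
    external: ExternalCnvSet,
    regions: list[CnvRegion],
    min_overlap_bp: int = 1,
    aliases: dict[str, str] | None = None,
    genome_chromosomes: list[str] | None = None,
) -> OverlapResult:
    """Fraction of external intervals overlapping any CNVR.

    An interval counts when some region overlaps it by at least
    ``min_overlap_bp``.  When ``genome_chromosomes`` is given (the
    chromosomes the array was designed against), intervals on chromosomes
    outside that set are excluded from the denominator and reported in
    ``excluded_chromosomes`` — e.g. a chromosome never used for probe
    design cannot be assessed.  A chromosome that was probed but has no
    CNVR simply contributes misses.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(_canonical_chrom(r.chrom, aliases), IntervalTree()).addi(
            r.start, r.end + 1
        )
    resolvable: set[str] | None = None
    if genome_chromosomes is not None:
        resolvable = {_canonical_chrom(c, aliases) for c in genome_chromosomes}
    n_hit = 0
    n_used = 0
    excluded: list[str] = []
    n_excluded = 0
    for chrom, start, end in external.intervals:
        canon = _canonical_chrom(chrom, aliases)
        if resolvable is not None and canon not in resolvable:
            n_excluded += 1
            if canon not in excluded:
                excluded.append(canon)
            continue
        n_used += 1
        tree = trees.get(canon)
        hit = tree is not None and any(
            min(iv.end - 1, end) - max(iv.begin, start) + 1 >= min_overlap_bp
            for iv in tree.overlap(start, end + 1)
        )
        n_hit += int(hit)
    if n_used == 0:
        raise ValueError(
            f"external set {external.label!r}: no interval on a catalog chromosome"
        )
    return OverlapResult(
        label=external.label,
        n_overlapping=n_hit,
        n_total=n_used,
        fraction=n_hit / n_used,
        excluded_chromosomes=excluded,
        n_excluded=n_excluded,
    )
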