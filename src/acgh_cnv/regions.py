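"""CNV region (CNVR) aggregation, catalog statistics and gene annotation.

A CNVR is the transitive union of CNVs that overlap by at least 1 bp,
regardless of gain/loss class — the Redon-style population-catalog
construction.  Region extents clip to the member extremes (no extension to
probe boundaries), so all size statistics are conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .calling import UniqueCnv
from .genome import chrom_sort_key

__all__ = [
    "CnvRegion",
    "CatalogStats",
    "merge_to_cnvrs",
    "region_size_kb",
    "catalog_stats",
    "annotate_genes",
]


@dataclass
class CnvRegion:
    """Union of overlapping unique CNVs across samples."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    member_cnvs: list[str]
    region_type: str  # "gain" | "loss" | "both"
    occurrence_total: int
    occurrence_per_line: dict[str, int] = field(default_factory=dict)

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass
class CatalogStats:
    """Summary statistics of a CNV/CNVR catalog."""

    n_cnv: int
    n_cnvr: int
    mean_cnv_size_kb: float
    n_recurrent_cnv: int
    mean_recurrent_cnv_size_kb: float
    total_cnvr_coverage_bp: int
    pct_genome: float
    pct_loss: float
    largest_cnv_kb: float
    per_line_mean_calls: dict[str, float] = field(default_factory=dict)


def region_size_kb(start: int, end: int | None = None) -> float:
    """Interval size in kb at 0.1 kb precision, boundary convention.

    Accepts a region object or explicit 1-based inclusive printed
    coordinates; the size is ``(end - start) / 1000`` so that
    144,185,960-144,403,060 reads as 217.1 kb.
    """
    if end is None:
        region = start
        start, end = region.start, region.end  # type: ignore[union-attr]
    if end <= start:
        raise ValueError(f"reversed or empty interval: {start}-{end}")
    return round((end - start) / 1000.0, 1)


def merge_to_cnvrs(cnvs: list[UniqueCnv]) -> list[CnvRegion]:
    """Merge unique CNVs into non-overlapping CNVRs.

    Single sweep per chromosome over position-sorted CNVs: intervals
    overlapping the growing region by >= 1 bp (1-based inclusive, so a
    shared endpoint counts) extend it; class is ignored for extent, and a
    region containing both gains and losses gets type ``both``.  Region ids
    are assigned in genome order; occurrence sums member occurrences.
    """
    ordered = sorted(cnvs, key=lambda c: (chrom_sort_key(c.chrom), c.start, c.end))
    regions: list[CnvRegion] = []
    current: list[UniqueCnv] | None = None
    cur_end = 0

    def _flush(members: list[UniqueCnv]) -> None:
        classes = {m.cnv_class for m in members}
        per_line: dict[str, int] = {}
        for m in members:
            for line, n in m.occurrence_per_line.items():
                per_line[line] = per_line.get(line, 0) + n
        regions.append(
            CnvRegion(
                cnvr_id="",  # assigned after the sweep, in genome order
                chrom=members[0].chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                member_cnvs=[m.cnv_id for m in members],
                region_type=classes.pop() if len(classes) == 1 else "both",
                occurrence_total=sum(m.occurrence_total for m in members),
                occurrence_per_line=per_line,
            )
        )

    for cnv in ordered:
        if current is not None and cnv.chrom == current[0].chrom and cnv.start <= cur_end:
            current.append(cnv)
            cur_end = max(cur_end, cnv.end)
        else:
            if current is not None:
                _flush(current)
            current = [cnv]
            cur_end = cnv.end
    if current is not None:
        _flush(current)
    for i, region in enumerate(regions, start=1):
        region.cnvr_id = f"CNVR{i}"
    return regions


def catalog_stats(
    cnvs: list[UniqueCnv],
    regions: list[CnvRegion],
    genome_length_bp: int,
    calls_per_sample: dict[str, int] | None = None,
    sample_to_line: dict[str, str] | None = None,
) -> CatalogStats:
    """Catalog-level summary: counts, mean sizes, coverage, loss fraction.

    Mean sizes are over all unique CNVs and over recurrent CNVs (occurrence
    >= 2); coverage is the summed extent of the (already disjoint) CNVRs;
    ``pct_genome`` relates coverage to the genome length; ``pct_loss`` is
    the percentage of unique CNVs classed as losses.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    if not cnvs:
        warnings.warn("empty CNV catalog; all statistics are zero", stacklevel=2)
        return CatalogStats(0, 0, 0.0, 0, 0.0, 0, 0.0, 0.0, 0.0, {})
    sizes = [c.size_bp for c in cnvs]
    recurrent = [c for c in cnvs if c.occurrence_total >= 2]
    coverage = sum(r.size_bp for r in regions)
    per_line_mean: dict[str, float] = {}
    if calls_per_sample and sample_to_line:
        by_line: dict[str, list[int]] = {}
        for sample, n in calls_per_sample.items():
            by_line.setdefault(sample_to_line[sample], []).append(n)
        per_line_mean = {line: sum(v) / len(v) for line, v in sorted(by_line.items())}
    return CatalogStats(
        n_cnv=len(cnvs),
        n_cnvr=len(regions),
        mean_cnv_size_kb=round(sum(sizes) / len(sizes) / 1000.0, 1),
        n_recurrent_cnv=len(recurrent),
        mean_recurrent_cnv_size_kb=(
            round(sum(c.size_bp for c in recurrent) / len(recurrent) / 1000.0, 1)
            if recurrent
            else 0.0
        ),
        total_cnvr_coverage_bp=int(coverage),
        pct_genome=round(100.0 * coverage / genome_length_bp, 2),
        pct_loss=round(100.0 * sum(c.cnv_class == "loss" for c in cnvs) / len(cnvs), 1),
        largest_cnv_kb=round(max(sizes) / 1000.0, 1),
        per_line_mean_calls=per_line_mean,
    )


def annotate_genes(
    regions: list[CnvRegion],
    genes: list[tuple[str, int, int, str]],
) -> tuple[dict[str, list[str]], int]:
    """Assign genes to CNVRs by >= 1 bp (complete or partial) overlap.

    ``genes`` rows are ``(chrom, start, end, gene_id)`` in 1-based inclusive
    coordinates.  Returns a per-region gene-id list (region id -> sorted
    gene ids) and the number of unique genes hit across all regions — a
    gene straddling two regions counts once in the unique total.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, gene_id in genes:
        if end < start:
            raise ValueError(f"gene {gene_id!r} has reversed coordinates")
        # half-open tree interval [start, end+1) represents the inclusive span
        trees.setdefault(str(chrom), IntervalTree()).addi(start, end + 1, gene_id)
    per_region: dict[str, list[str]] = {}
    unique: set[str] = set()
    for region in regions:
        tree = trees.get(region.chrom)
        hits = sorted({iv.data for iv in tree.overlap(region.start, region.end + 1)}) if tree else []
        per_region[region.cnvr_id] = hits
        unique.update(hits)
    return per_region, len(unique)
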