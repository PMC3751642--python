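"""Genome specifications and probe maps.

All genomic coordinates in this package are 1-based and inclusive on both
ends, matching the convention of aCGH catalogues ("GGA1:144,185,960-
144,403,060").  The only place a different convention appears is BED export,
which uses the standard 0-based half-open columns (see :mod:`acgh_cnv.io`).
Printed interval sizes follow the boundary convention ``end - start`` so
that, e.g., 144,403,060 - 144,185,960 = 217,100 bp reads as 217.1 kb.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeSpec",
    "ProbeMap",
    "build_probe_map",
    "chicken_like_genome",
    "chrom_sort_key",
    "overlap_bp",
]

#: Length of a synthetic oligo probe in bp (60-mer design).
PROBE_LENGTH = 60

# Approximate chromosome lengths (bp) of a chicken-style karyotype:
# macrochromosomes 1-5, intermediate 6-10, microchromosomes 11-28 and 32,
# plus the Z and W sex chromosomes.  Stand-in values, used only to shape
# synthetic data; scale them down for desk-size simulations.
_CHICKEN_LIKE_LENGTHS: dict[str, int] = {
    "1": 201_000_000, "2": 155_000_000, "3": 114_000_000, "4": 94_000_000,
    "5": 62_000_000, "6": 37_000_000, "7": 38_000_000, "8": 31_000_000,
    "9": 26_000_000, "10": 23_000_000, "11": 22_000_000, "12": 20_000_000,
    "13": 18_000_000, "14": 16_000_000, "15": 13_000_000, "16": 430_000,
    "17": 11_000_000, "18": 11_000_000, "19": 10_000_000, "20": 14_000_000,
    "21": 7_000_000, "22": 4_000_000, "23": 6_000_000, "24": 6_400_000,
    "25": 2_000_000, "26": 5_000_000, "27": 4_800_000, "28": 4_500_000,
    "32": 780_000, "Z": 74_000_000, "W": 260_000,
}


def chrom_sort_key(name: str) -> tuple[int, int, str]:
    """Sort key placing numeric chromosomes first in numeric order, then
    lettered chromosomes (Z, W, ...) alphabetically."""
    stripped = re.sub(r"^(chr|GGA)", "", str(name), flags=re.IGNORECASE)
    if stripped.isdigit():
        return (0, int(stripped), "")
    return (1, 0, stripped.upper())


def overlap_bp(start1: int, end1: int, start2: int, end2: int) -> int:
    """Overlap in bp between two 1-based inclusive intervals (<= 0: disjoint)."""
    return min(end1, end2) - max(start1, start2) + 1


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered set of chromosomes with their lengths in bp."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in genome spec")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, name: str) -> int:
        for c, length in self.chromosomes:
            if c == name:
                return length
        raise KeyError(name)


def chicken_like_genome(scale: float = 1.0, chromosomes: list[str] | None = None) -> GenomeSpec:
    """A chicken-style stand-in genome (synthetic lengths, not an assembly).

    Parameters
    ----------
    scale
        Multiplier on every chromosome length; use e.g. ``0.05`` for a
        desk-size cohort that keeps the karyotype shape.
    chromosomes
        Subset of chromosome names to keep (default: all).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    names = chromosomes if chromosomes is not None else list(_CHICKEN_LIKE_LENGTHS)
    chroms = tuple(
        (name, max(int(round(_CHICKEN_LIKE_LENGTHS[name] * scale)), 10 * PROBE_LENGTH))
        for name in names
    )
    return GenomeSpec(chromosomes=chroms)


@dataclass
class ProbeMap:
    """Ordered genomic probe coordinates defining the measurement grid.

    Arrays are parallel: ``probe_ids[i]`` sits on ``chroms[i]`` at
    ``starts[i]..ends[i]`` (1-based inclusive).  Probes are sorted by
    chromosome (in the order given by the genome) then start, and never
    overlap within a chromosome.
    """

    probe_ids: np.ndarray
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    spacing_bp: int
    genome: GenomeSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if not (len(self.chroms) == len(self.starts) == len(self.ends) == n):
            raise ValueError("probe map columns have unequal lengths")
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        for chrom in dict.fromkeys(self.chroms):
            sel = self.chroms == chrom
            s, e = self.starts[sel], self.ends[sel]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] <= e[:-1]):
                raise ValueError(f"probes on chromosome {chrom!r} unsorted or overlapping")

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in map order."""
        out: dict[str, slice] = {}
        idx = 0
        for chrom in dict.fromkeys(self.chroms):
            n = int(np.sum(self.chroms == chrom))
            out[str(chrom)] = slice(idx, idx + n)
            idx += n
        return out

    def probes_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of probes overlapping ``chrom:start-end`` by >= 1 bp."""
        sel = (self.chroms == chrom) & (self.starts <= end) & (self.ends >= start)
        return np.flatnonzero(sel)

    def median_gap(self, chrom: str | None = None) -> float:
        """Median start-to-start distance between adjacent probes."""
        gaps: list[np.ndarray] = []
        for c, sl in self.chromosome_slices().items():
            if chrom is not None and c != chrom:
                continue
            s = self.starts[sl]
            if len(s) > 1:
                gaps.append(np.diff(s))
        if not gaps:
            return float("nan")
        return float(np.median(np.concatenate(gaps)))


def build_probe_map(
    genome: GenomeSpec,
    spacing_bp: int = 4000,
    jitter_fraction: float = 0.0,
    seed: int = 0,
) -> ProbeMap:
    """Tile every chromosome with probes at a target spacing.

    The first probe of each chromosome starts at position 1; successive
    probe starts advance by ``spacing_bp`` perturbed uniformly by
    ``+/- jitter_fraction * spacing_bp``.  The default 4 kb spacing mirrors
    a 244K-style whole-genome CGH design.  Deterministic given ``seed``.
    """
    if not genome.chromosomes:
        raise ValueError("empty genome")
    if spacing_bp <= 0:
        raise ValueError("spacing_bp must be positive")
    if not 0 <= jitter_fraction < 0.5:
        raise ValueError("jitter_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    chroms: list[str] = []
    starts: list[int] = []
    k = 0
    for chrom, length in genome.chromosomes:
        pos = 1
        while pos + PROBE_LENGTH - 1 <= length:
            k += 1
            ids.append(f"P{k:07d}")
            chroms.append(chrom)
            starts.append(pos)
            gap = spacing_bp
            if jitter_fraction > 0:
                gap = int(round(spacing_bp * (1.0 + rng.uniform(-jitter_fraction, jitter_fraction))))
            pos += max(gap, PROBE_LENGTH + 1)
    starts_arr = np.asarray(starts, dtype=np.int64)
    return ProbeMap(
        probe_ids=np.asarray(ids, dtype=object),
        chroms=np.asarray(chroms, dtype=object),
        starts=starts_arr,
        ends=starts_arr + PROBE_LENGTH - 1,
        spacing_bp=spacing_bp,
        genome=genome,
    )
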