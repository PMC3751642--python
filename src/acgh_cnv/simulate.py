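"""Synthetic aCGH cohorts with known, implanted copy-number variants.

The generator emulates the measurement model of a two-color whole-genome
CGH experiment against a common diploid reference animal:

* a probe grid with ~4 kb median spacing (:func:`acgh_cnv.genome.build_probe_map`);
* per-probe log2(test/reference) ratios centered at 0 for copy number 2,
  shifted by ``log2(cn / 2)`` inside an implanted CNV;
* i.i.d. Gaussian per-probe noise at a per-array SD, optionally with an
  AR(1) "wave" component and a smooth dye-bias trend in a per-probe
  mean-signal covariate;
* a multi-line population in which some CNVs are fixed within a line,
  some segregate within a line, and some are private to one animal;
* self-self replicate arrays (reference vs reference) that carry no CNV
  and are used to calibrate calling thresholds.

Every function is deterministic given its ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeSpec, ProbeMap, overlap_bp
from .profiles import ArrayProfile

__all__ = [
    "CnvTemplate",
    "TruthCnv",
    "LineSpec",
    "expected_log2",
    "random_cnv_templates",
    "simulate_cohort",
    "simulate_self_self",
]

#: log2 ratio reported for homozygous deletions (arrays saturate; avoids -inf).
LOG2_FLOOR = -4.0


def expected_log2(copy_number: int, reference_copies: int = 2, floor: float = LOG2_FLOOR) -> float:
    """Expected log2 ratio for a locus at ``copy_number`` copies.

    ``log2(copy_number / reference_copies)``; a copy number of 0 returns
    ``floor`` instead of -inf, mimicking array saturation.
    """
    if copy_number < 0:
        raise ValueError("copy_number must be >= 0")
    if reference_copies < 1:
        raise ValueError("reference_copies must be >= 1")
    if copy_number == 0:
        return float(floor)
    return math.log2(copy_number / reference_copies)


@dataclass(frozen=True)
class CnvTemplate:
    """A CNV locus not yet tied to a sample (used for line-fixed variants)."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("CNV template requires start < end")
        if self.copy_number < 0 or self.copy_number == 2:
            raise ValueError("copy_number must be a non-negative integer != 2")


@dataclass(frozen=True)
class TruthCnv:
    """Ground-truth implanted CNV in one sample (reference diploid = 2)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("truth CNV requires start < end")
        if self.copy_number < 0 or self.copy_number == 2:
            raise ValueError("copy_number must be a non-negative integer != 2")

    @property
    def is_loss(self) -> bool:
        return self.copy_number < 2


@dataclass
class LineSpec:
    """Population structure of one line/breed in a simulated cohort.

    ``fixed_cnvs`` are carried by every sample of the line; ``shared_cnv_rate``
    is the per-sample carrier probability at each of the line's segregating
    loci; ``private_cnv_rate`` the per-candidate probability of an animal-
    private CNV.  ``noise_sd`` is the per-probe technical SD in log2 units.
    """

    line_id: str
    n_samples: int
    fixed_cnvs: list[CnvTemplate] = field(default_factory=list)
    shared_cnv_rate: float = 0.0
    private_cnv_rate: float = 0.0
    noise_sd: float = 0.1
    n_shared_loci: int = 6
    n_private_candidates: int = 5

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for rate in (self.shared_cnv_rate, self.private_cnv_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _check_template_in_genome(t: CnvTemplate, genome: GenomeSpec | None) -> None:
    if genome is None:
        return
    try:
        length = genome.length_of(t.chrom)
    except KeyError:
        raise ValueError(f"CNV template chromosome {t.chrom!r} not in probe map genome") from None
    if t.end > length:
        raise ValueError(f"CNV template {t.chrom}:{t.start}-{t.end} exceeds chromosome length {length}")


def _random_locus(
    rng: np.random.Generator,
    genome: GenomeSpec,
    size_range: tuple[int, int],
    loss_fraction: float,
) -> CnvTemplate:
    """Draw a random CNV locus: chromosome weighted by length, log-uniform size,
    loss-biased copy number (losses mostly 1 copy, gains mostly 3)."""
    names = genome.names
    lengths = np.array([genome.length_of(c) for c in names], dtype=float)
    chrom = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
    chrom_len = genome.length_of(chrom)
    lo, hi = size_range
    size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    size = min(size, max(chrom_len - 2, lo))
    start = int(rng.integers(1, max(chrom_len - size, 2)))
    if rng.random() < loss_fraction:
        cn = 1 if rng.random() < 0.9 else 0
    else:
        cn = 3 if rng.random() < 0.7 else 4
    return CnvTemplate(chrom=chrom, start=start, end=start + size, copy_number=cn)


def _conflicts(t: CnvTemplate, carried: list[CnvTemplate]) -> bool:
    return any(
        c.chrom == t.chrom and overlap_bp(c.start, c.end, t.start, t.end) > 0 for c in carried
    )


def random_cnv_templates(
    genome: GenomeSpec,
    n: int,
    seed: int = 0,
    size_range_bp: tuple[int, int] = (12_000, 200_000),
    loss_fraction: float = 0.75,
    avoid: list[CnvTemplate] | tuple[CnvTemplate, ...] = (),
) -> list[CnvTemplate]:
    """Draw ``n`` mutually non-overlapping random CNV loci.

    Loci also avoid everything in ``avoid`` — used to keep different lines'
    fixed CNVs at distinct positions when composing a cohort scenario.
    """
    rng = np.random.default_rng(seed)
    out: list[CnvTemplate] = []
    attempts = 0
    while len(out) < n:
        cand = _random_locus(rng, genome, size_range_bp, loss_fraction)
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError("could not place non-overlapping CNV templates; genome too small")
        if not _conflicts(cand, list(avoid) + out):
            out.append(cand)
    return out


_SEX_COPIES = {"F": {"Z": 1, "W": 1}, "M": {"Z": 2, "W": 0}}


def _sex_chromosome_shift(chrom: str, sample_sex: str, reference_sex: str) -> float:
    """Whole-chromosome dosage shift on Z/W for a sex-mismatched reference."""
    if reference_sex == "matched" or chrom not in ("Z", "W"):
        return 0.0
    sample_cn = _SEX_COPIES[sample_sex][chrom]
    ref_cn = _SEX_COPIES[reference_sex][chrom]
    if ref_cn == 0:
        # reference lacks the chromosome entirely; signal saturates high
        return -LOG2_FLOOR if sample_cn > 0 else 0.0
    return expected_log2(sample_cn, ref_cn)


def simulate_cohort(
    probe_map: ProbeMap,
    lines: list[LineSpec],
    seed: int = 0,
    *,
    size_range_bp: tuple[int, int] = (12_000, 200_000),
    loss_fraction: float = 0.75,
    dye_bias_amplitude: float = 0.0,
    wave_sd: float = 0.0,
    wave_rho: float = 0.98,
    reference_sex: str = "matched",
) -> tuple[list[ArrayProfile], list[TruthCnv]]:
    """Simulate a multi-line cohort of aCGH profiles with a truth table.

    Per sample, the implanted CNVs are its line's fixed templates, a random
    subset of the line's segregating loci (carrier probability
    ``shared_cnv_rate``), and freshly drawn private CNVs.  Probes whose
    interval overlaps a carried CNV are shifted by
    :func:`expected_log2` of its copy number; every other probe is centered
    at 0.  Noise is i.i.d. Gaussian at the line's ``noise_sd``, optionally
    plus an AR(1) wave (``wave_sd`` > 0) and a smooth dye-bias trend in the
    returned covariate (``dye_bias_amplitude`` > 0).

    Returns the profiles and the ground-truth CNV table (one row per sample
    per carried CNV, including CNVs too small to cover any probe).
    """
    if not lines:
        raise ValueError("at least one line is required")
    if reference_sex not in ("matched", "F", "M"):
        raise ValueError("reference_sex must be 'matched', 'F' or 'M'")
    genome = probe_map.genome
    rng = np.random.default_rng(seed)
    profiles: list[ArrayProfile] = []
    truth: list[TruthCnv] = []

    for line in lines:
        for t in line.fixed_cnvs:
            _check_template_in_genome(t, genome)
        # overlapping fixed templates with conflicting copy numbers are a
        # specification error, not something to silently resolve
        for i, a in enumerate(line.fixed_cnvs):
            for b in line.fixed_cnvs[i + 1 :]:
                if (
                    a.chrom == b.chrom
                    and overlap_bp(a.start, a.end, b.start, b.end) > 0
                    and a.copy_number != b.copy_number
                ):
                    raise ValueError(
                        f"line {line.line_id!r}: overlapping fixed CNVs with "
                        f"conflicting copy numbers ({a} vs {b})"
                    )
        shared_pool: list[CnvTemplate] = []
        if line.shared_cnv_rate > 0 and genome is not None:
            while len(shared_pool) < line.n_shared_loci:
                cand = _random_locus(rng, genome, size_range_bp, loss_fraction)
                if not _conflicts(cand, line.fixed_cnvs + shared_pool):
                    shared_pool.append(cand)
        for s in range(line.n_samples):
            sample_id = f"{line.line_id}_s{s + 1:02d}"
            sex = "F" if s % 2 == 0 else "M"
            carried = list(line.fixed_cnvs)
            for locus in shared_pool:
                if rng.random() < line.shared_cnv_rate:
                    carried.append(locus)
            if line.private_cnv_rate > 0 and genome is not None:
                n_private = rng.binomial(line.n_private_candidates, line.private_cnv_rate)
                for _ in range(int(n_private)):
                    cand = _random_locus(rng, genome, size_range_bp, loss_fraction)
                    if not _conflicts(cand, carried):
                        carried.append(cand)

            values = np.zeros(probe_map.n_probes)
            for cnv in carried:
                idx = probe_map.probes_in(cnv.chrom, cnv.start, cnv.end)
                values[idx] = expected_log2(cnv.copy_number)
                truth.append(
                    TruthCnv(
                        sample_id=sample_id,
                        chrom=cnv.chrom,
                        start=cnv.start,
                        end=cnv.end,
                        copy_number=cnv.copy_number,
                    )
                )
            if reference_sex != "matched":
                for chrom, sl in probe_map.chromosome_slices().items():
                    shift = _sex_chromosome_shift(chrom, sex, reference_sex)
                    if shift != 0.0:
                        values[sl] += shift
            covariate = rng.normal(size=probe_map.n_probes)
            if dye_bias_amplitude != 0.0:
                bias = covariate**2
                values += dye_bias_amplitude * (bias - bias.mean())
            if line.noise_sd > 0:
                values += rng.normal(0.0, line.noise_sd, size=probe_map.n_probes)
            if wave_sd > 0:
                values += _ar1_wave(rng, probe_map.n_probes, wave_sd, wave_rho)
            profiles.append(
                ArrayProfile(
                    sample_id=sample_id,
                    line_id=line.line_id,
                    values=values,
                    covariate=covariate,
                    sex=sex,
                )
            )
    return profiles, truth


def _ar1_wave(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd`` ("genomic waves")."""
    innov_sd = sd * math.sqrt(1 - rho**2)
    w = np.empty(n)
    w[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        w[i] = rho * w[i - 1] + eps[i - 1]
    return w


def simulate_self_self(
    probe_map: ProbeMap,
    noise_sd: float,
    n_arrays: int,
    seed: int = 0,
    *,
    wave_sd: float = 0.0,
    wave_rho: float = 0.98,
) -> list[ArrayProfile]:
    """Replicate self-self control hybridizations: pure noise around 0.

    The reference DNA is labeled with both dyes, so no probe carries a
    copy-number difference; the resulting profiles measure technical noise
    only and calibrate the calling threshold.
    """
    if n_arrays < 1:
        raise ValueError("n_arrays must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[ArrayProfile] = []
    for i in range(n_arrays):
        values = (
            rng.normal(0.0, noise_sd, size=probe_map.n_probes)
            if noise_sd > 0
            else np.zeros(probe_map.n_probes)
        )
        if wave_sd > 0:
            values = values + _ar1_wave(rng, probe_map.n_probes, wave_sd, wave_rho)
        out.append(
            ArrayProfile(
                sample_id=f"selfself_{i + 1:02d}",
                line_id="self_self",
                values=values,
                covariate=rng.normal(size=probe_map.n_probes),
            )
        )
    return out
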