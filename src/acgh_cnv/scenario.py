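"""Ready-made cohort scenarios.

The default scenario mirrors the shape of a 15-line chicken resource
population of 64 animals: four Red Jungle Fowl, several 5-animal
experimental layer lines, small commercial broiler/layer groups, and three
Silkies, each line carrying line-fixed CNVs, segregating within-line CNVs
and animal-private CNVs.  Line ids follow common breed-code style.
"""

from __future__ import annotations

from .genome import GenomeSpec, ProbeMap, build_probe_map, chicken_like_genome
from .profiles import ArrayProfile
from .simulate import (
    CnvTemplate,
    LineSpec,
    TruthCnv,
    random_cnv_templates,
    simulate_cohort,
    simulate_self_self,
)

__all__ = ["TABLE1_LINE_SIZES", "default_lines", "default_cohort"]

#: Line id -> number of sampled animals (64 total over 15 lines).
TABLE1_LINE_SIZES: dict[str, int] = {
    "aviandiv_101": 4,
    "LineBrL": 5,
    "Line6_1": 5,
    "Line6_3": 5,
    "LineN": 5,
    "Line15I_5": 5,
    "Line7_2": 5,
    "ComBroilA": 2,
    "ComBroilB": 3,
    "ComBroilC": 4,
    "BroilM": 8,
    "ComBrownL1": 4,
    "ComBrownL2": 4,
    "ComWhiteL": 2,
    "Silkie": 3,
}


def default_lines(
    genome: GenomeSpec,
    seed: int = 0,
    noise_sd: float = 0.10,
    n_fixed_per_line: int = 2,
    shared_cnv_rate: float = 0.5,
    private_cnv_rate: float = 0.3,
    size_range_bp: tuple[int, int] = (12_000, 200_000),
    loss_fraction: float = 0.75,
) -> list[LineSpec]:
    """Build the 15-line specs with disjoint line-fixed CNV loci.

    Fixed loci are drawn at distinct genomic positions across lines so
    every line has a recognizable CNV signature (what makes line-level
    clustering and line-specific classification meaningful).
    """
    avoid: list[CnvTemplate] = []
    lines: list[LineSpec] = []
    for i, (line_id, n_samples) in enumerate(TABLE1_LINE_SIZES.items()):
        fixed = random_cnv_templates(
            genome,
            n_fixed_per_line,
            seed=seed * 1000 + i,
            size_range_bp=size_range_bp,
            loss_fraction=loss_fraction,
            avoid=avoid,
        )
        avoid.extend(fixed)
        lines.append(
            LineSpec(
                line_id=line_id,
                n_samples=n_samples,
                fixed_cnvs=fixed,
                shared_cnv_rate=shared_cnv_rate,
                private_cnv_rate=private_cnv_rate,
                noise_sd=noise_sd,
            )
        )
    return lines


def default_cohort(
    seed: int = 0,
    genome_scale: float = 0.05,
    spacing_bp: int = 4000,
    jitter_fraction: float = 0.2,
    noise_sd: float = 0.10,
    n_self_self: int = 5,
    dye_bias_amplitude: float = 0.05,
    **line_kwargs,
) -> tuple[ProbeMap, list[ArrayProfile], list[TruthCnv], list[ArrayProfile]]:
    """Simulate the full default scenario.

    Returns ``(probe_map, cohort_profiles, truth, self_self_profiles)``.
    The default 0.05 genome scale keeps the karyotype shape (~52 Mb,
    ~13,000 probes at 4 kb spacing) at desk-size run times.
    """
    genome = chicken_like_genome(scale=genome_scale)
    probe_map = build_probe_map(
        genome, spacing_bp=spacing_bp, jitter_fraction=jitter_fraction, seed=seed
    )
    lines = default_lines(genome, seed=seed, noise_sd=noise_sd, **line_kwargs)
    profiles, truth = simulate_cohort(
        probe_map, lines, seed=seed + 1, dye_bias_amplitude=dye_bias_amplitude
    )
    self_self = simulate_self_self(probe_map, noise_sd=noise_sd, n_arrays=n_self_self, seed=seed + 2)
    return probe_map, profiles, truth, self_self
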