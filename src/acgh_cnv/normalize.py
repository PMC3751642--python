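"""Smooth dye-bias trend removal and centering of log2 profiles.

Two-color arrays show intensity-dependent dye biases; the standard remedy
is to fit a smooth curve of log2 ratio against a per-probe signal covariate
and subtract it, then median-center the residuals.  The fit is a robust
(iteratively reweighted) lowess, so that the minority of CNV-bearing probes
does not drag the trend.
"""

from __future__ import annotations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import ProbeMap
from .profiles import ArrayProfile

__all__ = ["fit_trend", "normalize_profile", "normalize_cohort"]

#: Chromosomes eligible for optional per-chromosome centering.
SEX_CHROMOSOMES = ("Z", "W")


def fit_trend(
    values: np.ndarray,
    covariate: np.ndarray,
    span: float = 0.3,
    robust_iterations: int = 3,
) -> np.ndarray:
    """Robust locally-weighted fit of ``values`` against ``covariate``.

    Returns the trend evaluated at every input point, preserving order.
    A (near-)constant covariate is degenerate for local regression; the
    trend then collapses to the median of the values.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.shape != covariate.shape:
        raise ValueError("values and covariate must have equal length")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    finite = np.isfinite(values) & np.isfinite(covariate)
    if not finite.any():
        raise ValueError("no finite (value, covariate) pairs to fit")
    cov_range = np.ptp(covariate[finite])
    if cov_range == 0:
        return np.full_like(values, float(np.median(values[finite])))
    trend = np.full_like(values, np.nan)
    # delta collapses near-duplicate x into linear interpolation, keeping
    # the fit near-linear-time on dense grids
    fitted = lowess(
        values[finite],
        covariate[finite],
        frac=span,
        it=robust_iterations,
        delta=0.01 * cov_range,
        return_sorted=False,
    )
    trend[finite] = fitted
    if not finite.all():
        trend[~finite] = float(np.median(values[finite]))
    return trend


def normalize_profile(
    profile: ArrayProfile,
    probe_map: ProbeMap | None = None,
    span: float = 0.3,
    per_chromosome_center: bool = False,
    max_nonfinite_fraction: float = 0.2,
) -> ArrayProfile:
    """Remove the covariate trend and median-center a profile.

    The trend (fit against ``profile.covariate``; probe index if absent) is
    subtracted, then the genome-wide median is set to 0.  With
    ``per_chromosome_center`` the Z and W chromosomes are additionally
    centered on their own medians, erasing whole-chromosome dosage offsets
    such as those from a sex-mismatched reference — deliberately restricted
    to the sex chromosomes so real whole-autosome signal is untouched.
    """
    values = np.asarray(profile.values, dtype=float)
    nonfinite = ~np.isfinite(values)
    if nonfinite.mean() > max_nonfinite_fraction:
        raise ValueError(
            f"profile {profile.sample_id!r}: {nonfinite.mean():.0%} non-finite values "
            f"exceeds the {max_nonfinite_fraction:.0%} limit"
        )
    covariate = (
        profile.covariate
        if profile.covariate is not None
        else np.arange(len(values), dtype=float)
    )
    trend = fit_trend(values, covariate, span=span)
    out = values - trend
    out = out - np.nanmedian(out)
    if per_chromosome_center:
        if probe_map is None:
            raise ValueError("per_chromosome_center requires a probe map")
        for chrom, sl in probe_map.chromosome_slices().items():
            if chrom in SEX_CHROMOSOMES:
                chunk = out[sl]
                finite = np.isfinite(chunk)
                if finite.any():
                    out[sl] = chunk - np.median(chunk[finite])
    return profile.copy_with(out, normalized=True)


def normalize_cohort(
    profiles: list[ArrayProfile],
    probe_map: ProbeMap | None = None,
    span: float = 0.3,
    per_chromosome_center: bool = False,
) -> list[ArrayProfile]:
    """Normalize every profile of a cohort with shared settings."""
    return [
        normalize_profile(
            p, probe_map=probe_map, span=span, per_chromosome_center=per_chromosome_center
        )
        for p in profiles
    ]
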