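"""Relative copy-number quantification from qPCR threshold cycles.

Two pieces of arithmetic, exactly as used for TaqMan CNV validation:

* reference-gene normalization of Ct values against a single-copy gene
  (ovotransferrin in chicken), interpolating on the standard curves:
  ``Ct + (Nt' - Ct') * S / S'`` where ``Nt'`` is the cohort-mean
  reference-gene Ct, ``Ct'`` the sample's reference-gene Ct, and S, S' the
  standard-curve slopes of target and reference assays;
* the standard ddCt method against a calibrator sample of known diploid
  copy number: ``ratio = 2^-ddCt``, ``copies = 2 * ratio``.

Perfect amplification efficiency (doubling per cycle) is assumed for the
ddCt step; slope-based efficiency correction enters only through the
normalization formula.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "QpcrRecord",
    "StandardCurve",
    "normalize_ct",
    "relative_copy_ratio",
    "CopyRatio",
    "classify_concordance",
    "simulate_ct",
]


@dataclass(frozen=True)
class QpcrRecord:
    """Mean Ct measurements for one sample on one assay.

    Replicate wells are averaged to a mean Ct before entering ratios.
    """

    sample_id: str
    assay_id: str
    ct_target: float
    ct_refgene: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_refgene", self.ct_refgene)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be positive and finite, got {ct}")


@dataclass(frozen=True)
class StandardCurve:
    """Standard-plot slopes and reference-gene Ct summary for one assay.

    ``slope_target`` (S) and ``slope_refgene`` (S') are the regression
    slopes of Ct against log input amount; ``mean_refgene_ct`` (Nt') the
    mean reference-gene Ct over all samples; ``sample_refgene_ct`` (Ct')
    the focal sample's reference-gene Ct.
    """

    slope_target: float
    slope_refgene: float
    mean_refgene_ct: float
    sample_refgene_ct: float

    def __post_init__(self) -> None:
        if self.slope_refgene == 0:
            raise ValueError("reference-gene slope S' must be nonzero")


def normalize_ct(ct: float, curve: StandardCurve) -> float:
    """Reference-gene-normalized Ct: ``ct + (Nt' - Ct') * S / S'``.

    Interpolates on the standard plots to the target Ct that would have
    been observed had the sample contained the cohort-mean amount of
    reference-gene DNA.  A zero target slope means the assay is insensitive
    to input amount; the Ct is returned unchanged with a warning.
    """
    if curve.slope_target == 0:
        warnings.warn("target standard-curve slope is 0; no normalization applied", stacklevel=2)
        return float(ct)
    return float(
        ct
        + (curve.mean_refgene_ct - curve.sample_refgene_ct)
        * curve.slope_target
        / curve.slope_refgene
    )


@dataclass(frozen=True)
class CopyRatio:
    """ddCt result: fold ratio vs the calibrator and derived copy number."""

    ddct: float
    ratio: float
    copies: float  # unrounded, = 2 * ratio
    copies_rounded: int


def relative_copy_ratio(test: QpcrRecord, reference: QpcrRecord) -> CopyRatio:
    """ddCt copy ratio of a test sample against the calibrator sample.

    ``ddCt = (Ct_target - Ct_refgene)_test - (Ct_target - Ct_refgene)_ref``;
    ``ratio = 2^-ddCt`` is the fold change vs the calibrator, whose genome
    is taken as diploid, so ``copies = 2 * ratio``.
    """
    if test.assay_id != reference.assay_id:
        raise ValueError(
            f"assay mismatch: {test.assay_id!r} vs {reference.assay_id!r}"
        )
    ddct = (test.ct_target - test.ct_refgene) - (reference.ct_target - reference.ct_refgene)
    ratio = 2.0 ** (-ddct)
    copies = 2.0 * ratio
    return CopyRatio(ddct=ddct, ratio=ratio, copies=copies, copies_rounded=round(copies))


def classify_concordance(qpcr_copies: int, called_class: str) -> str:
    """Concordance of a qPCR copy number with an array call.

    gain is confirmed by > 2 copies, loss by < 2, and an uncalled locus
    ('none') by exactly 2.
    """
    if qpcr_copies < 0:
        raise ValueError("copies must be >= 0")
    if called_class not in ("gain", "loss", "none"):
        raise ValueError("called_class must be 'gain', 'loss' or 'none'")
    expected = "gain" if qpcr_copies > 2 else ("loss" if qpcr_copies < 2 else "none")
    return "concordant" if expected == called_class else "discordant"


def simulate_ct(
    copies: int,
    baseline_ct: float = 30.0,
    input_log2_amount: float = 0.0,
) -> float:
    """Ideal Ct for a locus at ``copies`` copies, perfect efficiency.

    One extra template doubling removes one cycle:
    ``Ct = baseline - log2(copies) - input``.  Used to generate synthetic
    validation panels; ``copies`` must be >= 1 (a 0-copy locus never
    amplifies).
    """
    if copies < 1:
        raise ValueError("copies must be >= 1 for a finite Ct")
    return float(baseline_ct - math.log2(copies) - input_log2_amount)
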