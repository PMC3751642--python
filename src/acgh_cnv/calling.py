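"""Threshold-based CNV calling calibrated on self-self replicate arrays.

The caller follows the classic ratio-threshold design: estimate each
array's technical noise robustly, express gain/loss thresholds as a
multiple *t* of that noise, and choose *t* empirically as the smallest
grid value whose false-call rate on replicate self-self hybridizations
(arrays with no true CNV) does not exceed a target.  Segments are maximal
same-sign runs of supra-threshold probes, with short sub-threshold
dropouts bridged and short runs discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import ProbeMap
from .profiles import ArrayProfile

__all__ = [
    "NoiseCalibration",
    "CnvCall",
    "UniqueCnv",
    "estimate_noise",
    "calibrate_threshold",
    "call_segments",
    "collate_calls",
]

#: 75th-percentile of the standard normal; MAD -> SD conversion factor.
_MAD_TO_SD = 0.6745

DEFAULT_GRID = tuple(np.arange(2.0, 6.01, 0.5))


def estimate_noise(profile: ArrayProfile | np.ndarray) -> float:
    """Robust per-array noise SD from successive probe differences.

    ``median(|v[i+1] - v[i]|) / (0.6745 * sqrt(2))``: differencing cancels
    regional copy-number shifts (a CNV boundary perturbs only one
    difference), and the scaled median absolute difference estimates the
    per-probe SD with a high breakdown point.  A constant profile yields 0.
    """
    values = profile.values if isinstance(profile, ArrayProfile) else np.asarray(profile, float)
    values = values[np.isfinite(values)]
    if len(values) < 10:
        raise ValueError("need at least 10 probes to estimate noise")
    diffs = np.abs(np.diff(values))
    return float(np.median(diffs) / (_MAD_TO_SD * np.sqrt(2.0)))


@dataclass
class NoiseCalibration:
    """Calling parameters: threshold multiple plus run-shape constraints.

    ``sd_e`` records the mean self-self noise at calibration time for
    logging; :func:`call_segments` always re-estimates noise per array.
    """

    sd_e: float
    threshold_multiple: float
    min_probes: int = 2
    max_gap_probes: int = 1
    target_false_calls_per_array: float = 1.0
    mean_self_self_calls: float = float("nan")
    warning: bool = False

    def __post_init__(self) -> None:
        if self.sd_e < 0:
            raise ValueError("sd_e must be >= 0")
        if self.threshold_multiple <= 0:
            raise ValueError("threshold_multiple must be > 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass(frozen=True)
class CnvCall:
    """A contiguous gain or loss segment in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_class: str  # "gain" | "loss"
    n_probes: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("call requires start < end")
        if self.cnv_class not in ("gain", "loss"):
            raise ValueError("cnv_class must be 'gain' or 'loss'")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass
class UniqueCnv:
    """A CNV deduplicated by exact coordinates and class across samples."""

    cnv_id: str
    chrom: str
    start: int
    end: int
    cnv_class: str
    occurrence_total: int
    occurrence_per_line: dict[str, int] = field(default_factory=dict)
    carrier_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.occurrence_total < 1:
            raise ValueError("occurrence_total must be >= 1")
        if self.occurrence_total != sum(self.occurrence_per_line.values()):
            raise ValueError("occurrence_total inconsistent with per-line counts")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def _runs_above_threshold(
    sign_ok: np.ndarray, max_gap_probes: int, blocked: np.ndarray | None = None
) -> list[tuple[int, int]]:
    """Maximal runs of True, bridging gaps of <= max_gap_probes False probes.

    Returns (first_index, last_index) pairs; bridged gap probes are counted
    inside the run's extent but a run must start and end on a True probe.
    Gaps are only bridged across sub-threshold probes: a ``blocked`` probe
    (supra-threshold in the opposite direction) always splits the run.
    """
    idx = np.flatnonzero(sign_ok)
    if len(idx) == 0:
        return []
    runs: list[tuple[int, int]] = []
    run_start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        gap_clear = blocked is None or not blocked[prev + 1 : i].any()
        if i - prev - 1 <= max_gap_probes and gap_clear:
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
    runs.append((run_start, prev))
    return runs


def call_segments(
    profile: ArrayProfile,
    probe_map: ProbeMap,
    calibration: NoiseCalibration,
) -> list[CnvCall]:
    """Call gain/loss segments in one (normalized) profile.

    Per chromosome, probes with log2 above ``+t*sd_e`` (below ``-t*sd_e``)
    form candidate gain (loss) runs; same-sign runs separated by at most
    ``max_gap_probes`` sub-threshold probes are merged; runs covering fewer
    than ``min_probes`` probes are discarded.  A call spans from its first
    probe's start to its last probe's end.  ``sd_e`` is re-estimated from
    this profile, so thresholds track per-array noise.  If the profile is
    constant (sd_e = 0) the threshold degenerates to 0 and every run of
    nonzero probes is called.
    """
    values = np.asarray(profile.values, dtype=float)
    if len(values) != probe_map.n_probes:
        raise ValueError("profile length does not match probe map")
    sd_e = estimate_noise(profile)
    thr = calibration.threshold_multiple * sd_e
    calls: list[CnvCall] = []
    for chrom, sl in probe_map.chromosome_slices().items():
        v = values[sl]
        starts = probe_map.starts[sl]
        ends = probe_map.ends[sl]
        finite = np.isfinite(v)
        gain_mask = (v > thr) & finite
        loss_mask = (v < -thr) & finite
        for cnv_class, mask, opposite in (
            ("gain", gain_mask, loss_mask),
            ("loss", loss_mask, gain_mask),
        ):
            for first, last in _runs_above_threshold(mask, calibration.max_gap_probes, opposite):
                member = np.flatnonzero(mask[first : last + 1]) + first
                if len(member) < calibration.min_probes:
                    continue
                calls.append(
                    CnvCall(
                        sample_id=profile.sample_id,
                        chrom=str(chrom),
                        start=int(starts[first]),
                        end=int(ends[last]),
                        cnv_class=cnv_class,
                        n_probes=int(last - first + 1),
                        mean_log2=float(np.nanmean(v[first : last + 1])),
                    )
                )
    calls.sort(key=lambda c: (list(probe_map.chromosome_slices()).index(c.chrom), c.start))
    return calls


def calibrate_threshold(
    self_self: list[ArrayProfile],
    probe_map: ProbeMap,
    grid: tuple[float, ...] | list[float] = DEFAULT_GRID,
    min_probes: int = 2,
    max_gap_probes: int = 1,
    target_false_calls_per_array: float = 1.0,
) -> NoiseCalibration:
    """Choose the smallest threshold multiple meeting a self-self call budget.

    Every self-self array is called at each grid multiple (ascending); the
    selected multiple is the smallest whose mean call count over the
    replicate arrays is at most ``target_false_calls_per_array``.  Because
    self-self arrays contain no true CNV, every call on them is a false
    call, making this an empirical false-positive calibration.  If no grid
    value meets the target, the largest is returned with ``warning=True``.
    """
    if len(self_self) < 2:
        raise ValueError("need at least 2 self-self arrays to calibrate")
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("threshold grid must not be empty")
    if any(g <= 0 for g in grid):
        raise ValueError("threshold multiples must be positive")
    sds = [estimate_noise(p) for p in self_self]
    mean_calls_at: dict[float, float] = {}
    for t in grid:
        cal = NoiseCalibration(
            sd_e=float(np.mean(sds)),
            threshold_multiple=t,
            min_probes=min_probes,
            max_gap_probes=max_gap_probes,
            target_false_calls_per_array=target_false_calls_per_array,
        )
        n_calls = [len(call_segments(p, probe_map, cal)) for p in self_self]
        mean_calls_at[t] = float(np.mean(n_calls))
        if mean_calls_at[t] <= target_false_calls_per_array:
            cal.mean_self_self_calls = mean_calls_at[t]
            return cal
    warnings.warn(
        "no grid multiple met the self-self false-call target; "
        f"returning the largest ({grid[-1]})",
        stacklevel=2,
    )
    return NoiseCalibration(
        sd_e=float(np.mean(sds)),
        threshold_multiple=grid[-1],
        min_probes=min_probes,
        max_gap_probes=max_gap_probes,
        target_false_calls_per_array=target_false_calls_per_array,
        mean_self_self_calls=mean_calls_at[grid[-1]],
        warning=True,
    )


def collate_calls(
    calls: list[CnvCall],
    sample_to_line: dict[str, str],
) -> list[UniqueCnv]:
    """Deduplicate calls by exact (chromosome, start, end, class).

    Two calls are the same CNV only when all four coordinates agree; the
    same interval called gain in one sample and loss in another yields two
    records.  Occurrence is counted overall and per line.  Output is in
    genome order with ids ``CNV1..CNVn``.
    """
    from .genome import chrom_sort_key

    grouped: dict[tuple[str, int, int, str], list[CnvCall]] = {}
    for call in calls:
        if call.sample_id not in sample_to_line:
            raise KeyError(f"sample {call.sample_id!r} missing from line map")
        grouped.setdefault((call.chrom, call.start, call.end, call.cnv_class), []).append(call)
    keys = sorted(grouped, key=lambda k: (chrom_sort_key(k[0]), k[1], k[2], k[3]))
    out: list[UniqueCnv] = []
    for i, key in enumerate(keys, start=1):
        members = grouped[key]
        per_line: dict[str, int] = {}
        for call in members:
            line = sample_to_line[call.sample_id]
            per_line[line] = per_line.get(line, 0) + 1
        out.append(
            UniqueCnv(
                cnv_id=f"CNV{i}",
                chrom=key[0],
                start=key[1],
                end=key[2],
                cnv_class=key[3],
                occurrence_total=len(members),
                occurrence_per_line=per_line,
                carrier_samples=sorted(c.sample_id for c in members),
            )
        )
    return out
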