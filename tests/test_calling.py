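import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acgh_cnv import (
    GenomeSpec,
    NoiseCalibration,
    build_probe_map,
    calibrate_threshold,
    call_segments,
    collate_calls,
    estimate_noise,
    simulate_self_self,
)
from acgh_cnv.calling import CnvCall
from acgh_cnv.profiles import ArrayProfile


def _profile(values, sample_id="s1", line_id="L"):
    return ArrayProfile(sample_id, line_id, np.asarray(values, dtype=float))


@pytest.fixture(scope="module")
def big_map():
    genome = GenomeSpec((("1", 200_120_000),))
    return build_probe_map(genome, spacing_bp=4000, jitter_fraction=0.0)


class TestEstimateNoise:
    def test_zero_profile(self):
        assert estimate_noise(np.zeros(100)) == 0.0

    def test_gaussian_profile_matches_sample_sd(self, big_map):
        """Oracle: the plain sample SD of the same clean Gaussian draw."""
        (a,) = simulate_self_self(big_map, noise_sd=0.1, n_arrays=1, seed=3)
        est = estimate_noise(a)
        assert 0.097 <= est <= 0.103
        assert est == pytest.approx(float(np.std(a.values, ddof=1)), rel=0.03)

    def test_robust_to_cnv_contamination(self, big_map):
        """5% of probes shifted by -1 barely moves the estimate; oracle is
        a trimmed SD that excludes the shifted block."""
        (a,) = simulate_self_self(big_map, noise_sd=0.1, n_arrays=1, seed=3)
        values = a.values.copy()
        n_shift = int(0.05 * len(values))
        values[:n_shift] -= 1.0
        est = estimate_noise(values)
        assert abs(est - 0.1) <= 0.01
        trimmed_sd = float(np.std(values[n_shift:], ddof=1))
        assert est == pytest.approx(trimmed_sd, rel=0.05)

    def test_too_few_probes(self):
        with pytest.raises(ValueError):
            estimate_noise(np.zeros(5))


class TestCallSegments:
    def _cal(self, t=4.0, min_probes=2, max_gap=1):
        return NoiseCalibration(
            sd_e=0.1, threshold_multiple=t, min_probes=min_probes, max_gap_probes=max_gap
        )

    def test_all_zero_profile_gives_no_calls(self, small_map):
        assert call_segments(_profile(np.zeros(small_map.n_probes)), small_map, self._cal()) == []

    def test_single_loss_run_called_exactly(self, small_map, rng):
        values = rng.normal(0, 0.05, small_map.n_probes)
        values[20:30] = -1.0
        calls = call_segments(_profile(values), small_map, self._cal())
        losses = [c for c in calls if c.cnv_class == "loss"]
        assert len(losses) == 1
        c = losses[0]
        assert c.start == int(small_map.starts[20])
        assert c.end == int(small_map.ends[29])
        assert c.n_probes == 10
        assert c.mean_log2 < 0

    def test_noise_free_construction(self, small_map):
        values = np.zeros(small_map.n_probes)
        values[10:20] = -1.0
        calls = call_segments(_profile(values), small_map, self._cal())
        # sd_e = 0 is degenerate: threshold 0, every nonzero run called
        assert len(calls) == 1
        assert calls[0].cnv_class == "loss"
        assert calls[0].n_probes == 10

    def test_gap_of_one_subthreshold_probe_is_bridged(self, small_map, rng):
        values = rng.normal(0, 0.05, small_map.n_probes)
        values[40:50] = 1.0
        values[45] = 0.0  # dropout probe
        calls = [c for c in call_segments(_profile(values), small_map, self._cal())
                 if c.cnv_class == "gain"]
        assert len(calls) == 1
        assert calls[0].n_probes == 10

    def test_gap_larger_than_max_splits(self, small_map, rng):
        values = rng.normal(0, 0.05, small_map.n_probes)
        values[40:50] = 1.0
        values[44:46] = 0.0  # two dropout probes > max_gap_probes=1
        calls = [c for c in call_segments(_profile(values), small_map, self._cal())
                 if c.cnv_class == "gain"]
        assert len(calls) == 2

    def test_opposite_sign_probe_blocks_bridging(self, small_map, rng):
        values = rng.normal(0, 0.05, small_map.n_probes)
        values[40:50] = 1.0
        values[45] = -1.0  # supra-threshold loss probe inside the gain run
        calls = call_segments(_profile(values), small_map, self._cal())
        gains = [c for c in calls if c.cnv_class == "gain"]
        assert len(gains) == 2
        for a in calls:
            for b in calls:
                if a is not b:
                    assert a.end < b.start or b.end < a.start or a.chrom != b.chrom

    def test_runs_below_min_probes_are_dropped(self, small_map, rng):
        values = rng.normal(0, 0.05, small_map.n_probes)
        values[7] = -1.0  # isolated single probe
        calls = call_segments(_profile(values), small_map, self._cal(min_probes=2))
        assert all(not (c.start <= small_map.starts[7] <= c.end) for c in calls)

    def test_sub_spacing_cnv_not_callable(self, small_map):
        """A 3.2 kb variant on a 4 kb grid touches at most one probe, below
        the 2-probe minimum — structurally undetectable."""
        values = np.zeros(small_map.n_probes)
        for start in range(1000, 1_900_000, 37_777):
            idx = small_map.probes_in("1", start, start + 3200)
            assert len(idx) <= 1
            values[:] = 0.0
            values[idx] = -1.0
            assert call_segments(_profile(values), small_map, self._cal()) == []

    def test_calls_never_span_chromosomes(self, small_map):
        sl1 = small_map.chromosome_slices()["1"]
        sl2 = small_map.chromosome_slices()["2"]
        values = np.zeros(small_map.n_probes)
        values[sl1.stop - 5 : sl1.stop] = -1.0
        values[sl2.start : sl2.start + 5] = -1.0
        calls = call_segments(_profile(values), small_map, self._cal())
        assert {(c.chrom, c.n_probes) for c in calls} == {("1", 5), ("2", 5)}

    def test_no_overlapping_calls_per_sample(self, small_map, rng):
        values = rng.normal(0, 0.3, small_map.n_probes)  # heavy-noise stress
        calls = call_segments(_profile(values), small_map, self._cal(t=1.0))
        by_chrom: dict[str, list[CnvCall]] = {}
        for c in calls:
            by_chrom.setdefault(c.chrom, []).append(c)
        for group in by_chrom.values():
            group.sort(key=lambda c: c.start)
            for a, b in zip(group, group[1:]):
                assert a.end < b.start

    def test_gain_loss_labels_match_sign_at_zero_noise(self, small_map):
        values = np.zeros(small_map.n_probes)
        values[10:15] = 1.0
        values[30:35] = -1.0
        calls = call_segments(_profile(values), small_map, self._cal())
        assert [(c.cnv_class, c.mean_log2 > 0) for c in calls] == [
            ("gain", True),
            ("loss", False),
        ]

    def test_sensitivity_monotone_in_threshold(self, small_map, rng):
        values = rng.normal(0, 0.1, small_map.n_probes)
        for start in range(5, small_map.n_probes - 10, 40):
            values[start : start + 4] -= 1.0
        counts = [
            len(call_segments(_profile(values), small_map, self._cal(t=t)))
            for t in (2.0, 3.0, 4.0, 6.0, 9.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCalibrateThreshold:
    def test_zero_noise_selects_smallest_grid_value(self, small_map):
        arrays = simulate_self_self(small_map, noise_sd=0.0, n_arrays=3, seed=0)
        cal = calibrate_threshold(arrays, small_map, grid=[2.0, 3.0, 4.0])
        assert cal.threshold_multiple == 2.0
        assert cal.mean_self_self_calls == 0.0
        assert not cal.warning

    def test_selected_multiple_agrees_with_grid_brute_force(self, small_map):
        """Oracle: evaluate every grid point exhaustively and take the first
        meeting the target."""
        arrays = simulate_self_self(small_map, noise_sd=0.1, n_arrays=4, seed=5)
        grid = [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        target = 1.0
        cal = calibrate_threshold(arrays, small_map, grid=grid, target_false_calls_per_array=target)

        def mean_calls(t):
            c = NoiseCalibration(sd_e=0.1, threshold_multiple=t)
            return float(np.mean([len(call_segments(a, small_map, c)) for a in arrays]))

        brute = next(t for t in grid if mean_calls(t) <= target)
        assert cal.threshold_multiple == brute
        assert mean_calls(cal.threshold_multiple) <= target  # re-verified

    def test_unreachable_target_returns_largest_with_warning(self, small_map):
        arrays = simulate_self_self(small_map, noise_sd=0.3, n_arrays=3, seed=1)
        with pytest.warns(UserWarning, match="false-call target"):
            cal = calibrate_threshold(
                arrays, small_map, grid=[0.1, 0.2], target_false_calls_per_array=0.0
            )
        assert cal.threshold_multiple == 0.2
        assert cal.warning

    def test_bad_inputs(self, small_map):
        arrays = simulate_self_self(small_map, noise_sd=0.1, n_arrays=2, seed=0)
        with pytest.raises(ValueError):
            calibrate_threshold(arrays, small_map, grid=[])
        with pytest.raises(ValueError):
            calibrate_threshold(arrays[:1], small_map)


class TestCollateCalls:
    def _call(self, sample, chrom="1", start=100, end=200, cls="loss"):
        return CnvCall(sample, chrom, start, end, cls, n_probes=3, mean_log2=-1.0 if cls == "loss" else 1.0)

    def test_identical_calls_merge(self):
        calls = [self._call("a"), self._call("b")]
        out = collate_calls(calls, {"a": "L1", "b": "L2"})
        assert len(out) == 1
        assert out[0].occurrence_total == 2
        assert out[0].occurrence_per_line == {"L1": 1, "L2": 1}
        assert out[0].carrier_samples == ["a", "b"]

    def test_class_is_part_of_identity(self):
        calls = [self._call("a", cls="loss"), self._call("b", cls="gain")]
        out = collate_calls(calls, {"a": "L1", "b": "L1"})
        assert len(out) == 2
        assert {c.cnv_class for c in out} == {"gain", "loss"}

    def test_unmapped_sample_raises(self):
        with pytest.raises(KeyError):
            collate_calls([self._call("ghost")], {"a": "L1"})

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 7),  # sample index
                st.integers(0, 3),  # locus index
                st.booleans(),  # gain?
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_occurrence_equals_brute_force_group_by(self, rows):
        """Oracle: plain dict counting over (coords, class) keys."""
        loci = [(100, 200), (150, 400), (500, 900), (1000, 1100)]
        samples = [f"s{i}" for i in range(8)]
        line_map = {s: f"L{i % 3}" for i, s in enumerate(samples)}
        seen = set()
        calls = []
        for si, li, is_gain in rows:
            key = (si, li, is_gain)
            if key in seen:  # one call per sample/locus/class
                continue
            seen.add(key)
            start, end = loci[li]
            cls = "gain" if is_gain else "loss"
            calls.append(self._call(samples[si], start=start, end=end, cls=cls))
        out = collate_calls(calls, line_map)
        brute: dict[tuple, int] = {}
        for c in calls:
            brute[(c.chrom, c.start, c.end, c.cnv_class)] = (
                brute.get((c.chrom, c.start, c.end, c.cnv_class), 0) + 1
            )
        assert {(c.chrom, c.start, c.end, c.cnv_class): c.occurrence_total for c in out} == brute
        for c in out:
            assert c.occurrence_total == sum(c.occurrence_per_line.values())
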