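import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acgh_cnv import (
    LineCatalog,
    UniqueCnv,
    classify_regions,
    cluster_samples,
    merge_to_cnvrs,
    occurrence_matrix,
)
from acgh_cnv.population import GAIN, LOSS, NONE, linkage_to_newick


def _cnv(i, start, end, cls, carriers, line_of):
    per_line: dict[str, int] = {}
    for s in carriers:
        per_line[line_of[s]] = per_line.get(line_of[s], 0) + 1
    return UniqueCnv(
        cnv_id=f"CNV{i}",
        chrom="1",
        start=start,
        end=end,
        cnv_class=cls,
        occurrence_total=len(carriers),
        occurrence_per_line=per_line,
        carrier_samples=sorted(carriers),
    )


@pytest.fixture()
def toy_cohort():
    line_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
    cnvs = [
        _cnv(1, 100, 500, "loss", ["a1", "a2"], line_of),
        _cnv(2, 400, 900, "gain", ["b1"], line_of),
        _cnv(3, 5000, 6000, "gain", ["b1", "b2"], line_of),
        _cnv(4, 9000, 9500, "loss", ["c1"], line_of),
    ]
    regions = merge_to_cnvrs(cnvs)
    return cnvs, regions, LineCatalog(line_of)


class TestOccurrenceMatrix:
    def test_states(self, toy_cohort):
        cnvs, regions, catalog = toy_cohort
        m = occurrence_matrix(regions, cnvs, catalog)
        r1, r2, r3 = [r.cnvr_id for r in regions]
        assert m.loc["a1", r1] == LOSS
        assert m.loc["b2", r1] == NONE
        assert m.loc["b1", r2] == GAIN
        assert m.loc["c1", r3] == LOSS

    def test_conflict_resolved_to_largest_member(self, toy_cohort):
        _, _, catalog = toy_cohort
        line_of = catalog.sample_to_line
        cnvs = [
            _cnv(1, 100, 1000, "loss", ["a1"], line_of),  # 900 bp
            _cnv(2, 200, 500, "gain", ["a1"], line_of),  # 300 bp, same region
        ]
        regions = merge_to_cnvrs(cnvs)
        m = occurrence_matrix(regions, cnvs, catalog)
        assert m.loc["a1", regions[0].cnvr_id] == LOSS

    def test_matches_brute_force_lookup(self, rng, toy_cohort):
        _, _, catalog = toy_cohort
        line_of = catalog.sample_to_line
        samples = list(line_of)
        cnvs = []
        for i in range(60):
            start = int(rng.integers(1, 40_000))
            end = start + int(rng.integers(10, 2500))
            cls = "gain" if rng.random() < 0.4 else "loss"
            k = int(rng.integers(1, len(samples) + 1))
            carriers = list(rng.choice(samples, size=k, replace=False))
            cnvs.append(_cnv(i, start, end, cls, carriers, line_of))
        regions = merge_to_cnvrs(cnvs)
        m = occurrence_matrix(regions, cnvs, catalog)
        for r in regions:
            members = [c for c in cnvs if c.cnv_id in r.member_cnvs]
            for s in samples:
                mine = [c for c in members if s in c.carrier_samples]
                if not mine:
                    expected = NONE
                else:
                    best = max(mine, key=lambda c: (c.size_bp, -c.start, c.cnv_class))
                    expected = GAIN if best.cnv_class == "gain" else LOSS
                assert m.loc[s, r.cnvr_id] == expected

    def test_unmapped_sample_raises(self, toy_cohort):
        cnvs, regions, _ = toy_cohort
        with pytest.raises(KeyError):
            occurrence_matrix(regions, cnvs, LineCatalog({"a1": "A"}))


class TestClassifyRegions:
    def _matrix(self, data, samples):
        return pd.DataFrame(data, index=samples, columns=[f"R{i}" for i in range(len(data[0]))])

    def test_fixed_in_one_line_and_absent_elsewhere_is_specific(self):
        catalog = LineCatalog({"s1": "Silkie", "s2": "Silkie", "s3": "Silkie", "x1": "X"})
        m = self._matrix([[LOSS], [LOSS], [GAIN], [NONE]], ["s1", "s2", "s3", "x1"])
        (c,) = classify_regions(m, catalog)
        assert c.is_fixed and c.fixed_lines == {"Silkie"}
        assert c.is_line_specific and c.specific_line == "Silkie"

    def test_fixed_in_two_lines_not_specific(self):
        catalog = LineCatalog({"a1": "A", "a2": "A", "b1": "B"})
        m = self._matrix([[LOSS], [LOSS], [LOSS]], ["a1", "a2", "b1"])
        (c,) = classify_regions(m, catalog)
        assert c.fixed_lines == {"A", "B"}
        assert not c.is_line_specific

    def test_outside_carrier_blocks_strict_specific_but_not_lenient(self):
        catalog = LineCatalog({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        m = self._matrix([[LOSS], [LOSS], [LOSS], [NONE]], ["a1", "a2", "b1", "b2"])
        (strict,) = classify_regions(m, catalog, strict_specific=True)
        assert strict.fixed_lines == {"A"} and not strict.is_line_specific
        (lenient,) = classify_regions(m, catalog, strict_specific=False)
        assert lenient.is_line_specific and lenient.specific_line == "A"

    @given(
        st.lists(
            st.lists(st.sampled_from([LOSS, NONE, GAIN]), min_size=3, max_size=3),
            min_size=6,
            max_size=6,
        )
    )
    def test_matches_exhaustive_per_line_oracle(self, rows):
        samples = [f"s{i}" for i in range(6)]
        lines = {s: ("A" if i < 2 else "B" if i < 5 else "C") for i, s in enumerate(samples)}
        catalog = LineCatalog(lines)
        m = self._matrix(rows, samples)
        out = {c.cnvr_id: c for c in classify_regions(m, catalog)}
        for col in m.columns:
            fixed = set()
            for line in ("A", "B", "C"):
                members = [s for s in samples if lines[s] == line]
                if all(m.loc[s, col] != NONE for s in members):
                    fixed.add(line)
            assert out[col].fixed_lines == fixed
            assert out[col].is_fixed == bool(fixed)
            specific = False
            if len(fixed) == 1:
                (line,) = fixed
                outside = [s for s in samples if lines[s] != line]
                specific = all(m.loc[s, col] == NONE for s in outside)
            assert out[col].is_line_specific == specific
        # count identity: specific <= fixed <= total
        n_specific = sum(c.is_line_specific for c in out.values())
        n_fixed = sum(c.is_fixed for c in out.values())
        assert n_specific <= n_fixed <= len(out)

    def test_invariant_to_sample_order(self, toy_cohort):
        cnvs, regions, catalog = toy_cohort
        m = occurrence_matrix(regions, cnvs, catalog)
        shuffled = m.iloc[::-1]
        a = classify_regions(m, catalog)
        b = classify_regions(shuffled, catalog)
        assert [(c.cnvr_id, c.fixed_lines, c.is_line_specific) for c in a] == [
            (c.cnvr_id, c.fixed_lines, c.is_line_specific) for c in b
        ]


class TestClusterSamples:
    def test_identical_samples_merge_at_zero(self):
        m = pd.DataFrame([[LOSS, GAIN], [LOSS, GAIN], [NONE, NONE]], index=["a", "b", "c"])
        result = cluster_samples(m)
        heights = result.linkage_matrix[:, 2]
        assert heights[0] == 0.0  # a and b identical
        assert result.flat_clusters(2)["a"] == result.flat_clusters(2)["b"]

    def test_distance_matrix_equals_brute_force_jaccard(self, rng):
        states = rng.choice([LOSS, NONE, GAIN], size=(8, 20))
        m = pd.DataFrame(states, index=[f"s{i}" for i in range(8)])
        from acgh_cnv.population import _pairwise_distance
        from scipy.spatial.distance import squareform

        dist = squareform(_pairwise_distance(m.to_numpy(), "jaccard"))
        carrier = states != NONE
        for i in range(8):
            for j in range(8):
                union = np.sum(carrier[i] | carrier[j])
                inter = np.sum(carrier[i] & carrier[j])
                expected = 0.0 if union == 0 else 1 - inter / union
                assert dist[i, j] == pytest.approx(expected)

    def test_all_identical_samples_star_at_zero(self):
        m = pd.DataFrame([[NONE, NONE]] * 4, index=list("abcd"))
        result = cluster_samples(m)
        assert np.all(result.linkage_matrix[:, 2] == 0.0)

    def test_newick_has_all_leaves(self):
        m = pd.DataFrame(
            [[LOSS, NONE], [LOSS, GAIN], [NONE, GAIN], [NONE, NONE]],
            index=["w", "x", "y", "z"],
        )
        nwk = cluster_samples(m).to_newick()
        assert nwk.endswith(";")
        for leaf in "wxyz":
            assert leaf in nwk
        import io as _io

        from Bio import Phylo

        tree = Phylo.read(_io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["w", "x", "y", "z"]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame([[LOSS]], index=["only"]))


def test_line_catalog_validation():
    with pytest.raises(ValueError):
        LineCatalog({})
    catalog = LineCatalog({"a": "A"})
    with pytest.raises(KeyError):
        catalog.samples_of("B")
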