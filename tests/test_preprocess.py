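"""LOD computation, sequential filtering, log2, repeatability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synovnet import preprocess
from synovnet.preprocess import IntensityMatrix


def _matrix(values: dict, index, scale="linear"):
    return IntensityMatrix(pd.DataFrame(values, index=index), scale=scale)


class TestLOD:
    def test_constant_buffer_gives_lod_equal_to_value(self):
        m = _matrix({"a": [8.0, 8.0, 8.0]}, ["b1", "b2", "b3"])
        lod = preprocess.compute_lod(m)
        assert lod.lod["a"] == pytest.approx(3.0)  # log2(8), zero SD

    def test_known_buffer_arithmetic(self):
        m = _matrix({"a": [2.0, 4.0, 8.0, 16.0]}, list("wxyz"))
        lod = preprocess.compute_lod(m)
        # log2 values {1,2,3,4}: mean 2.5, SD sqrt(5/3), LOD 2.5 + 5·1.29099
        assert lod.lod["a"] == pytest.approx(2.5 + 5 * np.sqrt(5 / 3), abs=1e-9)
        assert lod.lod["a"] == pytest.approx(8.9550, abs=1e-4)

    def test_too_few_buffer_samples_errors_with_count(self):
        m = _matrix({"a": [2.0], "b": [3.0]}, ["b1"])
        with pytest.raises(ValueError, match="2 aptamers"):
            preprocess.compute_lod(m)

    @given(perm=st.permutations(range(4)))
    @settings(max_examples=24, deadline=None)
    def test_invariant_to_sample_order(self, perm):
        base = pd.DataFrame(
            {"a": [2.0, 4.0, 8.0, 16.0], "b": [5.0, 6.0, 7.0, 8.0]},
            index=list("wxyz"),
        )
        shuffled = IntensityMatrix(base.iloc[list(perm)], scale="linear")
        ref = preprocess.compute_lod(IntensityMatrix(base, scale="linear"))
        got = preprocess.compute_lod(shuffled)
        pd.testing.assert_series_equal(ref.lod, got.lod)


def _toy_filter_setup():
    """10 aptamers: a1,a2 unmapped; a3,a4 non-human; a2 also non-human
    (caught at stage 1); a5 below LOD; a6–a10 clean."""
    seq = [f"a{i}" for i in range(1, 11)]
    ann = pd.DataFrame(
        {
            "seq_id": seq,
            "uniprot_ids": ["", "", "P3", "P4", "P5", "P6", "P7", "P8", "P9", "P10"],
            "gene_symbol": [f"G{i}" for i in range(1, 11)],
            "organism": ["Human", "Mouse", "Mouse", "Rat"] + ["Human"] * 6,
        }
    )
    vals = pd.DataFrame(
        {s: [1024.0, 2048.0] for s in seq}, index=["s1", "s2"]
    )
    vals.loc["s1", "a5"] = 4.0  # log2 = 2, below every LOD below
    matrix = IntensityMatrix(vals, scale="linear")
    lods = preprocess.LODTable(
        lod=pd.Series(5.0, index=seq), n_buffer=3
    )
    return matrix, ann, lods


class TestFilter:
    def test_toy_counts_by_enumeration(self):
        matrix, ann, lods = _toy_filter_setup()
        filtered, report = preprocess.filter_aptamers(matrix, ann, lods)
        assert report.counts == {
            "unmapped": 2, "nonhuman": 2, "below_lod": 1, "retained": 5
        }
        assert report.removed_unmapped == ["a1", "a2"]
        assert report.removed_nonhuman == ["a3", "a4"]
        assert report.removed_below_lod == ["a5"]
        assert filtered.seq_ids == ["a6", "a7", "a8", "a9", "a10"]
        assert report.retained_protein_count == 5

    def test_clean_input_removes_nothing(self):
        matrix, ann, lods = _toy_filter_setup()
        clean_ann = ann.copy()
        clean_ann["uniprot_ids"] = [f"P{i}" for i in range(1, 11)]
        clean_ann["organism"] = "Homo sapiens"
        clean = IntensityMatrix(
            pd.DataFrame({s: [1024.0, 2048.0] for s in matrix.seq_ids},
                         index=["s1", "s2"]),
            scale="linear",
        )
        filtered, report = preprocess.filter_aptamers(clean, clean_ann, lods)
        assert report.counts["retained"] == 10
        assert sum(v for k, v in report.counts.items() if k != "retained") == 0

    def test_counts_sum_and_values_unchanged(self):
        matrix, ann, lods = _toy_filter_setup()
        filtered, report = preprocess.filter_aptamers(matrix, ann, lods)
        c = report.counts
        assert c["unmapped"] + c["nonhuman"] + c["below_lod"] + c["retained"] == 10
        stages = (set(report.removed_unmapped) | set(report.removed_nonhuman)
                  | set(report.removed_below_lod))
        assert len(stages) == 5  # disjoint
        pd.testing.assert_frame_equal(
            filtered.data, matrix.data[filtered.seq_ids]
        )

    def test_missing_annotation_errors(self):
        matrix, ann, lods = _toy_filter_setup()
        with pytest.raises(ValueError, match="a10"):
            preprocess.filter_aptamers(matrix, ann.iloc[:-1], lods)


class TestLog2:
    def test_known_values(self):
        m = _matrix({"a": [1024.0, 1.0]}, ["s1", "s2"])
        out = preprocess.log2_transform(m)
        assert out.scale == "log2"
        assert out.data["a"].tolist() == [10.0, 0.0]

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.uniform(0.5, 1e6, size=(5, 4)),
                            index=[f"s{i}" for i in range(5)],
                            columns=[f"a{i}" for i in range(4)])
        m = IntensityMatrix(vals, scale="linear")
        back = np.exp2(preprocess.log2_transform(m).data)
        assert np.allclose(back, vals, rtol=1e-12)

    def test_double_transform_refused(self):
        m = _matrix({"a": [4.0, 8.0]}, ["s1", "s2"])
        once = preprocess.log2_transform(m)
        with pytest.raises(ValueError, match="already log2"):
            preprocess.log2_transform(once)

    def test_nonpositive_reports_coordinates(self):
        df = pd.DataFrame({"a": [4.0, 8.0]}, index=["s1", "s2"])
        m = IntensityMatrix(df, scale="linear")
        m.data.loc["s2", "a"] = -1.0  # bypass constructor check
        with pytest.raises(ValueError, match="s2"):
            preprocess.log2_transform(m)


class TestRepeatability:
    def _setup(self, delta):
        seq = ["a", "b"]
        vals = pd.DataFrame(
            {
                "a": [10.0, 10.0 + delta, 12.0, 12.0 + delta],
                "b": [9.0, 9.0 + delta, 11.0, 11.0 + delta],
            },
            index=["s1", "s1r", "s2", "s2r"],
        )
        matrix = IntensityMatrix(vals, scale="log2")
        lods = preprocess.LODTable(lod=pd.Series(0.0, index=seq), n_buffer=3)
        pairs = [("s1", "s1r"), ("s2", "s2r")]
        return pairs, matrix, lods

    def test_identical_replicates_zero(self):
        pairs, matrix, lods = self._setup(0.0)
        rc = preprocess.repeatability_coefficients(pairs, matrix, lods)
        assert (rc["rc_percent"] == 0).all()

    def test_known_difference_arithmetic(self):
        pairs, matrix, lods = self._setup(0.2)
        rc = preprocess.repeatability_coefficients(pairs, matrix, lods)
        # s_w = 0.2/√2, RC = 1.96·√2·s_w = 0.392, percent = 100·(2^0.392 − 1)
        assert rc.loc["a", "s_w"] == pytest.approx(0.2 / np.sqrt(2), abs=1e-9)
        assert rc.loc["a", "rc_log2"] == pytest.approx(0.392, abs=1e-9)
        assert rc.loc["a", "rc_percent"] == pytest.approx(31.2, abs=0.05)

    def test_invariant_to_within_pair_order(self):
        pairs, matrix, lods = self._setup(0.3)
        fwd = preprocess.repeatability_coefficients(pairs, matrix, lods)
        rev = preprocess.repeatability_coefficients(
            [(b, a) for a, b in pairs], matrix, lods
        )
        pd.testing.assert_frame_equal(fwd, rev)

    def test_below_lod_aptamers_excluded_not_zeroed(self):
        pairs, matrix, lods = self._setup(0.2)
        lods.lod["b"] = 100.0
        rc = preprocess.repeatability_coefficients(pairs, matrix, lods)
        assert "b" not in rc.index
        assert "a" in rc.index

    def test_no_eligible_aptamers_warns_empty(self):
        pairs, matrix, lods = self._setup(0.2)
        lods.lod[:] = 100.0
        with pytest.warns(UserWarning):
            rc = preprocess.repeatability_coefficients(pairs, matrix, lods)
        assert rc.empty
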