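"""Data container validation, summarisation and round-trip I/O."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geecr import (
    CaptureDataError,
    CaptureHistory,
    chipmunk_summary,
    load_capture_csv,
    read_mark_inp,
    summarize,
    write_capture_csv,
    write_mark_inp,
)

from conftest import random_history


class TestValidation:
    def test_all_zero_row_rejected(self):
        with pytest.raises(CaptureDataError, match="no captures"):
            CaptureHistory(y=np.array([[1, 0], [0, 0]]))

    def test_non_binary_entry_rejected(self):
        with pytest.raises(CaptureDataError, match="0/1"):
            CaptureHistory(y=np.array([[1, 2], [1, 0]]))

    def test_missing_covariate_rejected(self):
        with pytest.raises(CaptureDataError, match="missing covariate"):
            CaptureHistory(
                y=np.array([[1, 0], [0, 1]]),
                covariates=pd.DataFrame({"sex": [1.0, np.nan]}),
            )

    def test_covariate_length_mismatch(self):
        with pytest.raises(CaptureDataError, match="rows"):
            CaptureHistory(
                y=np.array([[1, 0]]), covariates=pd.DataFrame({"sex": [1.0, 0.0]})
            )


class TestSummarize:
    def test_enumeration(self):
        ch = CaptureHistory(y=np.array([[1, 0, 0], [1, 1, 0]]))
        s = summarize(ch)
        assert s.T.tolist() == [1, 2]
        assert s.t_first.tolist() == [1, 1]
        assert s.f.tolist() == [1, 1, 0]
        assert s.n_per_occasion.tolist() == [2, 1, 0]
        assert s.total_captures == 3

    def test_conservation_identities(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ch = random_history(rng, n=int(rng.integers(2, 40)), m=int(rng.integers(2, 8)))
            s = summarize(ch)
            k = np.arange(1, ch.m + 1)
            assert (k * s.f).sum() == s.total_captures
            assert s.f.sum() == s.n
            assert s.n_per_occasion.sum() == s.total_captures
            assert (s.T >= 1).all()
            assert ((1 <= s.t_first) & (s.t_first <= ch.m)).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        ch = random_history(rng, n=25, m=6)
        perm = rng.permutation(25)
        ch2 = CaptureHistory(y=ch.y[perm], covariates=ch.covariates.iloc[perm])
        s1, s2 = summarize(ch), summarize(ch2)
        assert np.array_equal(s1.T[perm], s2.T)
        assert np.array_equal(s1.t_first[perm], s2.t_first)
        assert np.array_equal(s1.f, s2.f)
        assert np.array_equal(s1.n_per_occasion, s2.n_per_occasion)


class TestCsvIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        ch = random_history(rng, n=45, m=6)
        path = tmp_path / "caps.csv"
        write_capture_csv(ch, path)
        back = load_capture_csv(path)
        assert back.n == 45 and back.m == 6
        assert np.array_equal(back.y, ch.y)
        pd.testing.assert_frame_equal(back.covariates, ch.covariates)

    def test_all_zero_row_file_rejected(self):
        csv = "occ_1,occ_2,sex\n1,0,1\n0,0,0\n"
        with pytest.raises(CaptureDataError, match="no captures"):
            load_capture_csv(io.StringIO(csv))

    def test_non_binary_cell_rejected(self):
        csv = "occ_1,occ_2\n1,0\n2,1\n"
        with pytest.raises(CaptureDataError, match="0/1"):
            load_capture_csv(io.StringIO(csv))

    def test_unknown_covariate_requested(self):
        csv = "occ_1,occ_2\n1,0\n1,1\n"
        with pytest.raises(CaptureDataError, match="covariate"):
            load_capture_csv(io.StringIO(csv), covariate_names=["sex"])


class TestMarkInp:
    def test_two_by_three_layout(self):
        ch = CaptureHistory(
            y=np.array([[1, 0, 1], [0, 1, 0]]),
            covariates=pd.DataFrame({"sex": [1.0, 0.0]}),
        )
        text = write_mark_inp(ch)
        lines = [ln for ln in text.splitlines() if ln]
        assert len(lines) == 2
        assert lines[0].startswith("101") and lines[0].endswith(";")

    def test_round_trip_random(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ch = random_history(rng, n=int(rng.integers(1, 30)), m=int(rng.integers(2, 9)))
            back = read_mark_inp(write_mark_inp(ch), covariate_names=ch.covariates.columns)
            assert np.array_equal(back.y, ch.y)
            assert np.allclose(back.covariates.to_numpy(), ch.covariates.to_numpy())

    def test_inconsistent_history_length(self):
        with pytest.raises(CaptureDataError, match="length"):
            read_mark_inp("101 1.0 ;\n10 0.0 ;\n")

    def test_missing_terminator(self):
        with pytest.raises(CaptureDataError, match="terminator"):
            read_mark_inp("101 1.0\n")


@st.composite
def capture_matrices(draw):
    n = draw(st.integers(1, 12))
    m = draw(st.integers(2, 7))
    rows = []
    for _ in range(n):
        row = draw(st.lists(st.integers(0, 1), min_size=m, max_size=m))
        if sum(row) == 0:
            row[draw(st.integers(0, m - 1))] = 1
        rows.append(row)
    return np.array(rows)


class TestProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(capture_matrices())
    def test_inp_round_trip_identity(self, y):
        ch = CaptureHistory(y=y)
        back = read_mark_inp(write_mark_inp(ch))
        assert np.array_equal(back.y, ch.y)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(capture_matrices())
    def test_summary_conservation(self, y):
        s = summarize(CaptureHistory(y=y))
        k = np.arange(1, y.shape[1] + 1)
        assert (k * s.f).sum() == s.n_per_occasion.sum() == s.T.sum()


class TestChipmunkFixture:
    def test_group_structure(self):
        gs = chipmunk_summary()
        assert gs.groups["male"] == (22, 41)
        assert gs.groups["female"] == (23, 47)
        assert gs.n == 45 and gs.m == 6
        assert gs.total_captures == 88

    def test_group_means_match_published(self):
        gs = chipmunk_summary()
        assert round(gs.groups["male"][1] / gs.groups["male"][0], 2) == 1.86
        assert round(gs.groups["female"][1] / gs.groups["female"][0], 2) == 2.04

    def test_occasion_and_frequency_vectors(self):
        gs = chipmunk_summary()
        assert gs.n_per_occasion.sum() == 88
        k = np.arange(1, 7)
        assert (k * gs.f).sum() == 88
        assert gs.f.sum() == 45
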