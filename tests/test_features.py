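import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import eigh

from emgvmd import (
    EmgRecording,
    FeatureMatrix,
    combine,
    extract_emd_svd,
    extract_ls,
    extract_td8,
    extract_vmd_svd,
    ls_features,
    segment_svd_feature,
    svd_singular_values,
    td_features,
)

X4 = np.array([1.0, -1.0, 2.0, -2.0])


class TestSvdSingularValues:
    def test_identity_and_diagonal(self):
        assert np.allclose(svd_singular_values(np.eye(2)), [1.0, 1.0])
        assert np.allclose(svd_singular_values(np.diag([3.0, 4.0])), [4.0, 3.0])

    def test_matches_eigendecomposition_oracle(self):
        # singular values = sqrt(eigenvalues of X^T X), independent eigensolver
        rng = np.random.default_rng(1234)
        for _ in range(100):
            m, n = rng.integers(1, 6, size=2)
            X = rng.standard_normal((m, n))
            s = svd_singular_values(X)
            ev = eigh(X.T @ X, eigvals_only=True)
            expected = np.sqrt(np.clip(ev, 0.0, None))[::-1][: min(m, n)]
            assert np.allclose(s, expected, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svd_singular_values(np.array([[1.0, np.nan]]))


class TestSegmentSvdFeature:
    def test_zero_and_pythagorean(self):
        assert segment_svd_feature(np.zeros(10)) == 0.0
        assert segment_svd_feature(np.array([3.0, 4.0])) == pytest.approx(5.0)

    def test_vector_mode_equals_euclidean_norm(self):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(500)
        assert segment_svd_feature(x) == pytest.approx(
            np.sqrt(np.sum(x**2)), abs=1e-10
        )

    def test_matrix_mode_leading_singular_value(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        r = int(np.floor(np.sqrt(500)))
        expected = np.linalg.svd(
            x[: r * (500 // r)].reshape(r, 500 // r), compute_uv=False
        )[0]
        assert segment_svd_feature(x, "matrix") == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            segment_svd_feature(np.array([]))


class TestTdFeatures:
    def test_hand_arithmetic(self):
        mav, zc, wl, rms, se, std, var, snr = td_features(X4)
        assert mav == pytest.approx(1.5)
        assert zc == 3
        assert wl == pytest.approx(9.0)
        assert rms == pytest.approx(np.sqrt(2.5))
        assert var == pytest.approx(10.0 / 3.0)
        assert std == pytest.approx(np.sqrt(10.0 / 3.0))
        assert se == pytest.approx(np.sqrt(10.0 / 3.0) / 2.0)
        assert snr == pytest.approx(1.5 / np.sqrt(10.0 / 3.0))

    def test_constant_segment_degenerate(self):
        mav, zc, wl, rms, se, std, var, snr = td_features(np.full(10, 2.0))
        assert zc == 0 and wl == 0 and var == 0
        assert snr == 0.0  # undefined -> 0 by convention

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            td_features(np.array([1.0]))


class TestLsFeatures:
    def test_hand_counts(self):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        mfl, msr, wamp, ls = ls_features(x, "LS4", wamp_threshold=0.5)
        assert wamp == 3
        mav, zc, ssc, wl, rms, iav, dasdv, var, ls9 = ls_features(x, "LS9")
        assert iav == pytest.approx(2.0)
        assert ssc == 2
        assert dasdv == pytest.approx(1.0)

    def test_zero_segment(self):
        mfl, msr, wamp, ls = ls_features(np.zeros(5), "LS4")
        assert msr == 0.0 and wamp == 0
        vals9 = ls_features(np.zeros(5), "LS9")
        assert vals9[5] == 0.0  # IAV

    def test_l_scale_matches_direct_enumeration(self):
        # L-scale = E|X1 - X2| / 2 over all sample pairs
        rng = np.random.default_rng(17)
        x = rng.standard_normal(40)
        ls = ls_features(x, "LS4")[3]
        pairs = np.abs(x[:, None] - x[None, :])
        n = x.size
        expected = pairs.sum() / (2.0 * n * (n - 1))
        assert ls == pytest.approx(expected, abs=1e-12)


class TestRecordingExtraction:
    @pytest.mark.parametrize("K, expected_cols", [(2, 6), (6, 18), (12, 36)])
    def test_vmd_svd_dimensionality(self, tiny_recording, K, expected_cols):
        fm = extract_vmd_svd(tiny_recording, K=K)
        assert fm.n_cols == expected_cols
        assert len(fm.col_names) == expected_cols

    def test_td8_and_ls_dimensionality(self, tiny_recording):
        assert extract_td8(tiny_recording).n_cols == 24
        assert extract_ls(tiny_recording, "LS4").n_cols == 12
        assert extract_ls(tiny_recording, "LS9").n_cols == 27

    def test_emd_svd_dimensionality_and_zero_fill(self):
        rng = np.random.default_rng(0)
        rec = EmgRecording(rng.standard_normal((3, 2000)), fs=2000.0)
        fm = extract_emd_svd(rec, n_imfs=8)
        assert fm.n_cols == 24

    def test_monotonic_channels_give_all_zero_columns(self):
        ramp = np.linspace(0, 1, 1000)
        rec = EmgRecording(np.vstack([ramp, 2 * ramp]), fs=2000.0)
        fm = extract_emd_svd(rec, n_imfs=4)
        assert np.all(fm.values == 0.0)

    def test_stationary_tone_gives_equal_segment_norms(self):
        t = np.arange(8000) / 2000.0
        rec = EmgRecording(np.sin(2 * np.pi * 50 * t)[None, :], fs=2000.0)
        fm = extract_vmd_svd(rec, K=1)
        vals = fm.values[1:-1, 0]  # interior rows
        assert vals.max() / vals.min() < 1.01

    def test_extraction_deterministic(self, tiny_recording):
        a = extract_emd_svd(tiny_recording, n_imfs=4)
        b = extract_emd_svd(tiny_recording, n_imfs=4)
        assert np.array_equal(a.values, b.values)

    @given(c=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(55)
        x = rng.standard_normal(600)
        base_td = td_features(x)
        scaled_td = td_features(c * x)
        # MAV, WL, RMS, SE, STD scale by c; VAR by c^2; ZC unchanged
        for idx in (0, 2, 3, 4, 5):
            assert scaled_td[idx] == pytest.approx(c * base_td[idx], rel=1e-9)
        assert scaled_td[1] == base_td[1]
        assert scaled_td[6] == pytest.approx(c**2 * base_td[6], rel=1e-9)
        assert segment_svd_feature(c * x) == pytest.approx(
            c * segment_svd_feature(x), rel=1e-9
        )


class TestCombine:
    def _fm(self, n, m, set_id, labels=None):
        rng = np.random.default_rng(hash(set_id) % 2**31)
        return FeatureMatrix(
            rng.standard_normal((n, m)),
            labels,
            [f"{set_id}:{i}" for i in range(m)],
            set_id,
        )

    def test_concatenation(self):
        labels = np.repeat([1, 2], 5)
        a = self._fm(10, 24, "TD8", labels)
        b = self._fm(10, 36, "VMD_SVD", labels)
        out = combine([a, b])
        assert out.n_cols == 60
        assert out.feature_set_id == "TD8+VMD_SVD"
        assert np.array_equal(out.values[:, :24], a.values)

    def test_single_input_identity(self):
        a = self._fm(5, 3, "TD8")
        assert combine([a]) is a

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine([self._fm(5, 3, "a"), self._fm(6, 3, "b")])

    def test_csv_roundtrip(self, tmp_path):
        labels = np.repeat([1, 2, 3], 4)
        a = self._fm(12, 4, "TD8", labels)
        p = tmp_path / "fm.csv"
        a.to_csv(p)
        back = FeatureMatrix.from_csv(p, "TD8")
        assert np.allclose(back.values, a.values)
        assert np.array_equal(back.row_labels, labels)
        assert back.col_names == a.col_names
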