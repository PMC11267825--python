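import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pulmotrack.eit import (
    TidalImage,
    breath_landmarks_eit,
    center_of_ventilation,
    global_signal,
    regional_bands,
    silent_spaces,
    tidal_image,
    tiv_eeli,
)
from pulmotrack.io import EITSequence


def image_from(dz: np.ndarray, mask: np.ndarray | None = None) -> TidalImage:
    if mask is None:
        mask = np.ones_like(dz, dtype=bool)
    ridx, cidx = np.nonzero(mask)
    return TidalImage(
        dz=np.where(mask, dz, 0.0),
        mask=mask,
        ventral_edge=int(ridx.min()),
        dorsal_edge=int(ridx.max()),
        right_edge=int(cidx.min()),
        left_edge=int(cidx.max()),
    )


class TestGlobalSignal:
    def test_sum_inside_mask(self):
        frames = np.ones((3, 10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :] = True
        seq = EITSequence(frames=frames, frame_rate=47, lung_mask=mask)
        assert np.allclose(global_signal(seq), 100.0)

    def test_linearity_under_mask_halving(self):
        frames = np.ones((2, 10, 10))
        full = np.ones((10, 10), dtype=bool)
        half = full.copy()
        half[5:, :] = False
        g_full = global_signal(EITSequence(frames=frames, frame_rate=47, lung_mask=full))
        g_half = global_signal(EITSequence(frames=frames, frame_rate=47, lung_mask=half))
        assert np.allclose(g_half, g_full / 2)


class TestLandmarks:
    def test_monotone_ramp_endpoints(self):
        signal = np.concatenate([np.linspace(2000, 3500, 20), np.full(10, 3500)])
        fs, fe = breath_landmarks_eit(signal, 0, 29, frame_rate=47, window_s=0.2)
        assert fs == 0
        assert signal[fe] == 3500

    def test_flat_signal_tie_breaks_earliest(self):
        signal = np.full(40, 5.0)
        fs, fe = breath_landmarks_eit(signal, 10, 30, frame_rate=47, window_s=0.2)
        assert fs == 10 - int(round(0.2 * 47))
        assert fe == fs

    def test_tiv_eeli_from_ramp(self):
        signal = np.linspace(2000, 3500, 16)
        tiv, eeli = tiv_eeli(signal, 0, 15)
        assert eeli == 2000
        assert tiv == 1500


class TestTidalImage:
    def test_identical_frames_give_zero(self):
        frames = np.ones((2, 8, 8))
        mask = np.ones((8, 8), dtype=bool)
        img = tidal_image(EITSequence(frames=frames, frame_rate=47, lung_mask=mask), 0, 1)
        assert np.allclose(img.dz, 0.0)

    def test_single_pixel_breath(self):
        frames = np.zeros((2, 8, 8))
        frames[1, 3, 4] = 7.0
        mask = np.ones((8, 8), dtype=bool)
        img = tidal_image(EITSequence(frames=frames, frame_rate=47, lung_mask=mask), 0, 1)
        assert img.dz[3, 4] == 7.0
        assert np.count_nonzero(img.dz) == 1

    def test_unclipped_sum_equals_tiv(self, rng):
        frames = rng.normal(10, 2, size=(2, 12, 12))
        mask = rng.random((12, 12)) > 0.3
        seq = EITSequence(frames=frames, frame_rate=47, lung_mask=mask)
        img = tidal_image(seq, 0, 1)
        tiv, _ = tiv_eeli(global_signal(seq), 0, 1)
        assert img.dz[mask].sum() == pytest.approx(tiv, rel=1e-9)


class TestCenterOfVentilation:
    def test_dorsal_row_of_four_row_extent(self):
        dz = np.zeros((4, 4))
        dz[3, :] = 1.0
        assert center_of_ventilation(image_from(dz))[0] == pytest.approx(87.5)

    def test_uniform_symmetric_is_50(self):
        dz = np.ones((6, 6))
        cov_vd, cov_rl = center_of_ventilation(image_from(dz))
        assert cov_vd == pytest.approx(50.0)
        assert cov_rl == pytest.approx(50.0)

    def test_weighted_rows_worked_example(self):
        # row weights (ventral->dorsal) 0,1,3,0 -> (1*37.5 + 3*62.5)/4 = 56.25
        dz = np.zeros((4, 2))
        dz[1, :] = 0.5
        dz[2, :] = 1.5
        assert center_of_ventilation(image_from(dz))[0] == pytest.approx(56.25)

    def test_single_row_extent_reports_50(self):
        dz = np.ones((1, 5))
        assert center_of_ventilation(image_from(dz))[0] == pytest.approx(50.0)

    def test_zero_image_reported_missing(self):
        cov_vd, cov_rl = center_of_ventilation(image_from(np.zeros((4, 4))))
        assert np.isnan(cov_vd) and np.isnan(cov_rl)

    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(2, 9), st.integers(2, 9)),
            elements=st.floats(0, 100),
        )
    )
    def test_matches_brute_force_pixel_loop(self, dz):
        if dz.sum() <= 0:
            return
        img = image_from(dz)
        cov_vd, cov_rl = center_of_ventilation(img)
        h, w = dz.shape
        num_y = num_x = den = 0.0
        for i in range(h):
            for j in range(w):
                wgt = max(dz[i, j], 0.0)
                num_y += wgt * (i + 0.5) / h * 100.0
                num_x += wgt * (j + 0.5) / w * 100.0
                den += wgt
        assert cov_vd == pytest.approx(num_y / den, abs=1e-9)
        assert cov_rl == pytest.approx(num_x / den, abs=1e-9)


class TestSilentSpaces:
    def test_strict_ten_percent_threshold(self):
        dz = np.full((10, 10), 100.0)
        dz[0, 0] = 9.9  # ventral corner, below threshold
        dz[9, 0] = 10.1  # dorsal corner, above threshold
        nss, dss = silent_spaces(image_from(dz), cov_vd=50.0)
        assert dss == pytest.approx(1.0)
        assert nss == pytest.approx(0.0)

    def test_direct_count_dorsal(self):
        dz = np.full((10, 10), 100.0)
        dz[9, :7] = 0.0  # 7 silent pixels in the most dorsal row
        nss, dss = silent_spaces(image_from(dz), cov_vd=50.0)
        assert nss == pytest.approx(7.0)
        assert dss == pytest.approx(0.0)

    def test_uniform_image_has_no_silent_space(self):
        nss, dss = silent_spaces(image_from(np.ones((6, 6))), cov_vd=50.0)
        assert nss == 0.0 and dss == 0.0

    def test_pixel_on_plane_counts_dependent(self):
        dz = np.full((4, 1), 100.0)
        dz[1, 0] = 0.0  # center at y = 37.5
        nss, dss = silent_spaces(image_from(dz), cov_vd=37.5)
        assert dss == pytest.approx(25.0)
        assert nss == 0.0


class TestRegionalBands:
    def test_all_mass_ventral_quarter(self):
        dz = np.zeros((8, 4))
        dz[0, :] = 1.0
        assert regional_bands(image_from(dz)) == pytest.approx((100.0, 0.0, 0.0, 0.0))

    def test_shares_sum_to_100(self, rng):
        dz = rng.random((9, 7))
        assert sum(regional_bands(image_from(dz))) == pytest.approx(100.0, abs=0.01)


class TestInvariantProperties:
    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        dz = rng.random((8, 8)) + 0.01
        a, b = image_from(dz), image_from(c * dz)
        assert center_of_ventilation(a) == pytest.approx(center_of_ventilation(b), abs=1e-9)
        assert regional_bands(a) == pytest.approx(regional_bands(b), abs=1e-9)
        cov = center_of_ventilation(a)[0]
        assert silent_spaces(a, cov) == pytest.approx(silent_spaces(b, cov), abs=1e-9)

    def test_translation_covariance_dorsal_shift(self, rng):
        dz = np.zeros((10, 6))
        dz[2:6, :] = rng.random((4, 6)) + 0.1
        shifted = np.roll(dz, 1, axis=0)
        cov0 = center_of_ventilation(image_from(dz))[0]
        cov1 = center_of_ventilation(image_from(shifted))[0]
        assert cov1 > cov0
        assert regional_bands(image_from(shifted))[3] >= regional_bands(image_from(dz))[3]

    def test_nss_dss_decompose_total_silent_fraction(self, rng):
        dz = rng.random((12, 12)) * 100
        img = image_from(dz)
        cov = center_of_ventilation(img)[0]
        nss, dss = silent_spaces(img, cov)
        total = 100.0 * np.mean(dz < 0.10 * dz.max())
        assert nss + dss == pytest.approx(total, abs=1e-9)
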