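"""Wavelet-transform core: quadrature oracle, ridge registration,
skeleton extraction vs brute force."""

import numpy as np
import pytest

import oscipat as op
from oscipat.cwt import _local_maxima_mask


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def quadrature_cwt(x, fs, scale, t0, omega0=2 * np.pi, norm="sqrt"):
    """Direct numerical integration of the Morlet transform at one
    (scale, time) point -- the reference the FFT path must reproduce."""
    t = np.arange(x.size) / fs
    arg = (t - t0) / scale
    psi = np.pi ** -0.25 * np.exp(1j * omega0 * arg) * np.exp(-0.5 * arg ** 2)
    w = np.sum(x * np.conj(psi)) / fs
    if norm == "sqrt":
        return w / np.sqrt(scale)
    return w / scale


def brute_skeleton_frame(col, k=7, mask=None, rel_floor=1e-9):
    """Reference per-frame skeleton: scan interior scales, test both
    neighbours (plateaus -> lowest index), apply mask and floor, sort by
    (modulus desc, scale asc), truncate to k."""
    n = col.size
    floor = rel_floor * col.max()
    pts = []
    i = 1
    while i < n - 1:
        if col[i] > col[i - 1]:
            j = i
            while j + 1 < n and col[j + 1] == col[j]:
                j += 1
            if j < n - 1 and col[j] > col[j + 1]:
                pts.append(i)
            i = j + 1
        else:
            i += 1
    pts = [i for i in pts if col[i] > floor
           and (mask is None or mask[i])]
    pts.sort(key=lambda i: (-col[i], i))
    return pts[:k]


# ---------------------------------------------------------------------------
# Transform correctness
# ---------------------------------------------------------------------------

class TestComputeCwt:
    def test_zero_signal_yields_zero_modulus_and_empty_skeleton(self):
        rec = op.SignalRecord("O1", 200.0, np.zeros(2000))
        grid = op.ScaleGrid.from_frequency_range(1, 40, 40)
        spec = op.compute_cwt(rec, grid)
        assert np.allclose(spec.modulus, 0.0)
        sk = op.extract_skeleton(spec)
        assert sk.counts.sum() == 0

    def test_agrees_with_direct_quadrature(self, sinusoid_record):
        grid = op.ScaleGrid.from_frequency_range(1, 40, 40)
        spec = op.compute_cwt(sinusoid_record, grid)
        x = sinusoid_record.samples
        fs = sinusoid_record.sampling_rate
        ref_max = spec.modulus.max()
        for si in [0, 10, 20, 30, grid.n_scales - 1]:
            for t0 in [10.0, 15.0, 20.0]:
                w_ref = quadrature_cwt(x, fs, grid.scales[si], t0)
                w_fft = spec.coefficients[si, int(t0 * fs)]
                assert abs(w_fft - w_ref) <= 1e-6 * ref_max

    @pytest.mark.parametrize("f", [2.0, 5.0, 10.0, 20.0, 40.0])
    def test_ridge_frequency_registration(self, f):
        fs, dur = 250.0, 30.0
        t = np.arange(int(fs * dur)) / fs
        rec = op.SignalRecord("O1", fs, np.sin(2 * np.pi * f * t))
        cfg = op.AnalysisConfig()
        grid = op.make_grid(cfg)
        spec = op.compute_cwt(rec, grid, keep_coefficients=False)
        mid = spec.modulus[:, spec.n_times // 2]
        s_peak = grid.scales[np.argmax(mid)]
        assert abs(1.0 / s_peak - f) <= grid.grid_step_hz(f)

    def test_two_component_signal_has_two_ridges(self):
        fs, dur = 250.0, 30.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 20 * t)
        rec = op.SignalRecord("O1", fs, x)
        grid = op.make_grid(op.AnalysisConfig())
        spec = op.compute_cwt(rec, grid, keep_coefficients=False)
        mid = spec.modulus[:, spec.n_times // 2]
        pts = brute_skeleton_frame(mid)
        assert len(pts) == 2
        freqs = sorted(1.0 / grid.scales[i] for i in pts)
        assert abs(freqs[0] - 5.0) <= 2 * grid.grid_step_hz(5.0)
        assert abs(freqs[1] - 20.0) <= 2 * grid.grid_step_hz(20.0)

    def test_linearity_of_modulus(self, sinusoid_record):
        grid = op.ScaleGrid.from_frequency_range(1, 40, 30)
        spec1 = op.compute_cwt(sinusoid_record, grid, keep_coefficients=False)
        rec3 = op.SignalRecord("O1", sinusoid_record.sampling_rate,
                               3.0 * sinusoid_record.samples)
        spec3 = op.compute_cwt(rec3, grid, keep_coefficients=False)
        assert np.allclose(spec3.modulus, 3.0 * spec1.modulus, rtol=1e-10)

    def test_time_shift_covariance(self):
        fs = 200.0
        rng = np.random.default_rng(7)
        x = rng.standard_normal(int(20 * fs))
        m = 40
        grid = op.ScaleGrid.from_frequency_range(2, 40, 30)
        a = op.compute_cwt(op.SignalRecord("O1", fs, x), grid,
                           keep_coefficients=False)
        xs = np.roll(x, m)
        b = op.compute_cwt(op.SignalRecord("O1", fs, xs), grid,
                           keep_coefficients=False)
        # compare interior columns, away from both records' edges
        lo = int(5 * fs)
        hi = int(15 * fs)
        assert np.allclose(b.modulus[:, lo + m: hi + m],
                           a.modulus[:, lo:hi], rtol=1e-7, atol=1e-9)

    def test_modulus_phase_reconstruct_coefficients(self, sinusoid_record):
        grid = op.ScaleGrid.from_frequency_range(1, 40, 25)
        spec = op.compute_cwt(sinusoid_record, grid)
        rebuilt = spec.modulus * np.exp(1j * spec.phase)
        assert np.allclose(rebuilt, spec.coefficients, atol=1e-12)

    def test_linear_norm_rescales_rows(self, sinusoid_record):
        grid = op.ScaleGrid.from_frequency_range(1, 40, 25)
        s_sqrt = op.compute_cwt(sinusoid_record, grid, norm="sqrt",
                                keep_coefficients=False)
        s_lin = op.compute_cwt(sinusoid_record, grid, norm="linear",
                               keep_coefficients=False)
        expected = s_sqrt.modulus / np.sqrt(grid.scales)[:, None]
        assert np.allclose(s_lin.modulus, expected, rtol=1e-10)

    def test_nyquist_violation_raises(self):
        rec = op.SignalRecord("O1", 60.0, np.zeros(600))
        grid = op.ScaleGrid.from_frequency_range(1, 40, 30)
        with pytest.raises(ValueError, match="Nyquist"):
            op.compute_cwt(rec, grid)

    def test_non_finite_samples_raise(self):
        with pytest.raises(ValueError, match="finite"):
            op.SignalRecord("O1", 200.0, np.array([0.0, np.nan, 1.0]))


class TestScaleGrid:
    def test_covers_range_with_guard_points(self):
        grid = op.ScaleGrid.from_frequency_range(1, 40, 87)
        f = grid.frequencies
        assert f.max() > 40.0 and f.min() < 1.0
        assert np.any(np.isclose(f, 1.0)) and np.any(np.isclose(f, 40.0))

    def test_log_spacing_constant_ratio_inside_guards(self):
        """Core scales are exactly log-spaced; the high guard sits two
        ratio steps up (to preserve the minimum adjacent gap), the low
        guard one step down."""
        grid = op.ScaleGrid.from_frequency_range(1, 40, 50)
        ratios = grid.scales[1:] / grid.scales[:-1]
        assert np.allclose(ratios[1:], ratios[1])
        assert ratios[0] == pytest.approx(ratios[1] ** 2)

    def test_non_monotone_scales_rejected(self):
        with pytest.raises(ValueError):
            op.ScaleGrid(np.array([0.1, 0.05, 0.2]), 1, 40)


# ---------------------------------------------------------------------------
# Skeleton extraction
# ---------------------------------------------------------------------------

def random_spectrum(rng, n_scales=40, n_times=50):
    grid = op.ScaleGrid.from_frequency_range(1, 40, n_scales - 2)
    mod = rng.random((grid.n_scales, n_times))
    return op.WaveletSpectrum(modulus=mod, grid=grid, time_step=0.02,
                              omega0=2 * np.pi)


class TestExtractSkeleton:
    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            spec = random_spectrum(rng)
            k = int(rng.integers(1, 9))
            sk = op.extract_skeleton(spec, k=k, apply_coi=False)
            for t in range(spec.n_times):
                ref = brute_skeleton_frame(spec.modulus[:, t], k=k)
                got = list(sk.scale_idx[: sk.counts[t], t])
                assert got == ref

    def test_respects_cone_of_influence_mask(self):
        rng = np.random.default_rng(3)
        spec = random_spectrum(rng)
        sk = op.extract_skeleton(spec, k=7, apply_coi=True)
        mask = spec.valid_mask
        for t in range(spec.n_times):
            ref = brute_skeleton_frame(spec.modulus[:, t], k=7,
                                       mask=mask[:, t])
            assert list(sk.scale_idx[: sk.counts[t], t]) == ref

    def test_single_ridge_gives_one_point_per_interior_frame(
        self, sinusoid_record
    ):
        grid = op.make_grid(op.AnalysisConfig())
        spec = op.compute_cwt(sinusoid_record, grid, keep_coefficients=False)
        sk = op.extract_skeleton(spec, k=7)
        w = np.sqrt(2) * grid.scales[-1]
        interior = (spec.times > w) & (spec.times < spec.record_duration - w)
        assert np.all(sk.counts[interior] == 1)

    def test_fewer_maxima_than_k_not_padded(self):
        fs, dur = 250.0, 20.0
        t = np.arange(int(fs * dur)) / fs
        x = sum(np.sin(2 * np.pi * f * t) for f in (3.0, 9.0, 27.0))
        grid = op.make_grid(op.AnalysisConfig())
        spec = op.compute_cwt(op.SignalRecord("O1", fs, x), grid,
                              keep_coefficients=False)
        sk = op.extract_skeleton(spec, k=7)
        mid = sk.counts[spec.n_times // 2]
        assert mid <= 3

    def test_plateau_counts_once_at_lowest_scale(self):
        col = np.array([0.1, 0.5, 0.5, 0.5, 0.2, 0.7, 0.1])
        mod = np.tile(col[:, None], (1, 3))
        grid = op.ScaleGrid(np.geomspace(0.02, 1.0, 7), 1, 40)
        spec = op.WaveletSpectrum(modulus=mod, grid=grid, time_step=0.1,
                                  omega0=2 * np.pi)
        sk = op.extract_skeleton(spec, k=7, apply_coi=False)
        assert sk.counts[1] == 2
        assert set(sk.scale_idx[:2, 1]) == {1, 5}
        assert sk.scale_idx[0, 1] == 5  # larger modulus first

    def test_boundary_scales_never_maxima(self):
        mod = np.zeros((5, 3))
        mod[0] = 9.0
        mod[4] = 8.0
        grid = op.ScaleGrid(np.geomspace(0.02, 1.0, 5), 1, 40)
        spec = op.WaveletSpectrum(modulus=mod, grid=grid, time_step=0.1,
                                  omega0=2 * np.pi)
        sk = op.extract_skeleton(spec, k=7, apply_coi=False)
        assert sk.counts.sum() == 0

    def test_topk_mode_ignores_maximum_structure(self):
        rng = np.random.default_rng(5)
        spec = random_spectrum(rng, n_scales=20, n_times=10)
        sk = op.extract_skeleton(spec, k=4, mode="topk", apply_coi=False)
        for t in range(10):
            col = spec.modulus[1:-1, t]
            expect = np.sort(col)[::-1][:4]
            assert np.allclose(np.sort(sk.modulus[:4, t])[::-1], expect)

    def test_frames_iterator_matches_arrays(self):
        rng = np.random.default_rng(9)
        spec = random_spectrum(rng, n_scales=15, n_times=8)
        sk = op.extract_skeleton(spec, k=3, apply_coi=False)
        for frame in sk.frames():
            t = frame.time_index
            assert len(frame.points) == sk.counts[t]
            mods = [m for _, m in frame.points]
            assert mods == sorted(mods, reverse=True)
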