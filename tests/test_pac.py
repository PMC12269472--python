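import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megpac_rsn.pac import (
    FrequencyGrid,
    _alternating_extrema,
    analytic_band,
    direct_pac,
    estimate_pac,
    find_max_pac,
    megpac_from_pacmap,
    pac_comodulogram,
    pac_map,
    synthesize_megpac,
)

FS = 600.0
ANALYTIC = 1.0 / (2.0 * np.sqrt(1.5))


def _uniform_phase(n_cycles, per_cycle=64):
    return np.linspace(0, 2 * np.pi * n_cycles, n_cycles * per_cycle,
                       endpoint=False)


class TestDirectEstimator:
    def test_constant_amplitude_vanishes(self):
        phi = _uniform_phase(500)
        assert direct_pac(np.ones_like(phi), phi) < 1e-12

    def test_cosine_gated_amplitude_analytic_value(self):
        phi = _uniform_phase(10_000)
        val = direct_pac(1.0 + np.cos(phi), phi)
        assert val == pytest.approx(ANALYTIC, rel=1e-6)

    def test_zero_amplitude_defined_as_zero(self):
        phi = _uniform_phase(20)
        assert direct_pac(np.zeros_like(phi), phi) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_cauchy_schwarz_bound(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(50, 2000)
        a = np.abs(rng.standard_normal(n))
        phi = rng.uniform(-np.pi, np.pi, n)
        assert 0.0 <= direct_pac(a, phi) <= 1.0


class TestEstimatePac:
    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(20 * FS))
        base = estimate_pac(x, 6.0, 100.0, FS)
        for c in (1e-8, 0.5, 2.0, 1e8):
            assert abs(estimate_pac(c * x, 6.0, 100.0, FS) - base) < 1e-10

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(20 * FS))
        base = estimate_pac(x, 6.0, 100.0, FS)
        assert abs(estimate_pac(x + 123.4, 6.0, 100.0, FS) - base) < 1e-10

    def test_bound_on_random_signals(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.standard_normal(int(12 * FS))
            assert 0.0 <= estimate_pac(x, 4.0, 120.0, FS) <= 1.0

    def test_constant_signal_gives_zero(self):
        x = np.full(int(20 * FS), 3.3)
        assert estimate_pac(x, 6.0, 100.0, FS) == 0.0

    def test_too_short_signal_rejected(self):
        x = np.zeros(int(FS))  # 1 s: only 6 cycles at 6 Hz
        with pytest.raises(ValueError, match="too short"):
            estimate_pac(x, 6.0, 100.0, FS)

    def test_aliasing_fs_rejected(self):
        x = np.zeros(int(20 * 250))
        with pytest.raises(ValueError, match="fs"):
            estimate_pac(x, 6.0, 100.0, 250.0)


class TestFrequencyGrid:
    def test_defaults_cover_stated_ranges(self):
        g = FrequencyGrid()
        assert g.phase_freqs[0] == 2.0 and g.phase_freqs[-1] == 30.0
        assert g.amp_freqs[0] == 80.0 and g.amp_freqs[-1] == 150.0
        assert g.amp_halfwidth() >= max(g.phase_freqs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(phase_freqs=(1.0, 5.0))
        with pytest.raises(ValueError):
            FrequencyGrid(amp_freqs=(80.0, 160.0))
        with pytest.raises(ValueError):
            FrequencyGrid(phase_freqs=(5.0, 3.0))
        with pytest.raises(ValueError, match="sidebands"):
            FrequencyGrid(amp_bw=10.0)


class TestFindMaxPac:
    def test_tie_break_on_degenerate_input_is_lowest_cell(self, coarse_grid):
        x = np.zeros(int(20 * 500))
        fp, fa, val = find_max_pac(x, coarse_grid, 500.0)
        assert (fp, fa, val) == (2.0, 80.0, 0.0)

    def test_planted_pair_recovered(self, tiny_sim_config):
        from megpac_rsn.mesh import build_mesh
        from megpac_rsn.simulate import simulate_recording

        mesh = build_mesh(tiny_sim_config.mesh_spec)
        rec, _ = simulate_recording(tiny_sim_config, mesh, "s0", "first-OFF",
                                    0)
        grid = FrequencyGrid()
        fp, fa, val = find_max_pac(rec.data[0], grid, rec.fs)
        assert abs(fp - 6.0) <= 1.0 and abs(fa - 100.0) <= 5.0
        assert val > 0.05

    def test_true_cell_beats_distant_cells(self, tiny_sim_config):
        """PAC at the planted cell exceeds every cell >= 2 grid steps away."""
        from megpac_rsn.mesh import build_mesh
        from megpac_rsn.simulate import simulate_recording

        mesh = build_mesh(tiny_sim_config.mesh_spec)
        rec, _ = simulate_recording(tiny_sim_config, mesh, "s0", "first-OFF",
                                    3)
        grid = FrequencyGrid()
        como = pac_comodulogram(rec.data[0], rec.fs, grid)[0]
        pf = np.asarray(grid.phase_freqs)
        af = np.asarray(grid.amp_freqs)
        i0 = np.argmin(np.abs(pf - 6.0))
        j0 = np.argmin(np.abs(af - 100.0))
        far = (np.abs(np.arange(pf.size)[:, None] - i0) >= 2) | \
              (np.abs(np.arange(af.size)[None, :] - j0) >= 2)
        assert como[i0, j0] > como[far].max()


class TestMegPAC:
    def test_constant_envelope_alternates_and_zero_mean(self):
        t = np.arange(int(120 * FS)) / FS
        c = 0.8
        x = np.sin(2 * np.pi * 6.0 * t) + c * np.sin(2 * np.pi * 100.0 * t)
        series, idx = synthesize_megpac(x, 6.0, 100.0, FS)
        assert series.size == 1200  # 10 Hz x 120 s
        # extrema samples alternate and carry the envelope magnitude c
        low = analytic_band(x, FS, 6 - 1.5, 6 + 1.5).real
        signs = np.sign(low[idx])
        assert np.all(signs[1:] != signs[:-1])
        amp = np.abs(analytic_band(x, FS, 100 - 35, 100 + 35))
        assert np.allclose(amp[idx[2:-2]], c, rtol=0.05)
        # the symmetric +-c construction averages out in the 10 Hz series
        assert abs(series.mean()) < 0.05 * c

    def test_ramp_envelope_matches_piecewise_linear_oracle(self):
        """The extrema samples carry the (sign-adjusted) slow envelope, and
        the 10 Hz series equals an independently resampled piecewise-linear
        reconstruction of those samples."""
        fs = 600.0
        t = np.arange(int(60 * fs)) / fs
        ramp = 0.5 + t / t[-1]
        x = np.sin(2 * np.pi * 6.0 * t) + ramp * np.sin(2 * np.pi * 100.0 * t)
        series, idx = synthesize_megpac(x, 6.0, 100.0, fs)
        from scipy.signal import argrelextrema, resample_poly

        low = np.sin(2 * np.pi * 6.0 * t)
        maxima = argrelextrema(low, np.greater)[0]
        minima = argrelextrema(low, np.less)[0]
        knots = np.sort(np.concatenate([maxima, minima]))
        inner_knots = knots[(knots > fs) & (knots < t.size - fs)]
        # sampled values equal the ramp envelope there (sign-adjusted)
        amp = np.abs(analytic_band(x, fs, 100 - 35, 100 + 35))
        assert np.allclose(amp[inner_knots], ramp[inner_knots], rtol=0.05)
        # 10 Hz series ~ independently anti-aliased + decimated oracle
        vals = ramp[knots] * np.where(np.isin(knots, maxima), 1.0, -1.0)
        full_oracle = np.interp(t, knots / fs, vals)
        oracle = resample_poly(full_oracle, up=1, down=60)
        inner = slice(20, -20)
        err = np.abs(series[inner] - oracle[inner])
        assert err.max() < 0.08

    def test_extrema_alternation_property(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.standard_normal(3000)
            low = analytic_band(x, 600.0, 5, 7).real
            idx, sgn = _alternating_extrema(low)
            assert np.all(sgn[1:] != sgn[:-1])
            assert np.all(np.diff(idx) > 0)

    def test_too_few_extrema_error_names_vertex(self):
        x = np.zeros((2, int(20 * FS)))
        x[0] = np.sin(2 * np.pi * 6.0 * np.arange(x.shape[1]) / FS)
        from megpac_rsn.pac import PACMap

        pm = PACMap(np.array([6.0, 6.0]), np.array([100.0, 100.0]),
                    np.zeros(2))
        with pytest.raises(ValueError, match="vertex 1"):
            megpac_from_pacmap(x, FS, pm)

    def test_megpac_output_rate_and_length(self):
        t = np.arange(int(24 * 500)) / 500.0
        x = np.sin(2 * np.pi * 8.0 * t) + 0.5 * np.sin(2 * np.pi * 110.0 * t)
        series, _ = synthesize_megpac(x, 8.0, 110.0, 500.0)
        assert series.size == 240

    def test_vectorized_matches_single_vertex_path(self, tiny_sim_config):
        from megpac_rsn.mesh import build_mesh
        from megpac_rsn.simulate import simulate_recording

        mesh = build_mesh(tiny_sim_config.mesh_spec)
        rec, _ = simulate_recording(tiny_sim_config, mesh, "s0", "first-OFF",
                                    9)
        grid = FrequencyGrid.coarse()
        pm = pac_map(rec.data, rec.fs, grid)
        mp = megpac_from_pacmap(rec.data, rec.fs, pm, grid)
        v = 3
        single, _ = synthesize_megpac(rec.data[v], pm.phase_freq[v],
                                      pm.amp_freq[v], rec.fs, grid=grid)
        assert np.allclose(mp.data[v], single, atol=1e-5)
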