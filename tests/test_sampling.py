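import numpy as np
import pytest

from qmcffd import sampling as sp
from qmcffd import xsection as xs
from qmcffd.phantom import build_al_phantom
from qmcffd.physics import EnergySpectrum


class TestSampleStream:
    def test_sobol_point_reproducible(self):
        a = sp.SampleStream("sobol", 8, seed=3, scramble=1)
        b = sp.SampleStream("sobol", 8, seed=3, scramble=1)
        np.testing.assert_array_equal(a.next_point(), b.next_point())

    def test_distinct_scrambles_differ(self):
        a = sp.SampleStream("sobol", 8, seed=3, scramble=1)
        b = sp.SampleStream("sobol", 8, seed=3, scramble=2)
        assert not np.array_equal(a.next_point(), b.next_point())

    def test_base2_stratification(self):
        """Any coordinate of the first 2^10 points is perfectly stratified
        over 32 equal bins (digital-net property, preserved by scrambling)."""
        s = sp.SampleStream("sobol", 40, seed=0, scramble=0)
        pts = s.take(1024)
        for dim in (0, 7, 39):
            counts = np.bincount((pts[:, dim] * 32).astype(int), minlength=32)
            assert np.all(counts == 32)

    def test_pseudorandom_mean(self):
        s = sp.SampleStream("pseudorandom", 4, seed=11)
        pts = s.take(100_000)
        assert np.all(np.abs(pts.mean(axis=0) - 0.5) < 0.01)

    def test_counter_advances_only_state(self):
        s = sp.SampleStream("sobol", 8, seed=1, scramble=0)
        first_two = s.take(2)
        assert s.counter == 2
        fresh = sp.SampleStream("sobol", 8, seed=1, scramble=0)
        np.testing.assert_array_equal(fresh.take(2), first_two)

    def test_dimension_limit(self):
        with pytest.raises(ValueError):
            sp.SampleStream("sobol", 30000)

    def test_unscrambled_skips_origin(self):
        s = sp.SampleStream("sobol", 4, scramble=None)
        assert not np.allclose(s.next_point(), 0.0)


class TestAliasTable:
    def test_single_bin(self):
        t = sp.build_alias([1.0])
        assert sp.alias_sample(t, 0.3) == 0

    def test_two_equal_bins_threshold(self):
        t = sp.build_alias([1.0, 1.0])
        assert sp.alias_sample(t, 0.25) == 0
        assert sp.alias_sample(t, 0.75) == 1

    def test_exact_reconstruction_invariant(self):
        w = np.array([0.2, 0.3, 0.5])
        t = sp.build_alias(w)
        k = len(w)
        recon = np.array([
            (t.cut[b] + sum(1.0 - t.cut[a] for a in range(k)
                            if t.alias[a] == b and a != b)) / k
            for b in range(k)])
        np.testing.assert_allclose(recon, w / w.sum(), atol=1e-12)

    def test_brute_force_sweep_frequencies(self):
        w = np.array([0.2, 0.3, 0.5])
        t = sp.build_alias(w)
        n = 10 ** 6
        us = (np.arange(n) + 0.5) / n
        x = us * len(w)
        j = np.minimum(x.astype(int), len(w) - 1)
        frac = x - j
        idx = np.where(frac < t.cut[j], j, t.alias[j])
        freq = np.bincount(idx, minlength=3) / n
        np.testing.assert_allclose(freq, w, atol=2e-6)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            sp.build_alias([0.0, 0.0])
        with pytest.raises(ValueError):
            sp.build_alias([1.0, -0.1])


class TestSampleEnergy:
    def test_single_line(self):
        spec = EnergySpectrum.monoenergetic(77.0)
        assert sp.sample_energy(spec, 0.99) == 77.0

    def test_two_equal_lines_split(self):
        spec = EnergySpectrum(np.array([40.0, 80.0]), np.array([1.0, 1.0]))
        assert sp.sample_energy(spec, 0.25) == 40.0
        assert sp.sample_energy(spec, 0.75) == 80.0


class TestSourceDirection:
    def test_midpoint_is_central_axis(self):
        p = build_al_phantom()
        d = sp.sample_direction_source(0.5, 0.5, [0, 0, 0], p)
        center_dir = np.array([0.0, 486.0, 0.0])
        center_dir /= np.linalg.norm(center_dir)
        np.testing.assert_allclose(d, center_dir, atol=1e-12)

    def test_corners_map_to_rectangle_corners(self):
        p = build_al_phantom()
        d00 = sp.sample_direction_source(0.0, 0.0, [0, 0, 0], p)
        d11 = sp.sample_direction_source(1.0, 1.0, [0, 0, 0], p)
        t = 486.0 / d00[1]
        np.testing.assert_allclose((t * d00)[[0, 2]], [-80.0, -80.0],
                                   atol=1e-9)
        t = 486.0 / d11[1]
        np.testing.assert_allclose((t * d11)[[0, 2]], [80.0, 80.0],
                                   atol=1e-9)

    def test_all_rays_hit_phantom(self):
        from qmcffd.raytrace import intersect_phantom
        p = build_al_phantom()
        rng = np.random.default_rng(0)
        for u2, u3 in rng.random((200, 2)):
            d = sp.sample_direction_source(u2, u3, [0, 0, 0], p)
            assert intersect_phantom(p, [0, 0, 0], d) is not None


class TestScatterType:
    def test_compton_only(self):
        assert sp.sample_scatter_type(0.6, 0.0, 0.99) == (0, 0.6)

    def test_threshold_at_half(self):
        assert sp.sample_scatter_type(0.3, 0.3, 0.49)[0] == 0
        assert sp.sample_scatter_type(0.3, 0.3, 0.51)[0] == 1
        assert sp.sample_scatter_type(0.3, 0.3, 0.49)[1] == pytest.approx(0.6)

    def test_expectation_reproduces_channel_probability(self):
        """E[weight * 1{compton}] over a u-sweep equals p_T0."""
        p0, p1 = 0.45, 0.15
        us = (np.arange(10000) + 0.5) / 10000
        acc = sum(w for u in us
                  for k, w in [sp.sample_scatter_type(p0, p1, u)] if k == 0)
        assert acc / len(us) == pytest.approx(p0, abs=1e-4)

    def test_closed_channel_raises(self):
        with pytest.raises(ValueError):
            sp.sample_scatter_type(0.0, 0.0, 0.5)


class TestRita:
    def test_uniform_density_identity(self):
        t = sp.build_rita(lambda x: np.ones_like(np.asarray(x, float)))
        us = np.array([0.05, 0.3, 0.5, 0.8, 0.95])
        np.testing.assert_allclose(sp.sample_cos_theta(t, us), 2 * us - 1,
                                   atol=2e-4)

    def test_thomson_quantiles_match_numeric_inverse(self):
        pdf = lambda c: 1.0 + np.asarray(c, float) ** 2
        t = sp.build_rita(pdf, tolerance=1e-4)
        grid = np.linspace(-1, 1, 100001)
        v = pdf(grid)
        cdf = np.concatenate([[0], np.cumsum(
            0.5 * (v[1:] + v[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        uq = np.linspace(0.005, 0.995, 199)
        exact = np.interp(uq, cdf, grid)
        got = sp.sample_cos_theta(t, uq)
        assert np.max(np.abs(np.interp(got, grid, cdf) - uq)) < 2e-4

    def test_klein_nishina_cdf_tolerance(self):
        t = sp.build_rita(lambda c: xs.klein_nishina_dcs(80.0, c),
                          tolerance=1e-4)
        assert t.max_error < 1e-4

    def test_monotone_in_u(self):
        t = sp.build_rita(lambda c: xs.klein_nishina_dcs(60.0, c))
        us = np.linspace(0, 0.999, 500)
        xs_ = sp.sample_cos_theta(t, us)
        assert np.all(np.diff(xs_) >= 0)

    def test_zero_density_raises(self):
        with pytest.raises(sp.NonNormalizableError):
            sp.build_rita(lambda x: np.zeros_like(np.asarray(x, float)))

    def test_accepts_deflection_kernel(self):
        from qmcffd.physics import COMPTON, DeflectionKernel, load_material
        kernel = DeflectionKernel(COMPTON, load_material("water"), 60.0)
        t = sp.build_rita(kernel, tolerance=1e-4)
        assert t.max_error < 1e-4
        us = np.linspace(0.0, 0.999, 200)
        assert np.all(np.diff(sp.sample_cos_theta(t, us)) >= 0)


class TestVariateAccounting:
    def test_one_history_consumes_one_point(self):
        """Energy(1) + direction(2) + depth(1), then 4 per extra order."""
        n_orders = 5
        roles = 4  # first order
        roles += (n_orders - 1) * sp.VARIATES_PER_ORDER
        assert roles == 4 * n_orders
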