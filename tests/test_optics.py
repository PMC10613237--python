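"""Grid contracts, angular-spectrum propagation and basis changes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mstrace as ms
from mstrace.optics import ValidationError

from conftest import passband_field


class TestFieldGrid:
    @pytest.mark.parametrize("n,pitch,wavelength,na,expect", [
        (100, 0.45, 0.9, 1.0, {"extent": 45.0}),
        (2, 1.0, 2.0, 1.0, {"k0": np.pi}),
        (64, 0.65, 1.3, 1.0, {"pitch": 0.65}),  # exactly half a wavelength
    ])
    def test_valid_grids(self, n, pitch, wavelength, na, expect):
        g = ms.make_grid(n, pitch, wavelength, na)
        for attr, val in expect.items():
            assert getattr(g, attr) == pytest.approx(val, rel=1e-12)
        assert g.k0 == pytest.approx(2 * np.pi / wavelength, rel=1e-15)

    @pytest.mark.parametrize("kwargs,field_name", [
        (dict(n=1, pitch=0.4, wavelength=0.9, na=1.0), "n"),
        (dict(n=16, pitch=-0.1, wavelength=0.9, na=1.0), "pitch"),
        (dict(n=16, pitch=0.4, wavelength=0.0, na=1.0), "wavelength"),
        (dict(n=16, pitch=0.4, wavelength=0.9, na=1.5), "na"),
        (dict(n=16, pitch=0.5, wavelength=0.9, na=1.0), "pitch"),  # > lam/2
    ])
    def test_invalid_grids_name_the_field(self, kwargs, field_name):
        with pytest.raises(ValidationError, match=field_name):
            ms.make_grid(**kwargs)


class TestAngularSpectrum:
    def test_zero_distance_is_identity(self, grid16):
        f = passband_field(grid16, 1)
        out = ms.angular_spectrum_propagate(f, 0.0)
        np.testing.assert_allclose(out.values, f.values, atol=1e-14)

    def test_plane_wave_acquires_analytic_phase(self, grid32):
        # oblique plane wave with sin(theta) on the sampling lattice
        g = grid32
        kx = 2 * np.pi * np.fft.fftfreq(g.n, g.pitch)[4]
        sin_t = kx / g.k0
        assert 0 < sin_t < 1
        xx = g.coords[:, None] * np.ones(g.n)[None, :]
        wave = np.exp(1j * kx * xx)
        d = 7.3
        out = ms.angular_spectrum_propagate(ms.ComplexField(g, wave), d)
        expected = wave * np.exp(1j * g.k0 * np.sqrt(1 - sin_t ** 2) * d)
        np.testing.assert_allclose(out.values, expected, atol=1e-10)

    def test_point_source_matches_greens_reference(self, grid32):
        g = grid32
        delta = np.zeros((g.n, g.n), complex)
        src = (5, 9)
        delta[src] = 1.0
        d = 6.0
        prop = ms.angular_spectrum_propagate(ms.ComplexField(g, delta), d)
        ref = ms.greens_reference(g, src, d)
        mask = np.ones_like(prop.values, bool)
        rms = np.sqrt(np.mean(np.abs(prop.values - ref.values)[mask] ** 2))
        assert rms < 1e-6

    def test_forward_then_backward_restores(self, grid16):
        f = passband_field(grid16, 2)
        out = ms.angular_spectrum_propagate(
            ms.angular_spectrum_propagate(f, 11.2), -11.2)
        assert np.max(np.abs(out.values - f.values)) < 1e-9

    def test_nonfinite_field_rejected(self, grid16):
        vals = np.zeros((16, 16), complex)
        vals[0, 0] = np.nan
        with pytest.raises(ValidationError):
            ms.ComplexField(grid16, vals)

    def test_padded_variant_agrees_for_interior_beams(self):
        # a beam that never reaches the ROI edge sees no wrap-around, so the
        # periodic and the open-boundary (padded) propagators coincide
        g = ms.make_grid(32, 0.45, 0.9, 0.3)
        x = g.coords
        xx, yy = np.meshgrid(x, x, indexing="ij")
        beam = np.exp(-(xx ** 2 + yy ** 2) / (2 * 1.5 ** 2)).astype(complex)
        a = ms.angular_spectrum_propagate(ms.ComplexField(g, beam), 5.0)
        b = ms.angular_spectrum_propagate(ms.ComplexField(g, beam), 5.0,
                                          pad=True)
        # residual difference is set by the beam's ~1e-5 tails at the edge
        assert np.max(np.abs(a.values - b.values)) < 1e-4 * np.max(
            np.abs(a.values))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(d=st.floats(-40.0, 40.0), seed=st.integers(0, 100))
    def test_energy_conserved_for_passband_fields(self, d, seed):
        g = ms.make_grid(16, 0.45, 0.9, 1.0)
        f = passband_field(g, seed)
        out = ms.angular_spectrum_propagate(f, d)
        assert out.energy() == pytest.approx(f.energy(), rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(d1=st.floats(-15.0, 15.0), d2=st.floats(-15.0, 15.0))
    def test_propagation_composes_over_split_distances(self, d1, d2):
        g = ms.make_grid(16, 0.45, 0.9, 1.0)
        f = passband_field(g, 5)
        once = ms.angular_spectrum_propagate(f, d1 + d2)
        twice = ms.angular_spectrum_propagate(
            ms.angular_spectrum_propagate(f, d1), d2)
        scale = np.max(np.abs(once.values)) or 1.0
        assert np.max(np.abs(once.values - twice.values)) / scale < 1e-9


class TestPropagationMatrix:
    def test_zero_distance_is_identity_matrix(self, grid16):
        p = ms.propagation_matrix(grid16, 3.0, 3.0).as_matrix()
        np.testing.assert_allclose(p, np.eye(grid16.n ** 2), atol=1e-12)

    def test_column_action_matches_fft_propagation(self, grid16):
        g = grid16
        p = ms.propagation_matrix(g, 0.0, g.wavelength).as_matrix()
        delta = np.zeros((g.n, g.n), complex)
        delta[3, 12] = 1.0
        col = p @ delta.ravel()
        ref = ms.angular_spectrum_propagate(
            ms.ComplexField(g, delta), g.wavelength).values.ravel()
        np.testing.assert_allclose(col, ref, atol=1e-12)

    def test_composition_of_dense_operators(self, grid16):
        g = grid16
        lam = g.wavelength
        full = ms.propagation_matrix(g, 0.0, 2 * lam).as_matrix()
        split = (ms.propagation_matrix(g, lam, 2 * lam).as_matrix()
                 @ ms.propagation_matrix(g, 0.0, lam).as_matrix())
        assert (np.linalg.norm(full - split) / np.linalg.norm(full)) < 1e-9

    def test_space_basis_matrix_is_symmetric(self, grid16):
        p = ms.propagation_matrix(grid16, 0.0, 9.7).as_matrix()
        assert np.max(np.abs(p - p.T)) < 1e-10

    def test_unitary_on_passband(self, grid16):
        g = grid16
        p = ms.propagation_matrix(g, 0.0, 5.0).as_matrix()
        f = passband_field(g, 8).values.ravel()
        assert np.linalg.norm(p @ f) == pytest.approx(np.linalg.norm(f),
                                                      rel=1e-9)


class TestGreensReference:
    def test_zero_separation_rejected(self, grid16):
        with pytest.raises(ValidationError):
            ms.greens_reference(grid16, None, 0.0)

    def test_on_axis_source_is_circularly_symmetric(self, grid16):
        gfield = ms.greens_reference(grid16, None, 5.0).values
        # point symmetry about the source: mirror offsets carry equal values
        c = grid16.n // 2
        assert np.isclose(gfield[c + 3, c], gfield[c - 3, c], atol=1e-12)
        assert np.isclose(gfield[c, c + 5], gfield[c, c - 5], atol=1e-12)
        assert np.isclose(gfield[c + 2, c + 4], gfield[c - 2, c - 4],
                          atol=1e-12)

    def test_shift_invariance(self, grid16):
        a = ms.greens_reference(grid16, (4, 6), 4.0).values
        b = ms.greens_reference(grid16, (9, 2), 4.0).values
        np.testing.assert_allclose(
            np.roll(a, (9 - 4, 2 - 6), axis=(0, 1)), b, atol=1e-13)


class TestFrequencyBasis:
    def test_identity_is_fourier_invariant(self, grid16):
        m = ms.ReflectionMatrix(values=np.eye(grid16.n ** 2), grid=grid16)
        out = ms.to_frequency_basis(m)
        np.testing.assert_allclose(out.values, np.eye(grid16.n ** 2),
                                   atol=1e-10)

    def test_round_trip_and_double_transform_error(self, grid16):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((256, 256)) \
            + 1j * rng.standard_normal((256, 256))
        m = ms.ReflectionMatrix(values=vals, grid=grid16)
        freq = ms.to_frequency_basis(m)
        with pytest.raises(ValidationError):
            ms.to_frequency_basis(freq)
        back = ms.to_space_basis(freq)
        assert np.max(np.abs(back.values - vals)) < 1e-10

    def test_phase_plate_power_preserved(self, grid16):
        rng = np.random.default_rng(4)
        phi = rng.uniform(-np.pi, np.pi, (16, 16))
        m = ms.TransmissionMatrix(values=np.diag(np.exp(1j * phi).ravel()),
                                  grid=grid16)
        freq = ms.to_frequency_basis(m)
        np.testing.assert_allclose(
            np.sum(np.abs(freq.values) ** 2, axis=1),
            np.ones(256), rtol=1e-9)

    def test_tilt_plate_shifts_the_diagonal(self, grid16):
        g = grid16
        # phase ramp advancing one lattice frequency bin per row
        ramp = np.exp(2j * np.pi * np.arange(g.n) / g.n)
        plate = np.outer(ramp, np.ones(g.n))
        m = ms.TransmissionMatrix(values=np.diag(plate.ravel()), grid=g)
        freq = ms.to_frequency_basis(m).values
        # expect a permutation: mode (kx, ky) -> (kx + 1, ky)
        perm = np.zeros_like(freq)
        idx = np.arange(g.n ** 2).reshape(g.n, g.n)
        perm[idx.ravel(), np.roll(idx, 1, axis=0).ravel()] = 1.0
        assert np.max(np.abs(np.abs(freq) - perm)) < 1e-9
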