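"""Lattice operators: tortuosity correction, diffusion, uptake, stability."""

import numpy as np
import pytest

from dopasim import (
    ConcentrationField,
    DiffusionParams,
    ParameterError,
    StabilityError,
    UptakeParams,
    apparent_diffusion,
    diffusion_step,
    max_stable_dt,
    uptake_step,
)


class TestApparentDiffusion:
    def test_striatal_value_to_four_significant_figures(self):
        assert apparent_diffusion(763.0, 1.54) == pytest.approx(321.7, abs=0.05)

    @pytest.mark.parametrize("D, lam, expected", [
        (500.0, 1.0, 500.0),     # unit tortuosity is the identity
        (100.0, 2.0, 25.0),
    ])
    def test_formula(self, D, lam, expected):
        assert apparent_diffusion(D, lam) == pytest.approx(expected)

    @pytest.mark.parametrize("D, lam", [(-1.0, 1.5), (0.0, 1.5), (763.0, 0.9)])
    def test_invalid_parameters_rejected(self, D, lam):
        with pytest.raises(ParameterError):
            apparent_diffusion(D, lam)


class TestStableDt:
    def test_micron_grid_bound(self):
        f = ConcentrationField.zeros((4, 4, 4), voxel_size=1.0)
        dt = max_stable_dt(f, DiffusionParams())
        assert dt == pytest.approx(1.0 / (6 * 321.7237308), rel=1e-6)
        assert dt == pytest.approx(5.18e-4, rel=2e-3)

    def test_nanoscale_grid_bound_allows_reported_step(self):
        # at 20 nm grain the bound is ~2.07e-7 s, just above 1.875e-7 s
        f = ConcentrationField.zeros((4, 4, 4), voxel_size=0.02)
        dt = max_stable_dt(f, DiffusionParams())
        assert dt == pytest.approx(2.07e-7, rel=2e-3)
        assert dt > 1.875e-7

    def test_quadratic_scaling_with_voxel_size(self):
        f1 = ConcentrationField.zeros((4, 4, 4), voxel_size=1.0)
        f2 = ConcentrationField.zeros((4, 4, 4), voxel_size=2.0)
        p = DiffusionParams()
        assert max_stable_dt(f2, p) == pytest.approx(4 * max_stable_dt(f1, p))


class TestDiffusion:
    def test_uniform_field_is_fixed_point(self):
        f = ConcentrationField.uniform((8, 8, 8), 1.0, 42.0)
        out = diffusion_step(f, DiffusionParams(), 1e-4)
        np.testing.assert_allclose(out.values, 42.0, rtol=1e-12)

    def test_mass_conserved_over_thousand_steps(self):
        rng = np.random.default_rng(0)
        f = ConcentrationField(rng.random((12, 12, 12)) * 100, 1.0)
        total0 = f.values.sum()
        p = DiffusionParams()
        for _ in range(1000):
            f = diffusion_step(f, p, 1e-4)
        assert f.values.sum() == pytest.approx(total0, rel=1e-10)

    def test_unstable_dt_raises_and_names_bound(self):
        f = ConcentrationField.zeros((4, 4, 4), 1.0)
        with pytest.raises(StabilityError, match="dx\\^2"):
            diffusion_step(f, DiffusionParams(), 1e-3)

    def test_point_mass_matches_gaussian_kernel(self):
        # free-space Gaussian solution oracle, no uptake, fine grid
        dx, dt, t_end = 0.25, 2e-5, 5e-3
        n = 64
        f = ConcentrationField.zeros((n, n, n), dx)
        c0 = 1e6
        f.values[n // 2, n // 2, n // 2] = c0
        p = DiffusionParams()
        for _ in range(int(round(t_end / dt))):
            f = diffusion_step(f, p, dt)
        Da = p.Da
        centre = (np.arange(n) - n // 2) * dx
        X, Y, Z = np.meshgrid(centre, centre, centre, indexing="ij")
        r2 = X**2 + Y**2 + Z**2
        exact = c0 * dx**3 / (4 * np.pi * Da * t_end) ** 1.5 \
            * np.exp(-r2 / (4 * Da * t_end))
        mask = (r2 <= 25.0) & (r2 > 0.2)
        np.testing.assert_allclose(f.values[mask], exact[mask], rtol=0.02)


class TestUptake:
    def test_half_saturation_decrement(self):
        f = ConcentrationField.uniform((4, 4, 4), 1.0, 210.0)
        out = uptake_step(f, UptakeParams(6.0, 210.0), 1e-4)
        expected = 210.0 - 0.5 * 6000.0 * 1e-4
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_zero_substrate_unchanged(self):
        f = ConcentrationField.zeros((4, 4, 4), 1.0)
        out = uptake_step(f, UptakeParams(6.0, 210.0), 1e-4)
        assert np.all(out.values == 0.0)

    def test_direct_evaluation(self):
        # 6 uM/s * 10 / (210 + 10) * 1e-4 s = 0.0272727... nM
        f = ConcentrationField.uniform((2, 2, 2), 1.0, 10.0)
        out = uptake_step(f, UptakeParams(6.0, 210.0), 1e-4)
        dec = 10.0 - out.values[0, 0, 0]
        assert dec == pytest.approx(6000.0 * 10.0 / 220.0 * 1e-4, rel=1e-10)
        assert dec == pytest.approx(0.0273, abs=1e-4)

    def test_floors_at_zero_on_overshoot(self):
        f = ConcentrationField.uniform((2, 2, 2), 1.0, 1.0)
        out = uptake_step(f, UptakeParams(6.0, 210.0), dt=1.0)  # huge step
        assert np.all(out.values == 0.0)

    def test_linear_limit_matches_first_order_decay(self):
        c = 210.0 / 100.0
        f = ConcentrationField.uniform((2, 2, 2), 1.0, c)
        dt = 1e-4
        out = uptake_step(f, UptakeParams(6.0, 210.0), dt)
        k = 6000.0 / 210.0
        dec_linear = k * c * dt
        dec = c - out.values[0, 0, 0]
        assert dec == pytest.approx(dec_linear, rel=0.011)

    def test_per_voxel_capacity_map(self):
        f = ConcentrationField.uniform((2, 2, 2), 1.0, 210.0)
        vmax = np.zeros((2, 2, 2))
        vmax[0, 0, 0] = 6.0
        out = uptake_step(f, UptakeParams(vmax, 210.0), 1e-4)
        assert out.values[0, 0, 0] < 210.0
        assert np.all(out.values.reshape(-1)[1:] == 210.0)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            UptakeParams(-1.0, 210.0)
        with pytest.raises(ParameterError):
            UptakeParams(6.0, 0.0)


def test_composed_steps_preserve_non_negativity():
    rng = np.random.default_rng(3)
    f = ConcentrationField(rng.random((10, 10, 10)) * 5.0, 1.0)
    dp, up = DiffusionParams(), UptakeParams(6.0, 210.0)
    for _ in range(200):
        f = diffusion_step(uptake_step(f, up, 1e-4), dp, 1e-4)
    assert f.values.min() >= 0.0


def test_fused_engine_matches_composed_operators():
    """The fused integration kernel used by the experiment engine performs
    exactly uptake followed by diffusion (bitwise)."""
    from dopasim import _kernels

    rng = np.random.default_rng(7)
    C = rng.random((9, 9, 9)) * 300.0
    ref = ConcentrationField(C.copy(), 1.0)
    dp, up = DiffusionParams(), UptakeParams(6.0, 210.0)
    dt = 1e-4
    n_steps = 5
    for _ in range(n_steps):
        ref = diffusion_step(uptake_step(ref, up, dt), dp, dt)

    buf = np.empty_like(C)
    ev = np.zeros(0, dtype=np.int64)
    probe = np.zeros(1, dtype=np.int64)
    out_mean = np.zeros(n_steps)
    out_probe = np.zeros((n_steps, 1))
    alpha = dp.Da * dt / 1.0
    got, _, _, _ = _kernels.run_lattice_chunk(
        C, buf, alpha, 6.0 * 1e3 * dt, 210.0, 0.0, ev, ev, 0, 0, n_steps, 1,
        probe, out_mean, out_probe, 0)
    np.testing.assert_array_equal(got, ref.values)


def test_field_validation():
    with pytest.raises(ParameterError):
        ConcentrationField(np.full((3, 3, 3), -1.0), 1.0)
    with pytest.raises(ParameterError):
        ConcentrationField(np.zeros((3, 3)), 1.0)
    with pytest.raises(ParameterError):
        ConcentrationField(np.zeros((3, 3, 3)), 1.0, boundary="dirichlet")
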