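"""Release sites, Poisson firing, quantal increments, and event building."""

import numpy as np
import pytest
from scipy.constants import Avogadro

from dopasim import (
    ConcentrationField,
    FiringProtocol,
    ParameterError,
    PauseSegment,
    ReleaseParams,
    TrainSegment,
    apply_release,
    place_sites,
    quantal_concentration,
    sample_spikes,
)
from dopasim.release import build_release_events


class TestQuantalConcentration:
    def test_micron_voxel_with_volume_fraction(self):
        # 3000 molecules into the 21% extracellular share of 1 µm³
        expected = 3000 / Avogadro / (0.21 * 1e-15) * 1e-9 * 1e18  # nM
        got = quantal_concentration(3000, 1.0, 0.21)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(23.7e3, rel=1e-3)

    def test_without_volume_fraction(self):
        assert quantal_concentration(3000, 1.0, 1.0) == pytest.approx(4.98e3, rel=1e-3)

    def test_linearity_in_quantal_size(self):
        assert quantal_concentration(6000, 1.0, 0.21) == pytest.approx(
            2 * quantal_concentration(3000, 1.0, 0.21))

    def test_invalid(self):
        with pytest.raises(ParameterError):
            quantal_concentration(0, 1.0, 0.21)
        with pytest.raises(ParameterError):
            quantal_concentration(3000, 1.0, 0.0)


class TestPlaceSites:
    def test_count_within_binomial_bounds(self):
        m = place_sites((50, 50, 50), 1.0, 0.04, 150, rng=0)
        mean, sd = 5000.0, np.sqrt(125000 * 0.04 * 0.96)
        assert abs(m.n_sites - mean) < 3 * sd
        assert m.neuron_of_site.min() >= 0
        assert m.neuron_of_site.max() < 150

    def test_large_space_reaches_forty_thousand_sites(self):
        m = place_sites((100, 100, 100), 1.0, 0.04, 150, rng=1)
        assert abs(m.n_sites - 40000) < 3 * np.sqrt(1e6 * 0.04 * 0.96)

    def test_zero_density_empty(self):
        m = place_sites((10, 10, 10), 1.0, 0.0, 150, rng=0)
        assert m.n_sites == 0

    def test_at_most_one_site_per_voxel(self):
        m = place_sites((8, 8, 8), 1.0, 0.5, 10, rng=0)
        assert len(np.unique(m.flat_indices())) == m.n_sites

    def test_density_above_one_per_voxel_rejected(self):
        with pytest.raises(ParameterError):
            place_sites((10, 10, 10), 1.0, 1.5, 150, rng=0)

    def test_reproducible_under_seed(self):
        a = place_sites((20, 20, 20), 1.0, 0.04, 150, rng=42)
        b = place_sites((20, 20, 20), 1.0, 0.04, 150, rng=42)
        np.testing.assert_array_equal(a.site_voxels, b.site_voxels)
        np.testing.assert_array_equal(a.neuron_of_site, b.neuron_of_site)

    def test_active_fraction(self):
        m = place_sites((30, 30, 30), 1.0, 0.1, 50, rng=0, active_fraction=0.3)
        frac = m.active_mask.mean()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / m.n_sites)


class TestSampleSpikes:
    def test_poisson_totals(self):
        proto = FiringProtocol(4.0, 10.0)
        steps, neurons = sample_spikes(proto, 150, 1e-4, rng=0)
        # mean 6000 spikes, Poisson sd ~77
        assert abs(len(steps) - 6000) < 3 * np.sqrt(6000)
        assert np.all(np.diff(steps) >= 0)

    def test_zero_rate_empty(self):
        steps, _ = sample_spikes(FiringProtocol(1e-12, 10.0), 150, 1e-4, rng=0)
        assert len(steps) <= 1  # rate ~0: essentially no spikes

    def test_pause_silences_window(self):
        proto = FiringProtocol(50.0, 3.0, [PauseSegment(1.0, 1.0)])
        steps, _ = sample_spikes(proto, 20, 1e-4, rng=0)
        t = steps * 1e-4
        assert np.count_nonzero((t >= 1.0) & (t < 2.0)) == 0
        assert np.count_nonzero(t < 1.0) > 0

    def test_train_delivers_exact_pulses_to_every_neuron(self):
        proto = FiringProtocol(0.0 + 1e-12, 3.0, [TrainSegment(0.5, 120, 60.0)])
        steps, neurons = sample_spikes(proto, 5, 1e-4, rng=0)
        assert len(steps) == 120 * 5
        t = steps * 1e-4
        assert t.min() == pytest.approx(0.5, abs=1e-3)
        assert t.max() == pytest.approx(0.5 + 119 / 60.0, abs=1e-3)


class TestRelease:
    def _sites(self):
        return place_sites((10, 10, 10), 1.0, 0.04, 5, rng=0)

    def test_zero_probability_leaves_field_unchanged(self):
        f = ConcentrationField.zeros((10, 10, 10), 1.0)
        out = apply_release(f, self._sites(), [0, 1, 2],
                            ReleaseParams(r_pct=0.0), rng=0)
        assert np.all(out.values == 0.0)

    def test_certain_release_single_site(self):
        sites = place_sites((10, 10, 10), 1.0, 0.05, 1, rng=3)
        assert sites.n_sites >= 1
        f = ConcentrationField.zeros((10, 10, 10), 1.0)
        out = apply_release(f, sites, [0], ReleaseParams(r_pct=1.0), rng=0)
        q = ReleaseParams().q_conc_nM(1.0)
        # every active site of the spiking neuron released exactly once
        n_active = int(sites.active_mask.sum())
        assert np.count_nonzero(out.values) == n_active
        assert out.values.sum() == pytest.approx(n_active * q)

    def test_flux_matches_closed_form(self):
        # time-averaged added concentration = Q_conc * f * R * density * v
        sites = place_sites((20, 20, 20), 1.0, 0.04, 150, rng=1)
        proto = FiringProtocol(4.0, 20.0)
        steps, neurons = sample_spikes(proto, 150, 1e-4, rng=2)
        ev_steps, ev_vox = build_release_events(sites, steps, neurons, 0.06, rng=3)
        q = ReleaseParams().q_conc_nM(1.0)
        flux = len(ev_steps) * q / 8000.0 / 20.0
        expected = q * 4.0 * 0.06 * 0.04
        n_exp = expected * 8000 * 20.0 / q
        tol = 4 * np.sqrt(n_exp) / n_exp
        assert flux == pytest.approx(expected, rel=tol)
        assert expected == pytest.approx(227.7, rel=1e-3)

    def test_events_only_at_active_sites_of_spiking_neurons(self):
        sites = self._sites()
        sites.active_mask[:] = False
        ev_steps, ev_vox = build_release_events(
            sites, np.zeros(10, np.int64), np.zeros(10, np.int64), 1.0, rng=0)
        assert len(ev_steps) == 0

    def test_event_stream_reproducible(self):
        sites = self._sites()
        steps = np.arange(50, dtype=np.int64)
        neurons = np.arange(50, dtype=np.int64) % 5
        a = build_release_events(sites, steps, neurons, 0.5, rng=9)
        b = build_release_events(sites, steps, neurons, 0.5, rng=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


def test_protocol_validation():
    with pytest.raises(ParameterError):
        FiringProtocol(-1.0, 10.0)
    with pytest.raises(ParameterError):
        FiringProtocol(4.0, 10.0, [PauseSegment(1.0, 2.0), PauseSegment(2.5, 1.0)])


def test_sites_in_cube_geometry():
    sites = place_sites((30, 30, 30), 1.0, 0.2, 10, rng=0)
    mask = sites.sites_in_cube((15.0, 15.0, 15.0), 10.0)
    pos = (sites.site_voxels + 0.5) * 1.0
    inside = np.all(np.abs(pos - 15.0) <= 5.0, axis=1)
    np.testing.assert_array_equal(mask, inside)
    assert 0 < mask.sum() < sites.n_sites
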