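"""Monte Carlo kernel: Compton sampling, attenuation limits, reproducibility."""
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chi2 as chi2_dist

from skyshine import _kernel
from skyshine.geometry import CylinderShieldGeometry
from skyshine.source import BeamSource, BeamSpectrum
from skyshine.tally import RingTallySet
from skyshine.transport import (PhotonState, RunConfig, _XsPack,
                                compton_scatter, run, step_history)
from skyshine.xsdata import load_material

from conftest import absorber_tables

MEC2 = 0.51099895


def kn_pdf(energy, cost):
    """Unnormalized Klein-Nishina pdf in cos(theta) (quadrature oracle)."""
    r = 1.0 / (1.0 + (energy / MEC2) * (1.0 - cost))
    return r * r * (r + 1.0 / r - (1.0 - cost * cost))




class TestComptonScatter:
    def test_backscatter_kinematics_closed_form(self):
        """E' at 180 degrees: 10 MeV -> 10/(1+20/0.511) ~ 0.249 MeV."""
        e_min = 10.0 / (1.0 + 2.0 * 10.0 / MEC2)
        assert e_min == pytest.approx(0.249, abs=0.001)
        e_out, cost = _kernel.sample_compton_batch(10.0, 50_000, 3)
        assert e_out.min() >= e_min - 1e-12
        # sampled energies obey the Compton relation for their angle
        e_kin = 10.0 / (1.0 + (10.0 / MEC2) * (1.0 - cost))
        np.testing.assert_allclose(e_out, e_kin, rtol=1e-10)

    def test_energy_never_increases(self):
        for e in (0.02, 0.1, 1.0, 6.0, 18.0):
            e_out, _ = _kernel.sample_compton_batch(e, 20_000, 11)
            assert e_out.max() <= e + 1e-12
            assert e_out.min() >= e / (1.0 + 2.0 * e / MEC2) - 1e-12

    @pytest.mark.parametrize("energy", [0.05, 1.0, 6.0])
    def test_mean_cos_matches_quadrature(self, energy):
        n = 200_000
        _, cost = _kernel.sample_compton_batch(energy, n, 42)
        norm = quad(lambda c: kn_pdf(energy, c), -1, 1)[0]
        mean = quad(lambda c: c * kn_pdf(energy, c), -1, 1)[0] / norm
        assert abs(cost.mean() - mean) < 3 * cost.std() / math.sqrt(n)

    def test_low_energy_limit_is_thomson_like(self):
        """As E -> 0 the angular distribution approaches the symmetric
        Thomson form; at 10 keV the mean cosine is already < 0.03."""
        _, cost = _kernel.sample_compton_batch(0.01, 200_000, 5)
        norm = quad(lambda c: kn_pdf(0.01, c), -1, 1)[0]
        mean = quad(lambda c: c * kn_pdf(0.01, c), -1, 1)[0] / norm
        assert mean < 0.03
        assert abs(cost.mean() - mean) < 3 * cost.std() / math.sqrt(len(cost))

    def test_chi2_against_quadrature(self):
        """Sampled angles at 1 MeV match KN quadrature (chi^2, 20 bins)."""
        energy, n = 1.0, 1_000_000
        _, cost = _kernel.sample_compton_batch(energy, n, 7)
        bins = np.linspace(-1, 1, 21)
        obs, _ = np.histogram(cost, bins)
        norm = quad(lambda c: kn_pdf(energy, c), -1, 1)[0]
        expect = np.array([quad(lambda c: kn_pdf(energy, c), a, b)[0]
                           for a, b in zip(bins[:-1], bins[1:])]) / norm * n
        chi2 = float(((obs - expect) ** 2 / expect).sum())
        assert chi2_dist.sf(chi2, len(obs) - 1) > 0.01

    def test_python_wrapper(self):
        e_new, theta, phi = compton_scatter(1.0, 123)
        assert 0 < e_new <= 1.0
        assert 0 <= theta <= math.pi and 0 <= phi < 2 * math.pi
        with pytest.raises(ValueError):
            compton_scatter(0.005, 1)


class TestStepHistory:
    def test_beer_lambert_transmission(self):
        """Pencil beam in a pure absorber: survival e^{-mu L} within 3 sigma."""
        geom = CylinderShieldGeometry(
            d_w=0.02, wall_thickness=0.01, h=0.01, isocenter_height=0.0,
            world_radius=500.0, world_height=100.0, ground_depth=-0.01)
        tables = absorber_tables()
        src = BeamSource(BeamSpectrum.monoenergetic(1.0), position_z=0.0,
                         field_area_f0=0.0)
        cfg = RunConfig(n_histories=40_000, seed=9, tally_height=200.0,
                        n_rings=2, ground_kill=True)
        res = run(cfg, geom, src, tables=tables)
        mu = 0.06354 * 1.225e-3 * 100.0  # 1 MeV air, per metre
        p_surv = math.exp(-mu * 100.0)
        n_esc = res.kill_counts["escaped"]
        sigma = math.sqrt(cfg.n_histories * p_surv * (1 - p_surv))
        assert abs(n_esc - cfg.n_histories * p_surv) < 3 * sigma

    def test_vacuum_world_photon_escapes_with_zero_scores(self):
        geom = CylinderShieldGeometry(
            d_w=0.02, wall_thickness=0.01, h=0.01, isocenter_height=0.0,
            world_radius=100.0, world_height=100.0)
        air = load_material("air", density=1e-300)
        conc = load_material("concrete").with_density(1e-300)
        tables = _XsPack(air, conc)
        t = RingTallySet(z=50.0, dr=0.5, n_rings=10)
        ph = PhotonState(np.zeros(3), np.array([1.0, 0, 0]), 1.0)
        ph, reason = step_history(ph, geom, tables, t, rng=4)
        assert reason == "escaped"
        assert t.kerma.sum() == 0.0
        assert not ph.alive

    def test_scatter_limit_kills_at_next_interaction(self):
        geom = CylinderShieldGeometry.vault(d_w=5.0, h=3.0)
        src = BeamSource(BeamSpectrum.monoenergetic(2.0), position_z=0.3,
                         field_area_f0=0.0)
        cfg = RunConfig(n_histories=20_000, seed=3, scatter_limit=1,
                        ground_kill=True, n_rings=60)
        res = run(cfg, geom, src)
        assert res.kill_counts["scatter_limit"] > 0
        # no history may survive two interactions: photoelectric+pair+limit+
        # cutoff+ground+escape account for everything
        assert sum(res.kill_counts.values()) == cfg.n_histories


class TestRunContract:
    def _small_run(self, seed, n=30_000):
        geom = CylinderShieldGeometry.silo()
        src = BeamSource(BeamSpectrum.co60(), position_z=2.0, isotropic=True)
        cfg = RunConfig(n_histories=n, seed=seed, air_density=1.12e-3,
                        tally_height=1.0, n_rings=60)
        return run(cfg, geom, src)

    def test_same_seed_bit_identical(self):
        a = self._small_run(21)
        b = self._small_run(21)
        np.testing.assert_array_equal(a.kerma_per_photon, b.kerma_per_photon)
        np.testing.assert_array_equal(a.stderr, b.stderr)
        assert a.kill_counts == b.kill_counts

    def test_different_seed_differs(self):
        a = self._small_run(21)
        b = self._small_run(22)
        assert not np.array_equal(a.kerma_per_photon, b.kerma_per_photon)

    def test_stderr_scales_like_sqrt_n(self):
        """Quadrupling histories roughly halves the batch standard error."""
        a = self._small_run(31, n=25_000)
        b = self._small_run(31, n=100_000)
        sel = (a.counts > 50) & (b.counts > 50)
        ratio = np.median(a.stderr[sel] / b.stderr[sel])
        assert ratio == pytest.approx(2.0, rel=0.35)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            RunConfig(n_histories=1, n_batches=2)


class TestTallyAgainstAnalyticFlux:
    def test_inverse_square_point_source(self):
        """Isotropic source in near-vacuum: ring fluence is 1/(4 pi d^2)."""
        geom = CylinderShieldGeometry(
            d_w=0.011, wall_thickness=0.01, h=0.02, isocenter_height=0.0,
            world_radius=3000.0, world_height=3000.0, ground_depth=-0.001)
        tables = _XsPack(load_material("air", density=1e-12),
                         load_material("concrete"))
        src = BeamSource(BeamSpectrum.monoenergetic(1.0), position_z=11.0,
                         isotropic=True)
        cfg = RunConfig(n_histories=400_000, seed=5, tally_height=1.0,
                        ring_width=0.5, n_rings=40, ground_kill=True)
        t = RingTallySet(z=1.0, dr=0.5, n_rings=40)
        run(cfg, geom, src, tallies=t, tables=tables)
        height = 10.0
        for i in (4, 10, 20):
            r0, r1 = i * 0.5, (i + 1) * 0.5
            area = math.pi * (r1 ** 2 - r0 ** 2)
            flux = quad(lambda r: r / (4 * math.pi * (r * r + height ** 2)),
                        r0, r1)[0] * 2 * math.pi / area
            mc = t.phi[i] / cfg.n_histories
            sigma = mc / math.sqrt(max(t.count[i], 1.0))
            assert abs(mc - flux) < 3.5 * sigma
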