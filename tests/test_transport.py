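import math

import numpy as np
import pytest
from scipy import stats

from mcbacksim import (
    FluxAccumulator,
    MediaOptics,
    PhotonState,
    SimulationConfig,
    derive_optics,
    make_launch_streams,
    make_trajectory_streams,
    refraction_angle,
    run_simulation,
    trace_photon,
)
from mcbacksim.transport import absorb, bounce, launch, move, scatter


def _state(**kw):
    defaults = dict(x=0.0, y=0.0, z=0.5, u=0.0, v=0.0, w=1.0, weight=1.0)
    defaults.update(kw)
    return PhotonState(**defaults)


class TestLaunch:
    def test_normal_incidence(self, phantom_iso, small_cfg):
        derived = derive_optics(phantom_iso, small_cfg)
        beam = refraction_angle(0.0, phantom_iso.n)
        ls = make_launch_streams(small_cfg)
        st = launch(0, beam, ls, derived)
        assert (st.u, st.v, st.w) == (0.0, 0.0, 1.0)
        assert st.z == 0.0
        assert math.hypot(st.x, st.y) <= small_cfg.beam_radius + 1e-12

    def test_weight_is_one_minus_specular(self, apple, small_cfg):
        derived = derive_optics(apple, small_cfg)
        beam = refraction_angle(0.0, apple.n)
        ls = make_launch_streams(small_cfg)
        st = launch(5, beam, ls, derived)
        assert st.weight == pytest.approx(1 - (0.4 / 2.4) ** 2, rel=1e-12)
        assert st.weight == pytest.approx(0.97222, abs=1e-5)

    def test_oblique_direction_and_stretch(self, small_cfg):
        media = MediaOptics(mu_a=0.63, mu_s=30.0, g=0.0, n=1.4)
        derived = derive_optics(media, small_cfg)
        beam = refraction_angle(15.0, media.n)
        assert math.degrees(beam.phi2) == pytest.approx(10.65, abs=0.01)
        ls = make_launch_streams(small_cfg)
        st = launch(0, beam, ls, derived)
        assert st.w == pytest.approx(math.cos(beam.phi2), rel=1e-12)
        assert st.v == pytest.approx(math.sin(beam.phi2), rel=1e-12)
        assert st.u == 0.0

    def test_elliptic_footprint_variance_ratio(self):
        # var(y)/var(x) = 1/cos^2(phi2) for the tilted beam footprint
        cfg = SimulationConfig(n_photons=10**5, beam_radius=0.05, limit=1e-9,
                               obs_radius=3, rpx=0.05, seed=8, incident_angle_deg=20.0)
        beam = refraction_angle(20.0, 1.4)
        ls = make_launch_streams(cfg)
        x = ls.rbr * np.cos(ls.rba)
        y = ls.rbr * np.sin(ls.rba) / math.cos(beam.phi2)
        ratio = np.var(y) / np.var(x)
        assert ratio == pytest.approx(1 / math.cos(beam.phi2) ** 2, rel=0.05)


class TestMove:
    def test_closed_form_step(self):
        st = _state()
        move(st, 30.63, math.exp(-1.0))
        assert st.z == pytest.approx(0.5 + 1 / 30.63, rel=1e-12)

    def test_mean_free_path(self):
        rng = np.random.default_rng(4)
        mu_t = 2.6346
        draws = rng.random(20000)
        steps = -np.log(draws) / mu_t
        se = (1 / mu_t) / np.sqrt(draws.size)  # exponential: std = mean
        assert abs(steps.mean() - 1 / mu_t) < 3 * se

    def test_zero_deviate_clamped(self):
        st = _state()
        move(st, 10.0, 0.0)
        assert np.isfinite(st.z)


class TestBounce:
    def _derived(self, n, small_cfg):
        media = MediaOptics(mu_a=0.1056, mu_s=2.529, g=0.0, n=n)
        return derive_optics(media, small_cfg)

    def test_matched_boundary_full_escape(self, small_cfg):
        derived = self._derived(1.0, small_cfg)
        acc = FluxAccumulator.empty(small_cfg.n_bins)
        st = _state(z=-0.01, w=-0.6, v=0.8, weight=0.5)
        bounce(st, derived, acc, small_cfg.rpx)
        assert acc.rd == pytest.approx(0.5)
        assert st.weight == pytest.approx(0.0)
        assert st.z == 0.01 and st.w == 0.6

    def test_total_internal_reflection(self, small_cfg):
        derived = self._derived(1.35, small_cfg)
        acc = FluxAccumulator.empty(small_cfg.n_bins)
        st = _state(z=-0.01, w=-0.5, v=math.sqrt(1 - 0.25), weight=0.8)
        bounce(st, derived, acc, small_cfg.rpx)
        assert st.weight == 0.8
        assert acc.rd == 0.0
        assert acc.heat.sum() == 0.0

    def test_normal_exit_fresnel_and_lambertian(self, small_cfg):
        # w = 1: both polarizations give rf = ((1-n)/(1+n))^2, Lambertian = 1
        derived = self._derived(1.35, small_cfg)
        acc = FluxAccumulator.empty(small_cfg.n_bins)
        st = _state(x=0.1, y=0.0, z=-0.001, u=0.0, v=0.0, w=-1.0, weight=1.0)
        bounce(st, derived, acc, small_cfg.rpx)
        rf = ((1 - 1.35) / (1 + 1.35)) ** 2
        assert rf == pytest.approx(0.02218, abs=1e-5)
        assert acc.rd == pytest.approx(1 - rf, rel=1e-9)
        k = round(0.1 / small_cfg.rpx)
        assert acc.heat[k] == pytest.approx(1 - rf, rel=1e-9)  # lcc = 1
        assert st.weight == pytest.approx(rf, rel=1e-9)

    def test_escape_beyond_window_counts_toward_rd(self, small_cfg):
        derived = self._derived(1.0, small_cfg)
        acc = FluxAccumulator.empty(small_cfg.n_bins)
        st = _state(x=5.0, y=0.0, z=-0.001, w=-1.0, v=0.0, weight=1.0)
        bounce(st, derived, acc, small_cfg.rpx)
        assert acc.rd == pytest.approx(1.0)
        assert acc.heat.sum() == 0.0

    def test_contract_violation(self, small_cfg):
        derived = self._derived(1.35, small_cfg)
        acc = FluxAccumulator.empty(small_cfg.n_bins)
        with pytest.raises(ValueError):
            bounce(_state(z=0.1), derived, acc, small_cfg.rpx)


class TestAbsorb:
    def test_apple_albedo_split(self, apple, small_cfg):
        derived = derive_optics(apple, small_cfg)
        acc = FluxAccumulator.empty(small_cfg.n_bins)
        st = _state(weight=1.0)
        absorb(st, derived, acc, small_cfg.limit)
        assert st.weight == pytest.approx(0.979432, abs=1e-6)
        assert acc.absorbed == pytest.approx(0.020568, abs=1e-6)

    def test_termination_scores_residual(self, apple, small_cfg):
        derived = derive_optics(apple, small_cfg)
        acc = FluxAccumulator.empty(small_cfg.n_bins)
        st = _state(weight=1.01e-9)  # albedo attenuation drops it below limit
        absorb(st, derived, acc, small_cfg.limit)
        assert not st.alive
        assert st.weight == 0.0
        # absorbed-fraction split plus terminal residual account for everything
        assert acc.absorbed == pytest.approx(1.01e-9, rel=1e-9)

    def test_conservative_medium_no_absorption(self, small_cfg):
        media = MediaOptics(mu_a=0.0, mu_s=10.0, g=0.0, n=1.4)
        derived = derive_optics(media, small_cfg)
        acc = FluxAccumulator.empty(small_cfg.n_bins)
        st = _state(weight=0.7)
        absorb(st, derived, acc, small_cfg.limit)
        assert st.weight == 0.7
        assert acc.absorbed == 0.0


class TestScatter:
    def test_rejects_pair_outside_disc(self):
        assert scatter(_state(), 0.0, 0.5, 0.9, 0.9) is None

    def test_isotropic_cosine_uniform(self):
        rng = np.random.default_rng(12)
        cos_ts = []
        for _ in range(4000):
            st = _state()
            res = None
            while res is None:
                res = scatter(st, 0.0, rng.random(),
                              2 * rng.random() - 1, 2 * rng.random() - 1)
            cos_ts.append(st.w)  # from w=1, degenerate update gives w = cos(theta)
        p = stats.kstest(cos_ts, stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > 0.01

    def test_hg_mean_cosine_equals_g(self):
        rng = np.random.default_rng(13)
        g = 0.9
        cos_ts = []
        for _ in range(20000):
            st = _state()
            res = None
            while res is None:
                res = scatter(st, g, rng.random(),
                              2 * rng.random() - 1, 2 * rng.random() - 1)
            cos_ts.append(st.w)
        # HG variance = 1 + g^2 - ... bounded by 1; use sample SE
        se = np.std(cos_ts) / np.sqrt(len(cos_ts))
        assert abs(np.mean(cos_ts) - g) < 3 * se

    def test_direction_norm_preserved(self):
        rng = np.random.default_rng(14)
        for _ in range(300):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            st = _state(u=v[0], v=v[1], w=v[2])
            res = None
            while res is None:
                res = scatter(st, 0.7, rng.random(),
                              2 * rng.random() - 1, 2 * rng.random() - 1)
            assert st.u**2 + st.v**2 + st.w**2 == pytest.approx(1.0, abs=1e-9)


class TestTracePhoton:
    def _run_one(self, media, cfg, idx=0):
        derived = derive_optics(media, cfg)
        beam = refraction_angle(cfg.incident_angle_deg, media.n)
        ls = make_launch_streams(cfg)
        acc = FluxAccumulator.empty(cfg.n_bins)
        ts = make_trajectory_streams(derived, cfg.seed, idx)
        trace_photon(idx, beam, ls, ts, derived, cfg, acc, media.g)
        return acc

    def test_energy_accounted(self, phantom_iso, small_cfg):
        acc = self._run_one(phantom_iso, small_cfg)
        assert acc.balance_residual == pytest.approx(0.0, abs=1e-9)

    def test_absorbing_limit(self, small_cfg):
        media = MediaOptics(mu_a=500.0, mu_s=0.5, g=0.0, n=1.4)
        acc = self._run_one(media, small_cfg)
        assert acc.rd < 1e-3


class TestRunSimulation:
    def test_zero_photons(self, phantom_iso):
        cfg = SimulationConfig(n_photons=0, beam_radius=0.05, limit=1e-9,
                               obs_radius=3, rpx=0.05)
        acc = run_simulation(phantom_iso, cfg)
        assert acc.rd == 0.0 and acc.heat.sum() == 0.0 and acc.n_launched == 0

    @pytest.mark.parametrize("engine", ["python", "kernel"])
    def test_deterministic_for_fixed_seed(self, phantom_iso, engine):
        cfg = SimulationConfig(n_photons=300, beam_radius=0.05, limit=1e-9,
                               obs_radius=3, rpx=0.05, seed=21)
        a = run_simulation(phantom_iso, cfg, engine=engine)
        b = run_simulation(phantom_iso, cfg, engine=engine)
        np.testing.assert_array_equal(a.heat, b.heat)
        assert a.rd == b.rd and a.absorbed == b.absorbed

    @pytest.mark.parametrize("engine", ["python", "kernel"])
    def test_energy_conservation(self, phantom_iso, engine):
        cfg = SimulationConfig(n_photons=500, beam_radius=0.05, limit=1e-9,
                               obs_radius=3, rpx=0.05, seed=3)
        acc = run_simulation(phantom_iso, cfg, engine=engine)
        assert abs(acc.balance_residual) / cfg.n_photons < 1e-6

    def test_engines_agree_statistically(self, phantom_iso):
        """The compiled kernel and the scalar reference path sample the same
        physics; their total diffuse reflectance must agree within MC error."""
        cfg = SimulationConfig(n_photons=4000, beam_radius=0.05, limit=1e-9,
                               obs_radius=3, rpx=0.05, seed=17)
        a = run_simulation(phantom_iso, cfg, engine="python")
        b = run_simulation(phantom_iso, cfg, engine="kernel")
        # per-photon escaped weight has std <~ 0.5
        se = 0.5 / math.sqrt(cfg.n_photons)
        assert abs(a.rd - b.rd) / cfg.n_photons < 5 * se

    def test_rd_monotone_in_albedo(self):
        """Less absorption -> more light escapes, at every seed tested."""
        cfg_base = dict(beam_radius=0.05, limit=1e-9, obs_radius=3, rpx=0.05)
        for seed in (1, 2, 3):
            rds = []
            for mu_a in (2.0, 0.5, 0.05):
                media = MediaOptics(mu_a=mu_a, mu_s=2.529, g=0.0, n=1.35)
                cfg = SimulationConfig(n_photons=3000, seed=seed, **cfg_base)
                acc = run_simulation(media, cfg)
                rds.append(acc.rd)
            assert rds == sorted(rds)

    def test_weight_tallies_nonnegative(self, phantom_aniso):
        cfg = SimulationConfig(n_photons=1000, beam_radius=0.05, limit=1e-9,
                               obs_radius=3, rpx=0.05, seed=5)
        acc = run_simulation(phantom_aniso, cfg)
        assert np.all(acc.heat >= 0)
        assert np.all(acc.heat_rd >= acc.heat)  # Lambertian factor <= 1
        assert acc.rd >= acc.heat_rd.sum()  # escapes beyond window not binned

    def test_roulette_mode_agrees(self, phantom_iso):
        cfg = SimulationConfig(n_photons=3000, beam_radius=0.05, limit=1e-6,
                               obs_radius=3, rpx=0.05, seed=9)
        a = run_simulation(phantom_iso, cfg)
        b = run_simulation(phantom_iso, cfg, roulette=True)
        se = 0.5 / math.sqrt(cfg.n_photons)
        assert abs(a.rd - b.rd) / cfg.n_photons < 5 * se
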