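"""Compiled Monte Carlo kernel for production photon counts.

Same physics as the scalar reference in :mod:`mcbacksim.transport`, in a
single numba-compiled loop over photons.  Trajectory randomness is drawn
on demand from one PCG64 generator seeded from the run seed (photon-major
order), so results are deterministic for a fixed seed but lie on a
different random stream layout than the per-photon sub-streams of the
reference path: the two engines agree statistically, not bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .optics import BeamGeometry, DerivedOptics, MediaOptics, SimulationConfig
from .streams import LaunchStreams
from .transport import ROULETTE_CHANCE, FluxAccumulator

__all__ = ["run_kernel"]

# Spawn-key domain for the kernel's trajectory generator, disjoint from
# the launch and per-photon stream domains in mcbacksim.streams.
_KERNEL_DOMAIN = 2


@njit(cache=False)
def _simulate(
    gen,
    rbr,
    rba,
    sin_phi2,
    cos_phi2,
    mu_t,
    albedo,
    rs,
    cangle,
    n,
    g,
    limit,
    maxlen,
    rpx,
    heat,
    heat_rd,
    roulette,
):  # pragma: no cover - exercised through run_kernel
    rd = 0.0
    absorbed = 0.0
    n_photons = rbr.size
    tiny = 2.2250738585072014e-308
    hard_cap = maxlen if not roulette else 100 * maxlen
    for i in range(n_photons):
        # launch
        x = rbr[i] * np.cos(rba[i])
        y = rbr[i] * np.sin(rba[i]) / cos_phi2
        z = 0.0
        u = 0.0
        v = sin_phi2
        w = cos_phi2
        weight = 1.0 - rs
        alive = True
        for _ in range(hard_cap):
            # move
            xi = gen.random()
            if xi <= 0.0:
                xi = tiny
            s = -np.log(xi) / mu_t
            x += s * u
            y += s * v
            z += s * w
            # bounce
            if z < 0.0:
                w = -w
                z = -z
                if w > cangle:
                    t = np.sqrt(1.0 - (1.0 - w * w) * n * n)
                    temp1 = (w - n * t) / (w + n * t)
                    temp = (t - n * w) / (t + n * w)
                    rf = (temp1 * temp1 + temp * temp) / 2.0
                    escaped = (1.0 - rf) * weight
                    rd += escaped
                    lcc = np.abs(w) / np.sqrt(u * u + v * v + w * w)
                    lcc = n * np.sqrt(1.0 - lcc * lcc)
                    if lcc * lcc > 1.0:
                        lcc = 0.0
                    else:
                        lcc = np.sqrt(1.0 - lcc * lcc)
                    k = int(np.rint(np.sqrt(x * x + y * y) / rpx))
                    if k < heat.size:
                        heat[k] += lcc * escaped
                        heat_rd[k] += escaped
                    weight -= escaped
            # absorb
            absorbed += weight * (1.0 - albedo)
            weight *= albedo
            if weight < limit:
                rabs = gen.random()
                if roulette and rabs < ROULETTE_CHANCE:
                    weight /= ROULETTE_CHANCE
                else:
                    absorbed += weight
                    alive = False
                    break
            else:
                gen.random()  # rabs survival deviate, unused by the cutoff
            # scatter
            while True:
                x1 = 2.0 * gen.random() - 1.0
                x2 = 2.0 * gen.random() - 1.0
                rho2 = x1 * x1 + x2 * x2
                if 0.0 < rho2 <= 1.0:
                    break
            rho = np.sqrt(rho2)
            cos_phi = x1 / rho
            sin_phi = x2 / rho
            rmu = gen.random()
            if g == 0.0:
                cos_t = 2.0 * rmu - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * rmu)
                cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            if cos_t > 1.0:
                cos_t = 1.0
            elif cos_t < -1.0:
                cos_t = -1.0
            sin_t = np.sqrt(1.0 - cos_t * cos_t)
            if np.abs(w) > 0.99999:
                u = sin_t * cos_phi
                v = sin_t * sin_phi
                w = cos_t if w >= 0.0 else -cos_t
            else:
                denom = np.sqrt(1.0 - w * w)
                u_new = sin_t * (u * w * cos_phi - v * sin_phi) / denom + u * cos_t
                v_new = sin_t * (v * w * cos_phi + u * sin_phi) / denom + v * cos_t
                w_new = -sin_t * cos_phi * denom + w * cos_t
                u, v, w = u_new, v_new, w_new
        if alive:
            absorbed += weight
    return rd, absorbed


def run_kernel(
    media: MediaOptics,
    cfg: SimulationConfig,
    beam: BeamGeometry,
    derived: DerivedOptics,
    launch_streams: LaunchStreams,
    acc: FluxAccumulator,
    roulette: bool = False,
) -> None:
    """Simulate all photons with the compiled kernel, updating ``acc``."""
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(_KERNEL_DOMAIN,))
    gen = np.random.Generator(np.random.PCG64(ss))
    rd, absorbed = _simulate(
        gen,
        launch_streams.rbr,
        launch_streams.rba,
        np.sin(beam.phi2),
        np.cos(beam.phi2),
        derived.mu_t,
        derived.albedo,
        derived.rs,
        derived.cangle,
        derived.n,
        media.g,
        cfg.limit,
        derived.maxlen,
        cfg.rpx,
        acc.heat,
        acc.heat_rd,
        roulette,
    )
    acc.rd += rd
    acc.absorbed += absorbed
    acc.specular += derived.rs * cfg.n_photons
    acc.n_launched += cfg.n_photons
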