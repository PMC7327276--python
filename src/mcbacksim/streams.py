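"""Seedable random-number streams for photon launch and trajectory sampling.

All randomness in a run descends from a single root seed.  Launch
coordinates (one pair per photon) are drawn in bulk from a dedicated
sub-stream.  Each photon's trajectory variables come from five per-photon
sub-streams — step length, survival roulette, the two azimuth coordinates
and the Henyey-Greenstein deviate — derived deterministically from the
root seed and the photon index, so trajectories are independent of the
order in which photons are simulated.

Streams are pre-generated in blocks for speed, but each stream owns its
generator, so block pre-generation is numerically identical to drawing
each value on demand in consumption order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optics import DerivedOptics, SimulationConfig

__all__ = ["LaunchStreams", "TrajectoryStreams", "make_launch_streams", "make_trajectory_streams"]

# Spawn-key domains keeping launch and trajectory streams disjoint.
_LAUNCH_DOMAIN = 0
_TRAJ_DOMAIN = 1


@dataclass(frozen=True)
class LaunchStreams:
    """Per-photon launch position in beam polar coordinates.

    ``rbr`` is the radius within the beam, cm, distributed as
    beam_radius * sqrt(U(0,1)) so launch points are uniform over the beam
    disc; ``rba`` is the azimuth, U(0, 2*pi) radians.
    """

    rbr: np.ndarray
    rba: np.ndarray


class _Stream:
    """A buffered scalar stream over its own generator.

    Values are pre-generated ``block`` at a time; refilling draws the next
    block from the same generator, so the sequence of values equals
    on-demand draws in consumption order.
    """

    __slots__ = ("_gen", "_low", "_span", "_buf", "_pos")

    def __init__(self, gen: np.random.Generator, block: int, low: float = 0.0, high: float = 1.0):
        self._gen = gen
        self._low = low
        self._span = high - low
        self._buf = self._low + self._span * gen.random(block)
        self._pos = 0

    @property
    def values(self) -> np.ndarray:
        """The pre-generated buffer (grows if the stream is extended)."""
        return self._buf

    def __next__(self) -> float:
        if self._pos >= self._buf.size:
            extra = self._low + self._span * self._gen.random(self._buf.size)
            self._buf = np.concatenate([self._buf, extra])
        v = self._buf[self._pos]
        self._pos += 1
        return v


class TrajectoryStreams:
    """The five random streams consumed along one photon trajectory.

    ``rmv``  U(0,1)  — step length (exponential free path deviate)
    ``rabs`` U(0,1)  — survival decision after an interaction (roulette mode)
    ``rx1``, ``rx2`` U(-1,1) — scattering azimuth via unit-disc rejection
    ``rmu``  U(0,1)  — Henyey-Greenstein deflection deviate

    Each stream is pre-generated to length ``maxlen`` and extends itself
    if the unit-disc rejection consumes extra (rx1, rx2) pairs.
    """

    def __init__(self, seed: int, photon_index: int, maxlen: int):
        ss = np.random.SeedSequence(seed, spawn_key=(_TRAJ_DOMAIN, photon_index))
        kids = ss.spawn(5)
        gens = [np.random.Generator(np.random.PCG64(k)) for k in kids]
        self.rmv = _Stream(gens[0], maxlen)
        self.rabs = _Stream(gens[1], maxlen)
        self.rx1 = _Stream(gens[2], maxlen, low=-1.0, high=1.0)
        self.rx2 = _Stream(gens[3], maxlen, low=-1.0, high=1.0)
        self.rmu = _Stream(gens[4], maxlen)

    def next_azimuth(self) -> tuple[float, float]:
        """Sample (cos(phi), sin(phi)) by rejection on the unit disc.

        Draws (rx1, rx2) pairs until one lands inside the unit disc, then
        normalizes; avoids trigonometric calls.
        """
        while True:
            x1 = next(self.rx1)
            x2 = next(self.rx2)
            rho2 = x1 * x1 + x2 * x2
            if 0.0 < rho2 <= 1.0:
                rho = math.sqrt(rho2)
                return x1 / rho, x2 / rho


def make_launch_streams(cfg: SimulationConfig, seed: int | None = None) -> LaunchStreams:
    """Draw launch-position polar coordinates for all photons of a run.

    ``rbr = beam_radius * sqrt(U(0,1))`` places photons uniformly over the
    area of the circular beam; ``rba`` is the uniform azimuth.
    """
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed, spawn_key=(_LAUNCH_DOMAIN,))
    gen = np.random.Generator(np.random.PCG64(ss))
    rbr = cfg.beam_radius * np.sqrt(gen.random(cfg.n_photons))
    rba = 2.0 * np.pi * gen.random(cfg.n_photons)
    return LaunchStreams(rbr=rbr, rba=rba)


def make_trajectory_streams(
    derived: DerivedOptics, seed: int, photon_index: int
) -> TrajectoryStreams:
    """Build the five trajectory streams for one photon.

    Streams are derived from (seed, photon_index) alone, so any subset of
    photons can be re-simulated independently and in any order.
    """
    return TrajectoryStreams(seed=seed, photon_index=photon_index, maxlen=derived.maxlen)
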