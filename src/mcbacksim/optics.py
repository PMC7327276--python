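"""Optical parameters of the medium and the per-run constants derived from them.

The simulator describes a semi-infinite homogeneous turbid medium by four
optical parameters (absorption coefficient mu_a, scattering coefficient mu_s,
scattering anisotropy g, refractive index n) and the measurement geometry by
five system parameters (photon count, beam radius, limiting energy level,
observed radius, spatial resolution).  This module holds those parameter
containers, validates them, and evaluates the closed-form physics relations:
the reduced scattering coefficient, the Planck-law photon budget of a laser
pulse, Snell refraction of the launch direction, and the per-run transport
constants (transport albedo, specular reflectance, critical-angle cosine,
maximum trajectory length).

Units: lengths in cm, coefficients in cm^-1 throughout the package; the
photon-budget calculation is evaluated in SI and returns a pure count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "MediaOptics",
    "SimulationConfig",
    "DerivedOptics",
    "BeamGeometry",
    "reduced_scattering",
    "planck_photon_count",
    "refraction_angle",
    "derive_optics",
]

#: Planck's constant, J s (CODATA 2018 exact value).
PLANCK_H = 6.62607015e-34
#: Speed of light in vacuum, m/s (exact).
SPEED_OF_LIGHT = 2.99792458e8

#: Trajectory-length cap used when the medium is non-absorbing (albedo = 1)
#: and the albedo-based bound degenerates.
DEFAULT_MAXLEN_CAP = 10**6


@dataclass(frozen=True)
class MediaOptics:
    """Optical properties of the homogeneous medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1 (>= 0).
    mu_s : float
        Scattering coefficient, cm^-1 (> 0).
    g : float
        Scattering anisotropy factor, the mean cosine of the deflection
        angle; 0 is isotropic, biological tissue is typically > 0.6.
    n : float
        Refractive index of the medium relative to air (>= 1).
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s <= 0:
            raise ValueError(f"mu_s must be > 0, got {self.mu_s}")
        if not -1 < self.g < 1:
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s, cm^-1."""
        return self.mu_a + self.mu_s

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient (1 - g) * mu_s, cm^-1."""
        return reduced_scattering(self.mu_s, self.g)


@dataclass(frozen=True)
class SimulationConfig:
    """Vision-system and simulation parameters.

    Parameters
    ----------
    n_photons : int
        Number of launched photon packets.
    beam_radius : float
        Radius of the circular laser beam, cm.
    limit : float
        Limiting energy level: packets are dropped once their weight falls
        below this fraction of the launch weight (0 < limit < 1).
    obs_radius : float
        Radius of the observed surface area, cm.
    rpx : float
        Spatial resolution of the vision system, cm per pixel (ring width).
    incident_angle_deg : float, default 0
        Incident angle of the beam measured from the surface normal,
        degrees (0 <= angle < 90).
    seed : int, default 1
        Seed for the pseudo-random number generator.
    """

    n_photons: int
    beam_radius: float
    limit: float
    obs_radius: float
    rpx: float
    incident_angle_deg: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_photons < 0:
            raise ValueError(f"n_photons must be >= 0, got {self.n_photons}")
        if self.beam_radius < 0:
            raise ValueError(f"beam_radius must be >= 0, got {self.beam_radius}")
        if not 0 < self.limit < 1:
            raise ValueError(f"limit must lie in (0, 1), got {self.limit}")
        if self.obs_radius <= 0:
            raise ValueError(f"obs_radius must be > 0, got {self.obs_radius}")
        if self.rpx <= 0:
            raise ValueError(f"rpx must be > 0, got {self.rpx}")
        if not 0 <= self.incident_angle_deg < 90:
            raise ValueError(
                f"incident_angle_deg must lie in [0, 90), got {self.incident_angle_deg}"
            )

    @property
    def n_bins(self) -> int:
        """Number of radial bins: 1 + round(obs_radius / rpx)."""
        return 1 + round(self.obs_radius / self.rpx)


@dataclass(frozen=True)
class BeamGeometry:
    """Launch geometry of an obliquely incident beam.

    ``phi1`` is the incident angle in air, ``phi2`` the refracted angle
    inside the medium (both radians).  ``stretch`` = 1/cos(phi2) is the
    elliptic distortion factor applied to the beam footprint along the
    tilt axis (y).
    """

    phi1: float
    phi2: float
    stretch: float


@dataclass(frozen=True)
class DerivedOptics:
    """Per-run constants derived from the medium and the configuration.

    ``albedo`` is the transport albedo mu_s/(mu_s + mu_a), the fraction of
    packet weight surviving each interaction event.  ``rs`` is the
    normal-incidence specular reflectance deducted once at launch.
    ``cangle`` is the cosine of the critical angle for total internal
    reflection.  ``maxlen`` bounds the trajectory length in interaction
    events: albedo**maxlen <= limit.
    """

    mu_t: float
    albedo: float
    rs: float
    cangle: float
    maxlen: int
    n: float


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = (1 - g) * mu_s, cm^-1.

    The similarity-transformed scattering parameter reported in most of
    the tissue-optics literature: media with equal mu_s' (and mu_a) have
    near-identical far-field diffuse reflectance regardless of g.
    """
    if mu_s < 0:
        raise ValueError(f"mu_s must be >= 0, got {mu_s}")
    if not -1 < g < 1:
        raise ValueError(f"g must lie in (-1, 1), got {g}")
    return (1.0 - g) * mu_s


def planck_photon_count(power: float, duration: float, wavelength: float, n: float) -> float:
    """Number of photons delivered by a light pulse, from Planck's law.

    The energy of one photon inside a medium of refractive index ``n`` is
    E = h * C0 / (n * lambda); a pulse of ``power`` watts lasting
    ``duration`` seconds therefore carries power*duration/E photons.

    Parameters are SI: power in W, duration in s, wavelength in m.
    Returns a (generally non-integer) photon count.
    """
    if power < 0:
        raise ValueError(f"power must be >= 0, got {power}")
    if duration <= 0 or wavelength <= 0 or n <= 0:
        raise ValueError("duration, wavelength and n must be positive")
    energy = PLANCK_H * SPEED_OF_LIGHT / (n * wavelength)
    return power * duration / energy


def refraction_angle(phi1_deg: float, n: float) -> BeamGeometry:
    """Refract the incident beam direction into the medium (Snell's law).

    phi2 = asin(sin(phi1) / n).  Also returns the elliptic stretch factor
    1/cos(phi2) that the tilted beam's circular cross-section acquires on
    the surface along the tilt axis.
    """
    if not 0 <= phi1_deg < 90:
        raise ValueError(f"phi1_deg must lie in [0, 90), got {phi1_deg}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    phi1 = math.radians(phi1_deg)
    phi2 = math.asin(math.sin(phi1) / n)
    return BeamGeometry(phi1=phi1, phi2=phi2, stretch=1.0 / math.cos(phi2))


def derive_optics(
    media: MediaOptics,
    cfg: SimulationConfig,
    maxlen_cap: int = DEFAULT_MAXLEN_CAP,
) -> DerivedOptics:
    """Compute the per-run transport constants.

    albedo = mu_s / (mu_s + mu_a)
    rs     = ((n - 1) / (n + 1))**2          (specular reflectance)
    cangle = sqrt(1 - 1/n**2)                (cosine of the critical angle)
    maxlen = round(ln(limit) / ln(albedo)) + 1

    Rounding is round-half-to-even.  For a non-absorbing medium
    (mu_a = 0, albedo = 1) the albedo-based bound degenerates and
    ``maxlen_cap`` is used instead.
    """
    albedo = media.mu_s / media.mu_t
    rs = ((media.n - 1.0) / (media.n + 1.0)) ** 2
    cangle = math.sqrt(1.0 - 1.0 / media.n**2)
    if media.mu_a == 0:
        maxlen = int(maxlen_cap)
    else:
        maxlen = round(math.log(cfg.limit) / math.log(albedo)) + 1
    return DerivedOptics(
        mu_t=media.mu_t, albedo=albedo, rs=rs, cangle=cangle, maxlen=maxlen, n=media.n
    )
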