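"""Sonar integration-volume geometry and shared angular utilities.

The temporal integration of an echolocation system smears together echoes
arriving within one integration constant ``tau``.  The region of space whose
echoes are integrated at range ``r`` is well approximated by a section of a
spherical shell: the shell thickness is set by the two-way travel covered in
``tau`` and the opening angle by the sonar beam width.  The closed-form volume
of that section grows as r², which is why a wide-beam sonar integrates over
cubic-metre volumes at ranges of only a few metres.

Angles are degrees, distances metres, times seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: speed of sound in air at 20 °C, m/s
SPEED_OF_SOUND = 343.0


def shell_thickness(tau: float, c: float = SPEED_OF_SOUND) -> float:
    """Radial thickness of the integration shell, ``c * tau / 2``.

    The factor 1/2 converts the two-way acoustic travel during the temporal
    integration window ``tau`` into a one-way range interval.

    Parameters
    ----------
    tau : float
        Temporal integration constant of the receiver, seconds.
    c : float
        Speed of sound, m/s.
    """
    if tau < 0 or c <= 0:
        raise ValueError("tau must be >= 0 and c > 0")
    return c * tau / 2.0


@dataclass
class IntegrationParams:
    """Parameters of the spherical-shell integration volume.

    Attributes
    ----------
    r : float
        Distance from the sonar to the inner shell surface, metres.
    beam_width : float
        Full opening angle of the beam cone, degrees (the half-angle enters
        the solid-angle formula).
    tau : float
        Temporal integration constant, seconds.
    c : float
        Speed of sound, m/s.
    """

    r: float
    beam_width: float
    tau: float = 200e-6
    c: float = SPEED_OF_SOUND
    delta_r: float = field(init=False)

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if not 0 < self.beam_width < 360:
            raise ValueError("beam_width must be in (0, 360) degrees")
        self.delta_r = shell_thickness(self.tau, self.c)


def integration_volume(params: IntegrationParams) -> float:
    """Volume (m³) of the spherical-shell section integrated by the sonar.

    V = (Ω / 3) * ((r + Δr)³ − r³), with solid angle
    Ω = 2π (1 − cos(beam_width / 2)).

    Monotone increasing in r, beam_width and tau.
    """
    half = np.deg2rad(params.beam_width / 2.0)
    omega = 2.0 * np.pi * (1.0 - np.cos(half))
    r0, r1 = params.r, params.r + params.delta_r
    return float(omega / 3.0 * (r1**3 - r0**3))


def direction_unit_vector(azimuth: float, elevation: float) -> np.ndarray:
    """Unit vector for a gaze direction; boresight (0, 0) is +x, up is +z."""
    az = np.deg2rad(np.asarray(azimuth, dtype=float))
    el = np.deg2rad(np.asarray(elevation, dtype=float))
    return np.stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=-1
    )


def great_circle(dir_a, dir_b) -> float:
    """Great-circle (central) angle in degrees between two (az, el) directions.

    Accepts scalars or broadcastable arrays of (azimuth, elevation) pairs in
    degrees; returns values in [0, 180].
    """
    va = direction_unit_vector(*np.asarray(dir_a, dtype=float).T)
    vb = direction_unit_vector(*np.asarray(dir_b, dtype=float).T)
    dot = np.sum(va * vb, axis=-1)
    cross = np.linalg.norm(np.cross(va, vb), axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    return float(ang) if np.ndim(ang) == 0 else ang


def cartesian_to_direction(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(azimuth, elevation) in degrees of cartesian vectors (..., 3)."""
    v = np.asarray(vec, dtype=float)
    r = np.linalg.norm(v, axis=-1)
    az = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    with np.errstate(invalid="ignore"):
        el = np.degrees(np.arcsin(np.clip(v[..., 2] / np.where(r > 0, r, 1.0), -1, 1)))
    return az, el
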