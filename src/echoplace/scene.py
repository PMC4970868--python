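"""Parametric acoustic scenes and echo-train synthesis.

Emulates a panoramic ensonification device: a loudspeaker emitting a 1 ms
hyperbolic FM call sweeping 100→40 kHz, recorded for 34 ms at 219 kS/s on a
compact 31-microphone array, swept over a 31×7 azimuth–elevation grid with
3 repeated measurements per direction.  Scenes are collections of ideal point
reflectors (extended objects are modelled as seeded clusters of points); the
forward model is direct-path two-way spherical spreading plus additive white
Gaussian device self-noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.signal.windows import tukey

from .geometry import SPEED_OF_SOUND, cartesian_to_direction, great_circle

logger = logging.getLogger(__name__)

ARCHETYPES = ("open", "semi-cluttered", "cluttered")

#: beam gains below this are treated as zero during synthesis (~ −80 dB)
_GAIN_CUTOFF = 1e-4


class ConfigurationError(ValueError):
    """Invalid device, scene or analysis configuration."""


class DegenerateGeometryError(ValueError):
    """Device pose coincides with a reflector (zero range)."""


# ---------------------------------------------------------------------------
# direction grid and device specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectionGrid:
    """Ordered azimuth × elevation gaze grid of the pan–tilt device.

    Directions are indexed elevation-major: ``index = el_index * n_az + az_index``.
    """

    azimuths: np.ndarray
    elevations: np.ndarray

    @classmethod
    def default(cls) -> "DirectionGrid":
        """The 31×7 device grid: 10° azimuth steps over −150..150°, 10.8°
        elevation steps starting at −25°."""
        return cls(
            azimuths=np.linspace(-150.0, 150.0, 31),
            elevations=-25.0 + 10.8 * np.arange(7),
        )

    @classmethod
    def reduced(cls, n_az: int, n_el: int) -> "DirectionGrid":
        """Down-sampled grid spanning the same field of view (smoke configs)."""
        return cls(
            azimuths=np.linspace(-150.0, 150.0, n_az),
            elevations=np.linspace(-25.0, 39.8, n_el),
        )

    @property
    def n_azimuths(self) -> int:
        return len(self.azimuths)

    @property
    def n_elevations(self) -> int:
        return len(self.elevations)

    @property
    def n_directions(self) -> int:
        return len(self.azimuths) * len(self.elevations)

    @property
    def directions(self) -> np.ndarray:
        """(n_directions, 2) array of (azimuth, elevation), elevation-major."""
        az, el = np.meshgrid(self.azimuths, self.elevations)
        return np.column_stack([az.ravel(), el.ravel()])

    def direction(self, index: int) -> tuple[float, float]:
        d = self.directions[index]
        return float(d[0]), float(d[1])

    def index_of(self, az_index: int, el_index: int) -> int:
        return el_index * self.n_azimuths + az_index


def _default_mic_offsets(n_mics: int, radius: float = 0.025) -> np.ndarray:
    """Planar sunflower-packed microphone array in the device (y, z) plane,
    at most ``2 * radius`` across; boresight is +x."""
    k = np.arange(n_mics)
    r = radius * np.sqrt((k + 0.5) / n_mics)
    theta = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    offsets = np.zeros((n_mics, 3))
    offsets[:, 1] = r * np.cos(theta)
    offsets[:, 2] = r * np.sin(theta)
    return offsets


@dataclass(frozen=True)
class DeviceSpec:
    """Ensonification device: call, recorder, microphone array and beam.

    Defaults reproduce the study device; smoke configurations override
    ``n_mics`` and ``grid``.
    """

    call_sweep: tuple[float, float] = (100e3, 40e3)  # Hz, start → end
    call_duration: float = 1e-3  # s
    record_duration: float = 34e-3  # s
    sample_rate: float = 219000.0  # samples / s
    n_mics: int = 31
    mic_offsets: np.ndarray | None = None
    grid: DirectionGrid = field(default_factory=DirectionGrid.default)
    n_repeats: int = 3
    beam_width_3db: float = 20.0  # full two-sided width, degrees
    beam_ref_freq: float = 55e3  # Hz at which beam_width_3db holds
    self_noise_level: float = 1e-3  # linear amplitude of device noise
    speed_of_sound: float = SPEED_OF_SOUND

    def __post_init__(self) -> None:
        n = self.record_duration * self.sample_rate
        if abs(n - round(n)) > 1e-6:
            raise ConfigurationError(
                "record_duration x sample_rate must be an integer sample count"
            )
        if self.mic_offsets is None:
            object.__setattr__(self, "mic_offsets", _default_mic_offsets(self.n_mics))
        else:
            object.__setattr__(
                self, "mic_offsets", np.asarray(self.mic_offsets, dtype=float)
            )
        if self.mic_offsets.shape != (self.n_mics, 3):
            raise ConfigurationError("mic_offsets must have shape (n_mics, 3)")

    @property
    def n_samples(self) -> int:
        return int(round(self.record_duration * self.sample_rate))

    @property
    def max_range(self) -> float:
        """Two-way sonar range covered by the recording window, metres."""
        return self.record_duration * self.speed_of_sound / 2.0

    def with_(self, **kwargs) -> "DeviceSpec":
        if "n_mics" in kwargs and "mic_offsets" not in kwargs:
            kwargs["mic_offsets"] = None
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# scenes and sampling designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reflector:
    """Ideal point scatterer: reflectivity ``strength`` is the linear echo
    amplitude factor referenced to 1 m two-way spreading."""

    position: np.ndarray
    strength: float = 1.0
    kind: str = "point-scatterer"

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.strength < 0:
            raise ValueError("reflector strength must be non-negative")


@dataclass(frozen=True)
class Scene:
    reflectors: tuple[Reflector, ...]
    archetype: str
    rng_seed: int = 0

    @property
    def positions(self) -> np.ndarray:
        if not self.reflectors:
            return np.zeros((0, 3))
        return np.stack([r.position for r in self.reflectors])

    @property
    def strengths(self) -> np.ndarray:
        return np.array([r.strength for r in self.reflectors], dtype=float)


@dataclass(frozen=True)
class SamplingDesign:
    """Device positions: isolated spots or a straight evenly spaced transect."""

    poses: np.ndarray
    design_name: str = "spots"
    spacing: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "poses", np.atleast_2d(np.asarray(self.poses, float)))
        if self.design_name == "transect":
            d = np.diff(self.poses, axis=0)
            if len(d) and not np.allclose(d, d[0], atol=1e-9):
                raise ConfigurationError(
                    "transect poses must be collinear and evenly spaced"
                )
            if self.spacing is None:
                object.__setattr__(self, "spacing", float(np.linalg.norm(d[0])))

    @classmethod
    def transect(
        cls, n_positions: int, spacing: float, origin=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0)
    ) -> "SamplingDesign":
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        poses = np.asarray(origin, float) + spacing * np.arange(n_positions)[:, None] * axis
        return cls(poses=poses, design_name="transect", spacing=spacing)

    @property
    def n_positions(self) -> int:
        return len(self.poses)

    def n_echo_trains(self, spec: DeviceSpec, per_mic: bool = False) -> int:
        """Exact count contract: |poses| × |directions| × repeats (× mics)."""
        n = self.n_positions * spec.grid.n_directions * spec.n_repeats
        return n if per_mic else n * spec.n_mics


def generate_scene(
    archetype: str,
    density: float,
    region: Sequence[Sequence[float]],
    rng_seed: int,
    strength: float = 1.0,
    strength_spread: float = 0.0,
    keep_out: float = 0.5,
    keep_out_centre=(0.0, 0.0, 0.0),
) -> Scene:
    """Draw a scene of point reflectors.

    Cluttered and semi-cluttered archetypes place a homogeneous Poisson draw
    at ``density`` reflectors/m³ inside the axis-aligned ``region``
    (``[(xmin, xmax), (ymin, ymax), (zmin, zmax)]``); the open archetype
    returns no reflectors.  A ``keep_out`` radius around the device location
    excludes reflectors that would collide with the device.  Deterministic for
    a fixed ``rng_seed``.
    """
    if archetype not in ARCHETYPES:
        raise ConfigurationError(
            f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}"
        )
    if density < 0:
        raise ConfigurationError("density must be non-negative")
    region = np.asarray(region, dtype=float)
    if region.shape != (3, 2) or np.any(region[:, 1] <= region[:, 0]):
        raise ConfigurationError("region must be a non-degenerate 3D bounding box")
    if archetype == "open":
        return Scene(reflectors=(), archetype=archetype, rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    volume = float(np.prod(region[:, 1] - region[:, 0]))
    n = rng.poisson(density * volume)
    pos = rng.uniform(region[:, 0], region[:, 1], size=(n, 3))
    centre = np.asarray(keep_out_centre, float)
    pos = pos[np.linalg.norm(pos - centre, axis=1) >= keep_out]
    if strength_spread > 0:
        s = strength * np.exp(rng.normal(0.0, strength_spread, size=len(pos)))
    else:
        s = np.full(len(pos), strength)
    reflectors = tuple(Reflector(p, float(si)) for p, si in zip(pos, s))
    return Scene(reflectors=reflectors, archetype=archetype, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# call model and beam
# ---------------------------------------------------------------------------


def hfm_call(spec: DeviceSpec) -> np.ndarray:
    """Hyperbolic (linear-period) FM call waveform, unit peak amplitude.

    Instantaneous frequency f(t) = f0 f1 T / (f1 T + (f0 − f1) t), which
    sweeps f0 → f1 over the call duration T.  A 5% cosine (Tukey) taper on
    each edge limits spectral splatter.
    """
    f0, f1 = spec.call_sweep
    T = spec.call_duration
    n = int(round(T * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    if f0 == f1:
        phase = 2 * np.pi * f0 * t
    else:
        k = (f0 - f1) / (f1 * T)
        phase = 2 * np.pi * f0 / k * np.log1p(k * t)
    return np.sin(phase) * tukey(n, alpha=0.1)


def beam_gain(direction_offset: float, frequency: float, spec: DeviceSpec):
    """Linear one-way beam gain at an angular offset from boresight.

    Gaussian taper in dB: attenuation = 3 dB × (offset / θ₃(f))², with the
    −3 dB half-angle θ₃ scaling inversely with frequency so the full 3 dB
    opening angle equals ``beam_width_3db`` at ``beam_ref_freq``.
    """
    frequency = np.asarray(frequency, dtype=float)
    lo, hi = sorted(spec.call_sweep)
    if np.any(frequency < lo) or np.any(frequency > hi):
        raise ConfigurationError("frequency outside the call sweep band")
    theta3 = (spec.beam_width_3db / 2.0) * (spec.beam_ref_freq / frequency)
    atten_db = 3.0 * (np.abs(direction_offset) / theta3) ** 2
    g = 10.0 ** (-atten_db / 20.0)
    return float(g) if np.ndim(g) == 0 else g


# ---------------------------------------------------------------------------
# echo-train synthesis
# ---------------------------------------------------------------------------


@dataclass
class EchoTrain:
    """One 34 ms recording plus its device/pose/direction/mic/repeat tags."""

    waveform: np.ndarray
    sample_rate: float
    position_index: int = 0
    direction_index: int = 0
    mic_index: int = 0
    repeat_index: int = 0


def _call_pickup(spec: DeviceSpec, drive: float = 4.0) -> np.ndarray:
    """Saturating pickup of the emission: a full-scale clipped call copy."""
    return np.clip(drive * hfm_call(spec), -1.0, 1.0)


def _echo_geometry(scene: Scene, pose: np.ndarray, spec: DeviceSpec):
    """Per-reflector ranges, directions and per-mic delays for one pose."""
    pose = np.asarray(pose, dtype=float)
    pos = scene.positions
    vec = pos - pose
    r = np.linalg.norm(vec, axis=1)
    if np.any(r < 1e-9):
        raise DegenerateGeometryError("device pose coincides with a reflector")
    az, el = cartesian_to_direction(vec)
    # two-way path per mic: emitter at pose, receiver at pose + offset
    r_rx = np.linalg.norm(pos[:, None, :] - (pose + spec.mic_offsets)[None, :, :], axis=2)
    delays = (r[:, None] + r_rx) / spec.speed_of_sound  # (n_refl, n_mics)
    return r, np.column_stack([az, el]), delays


def _noiseless_echoes(
    scene: Scene, pose, direction, spec: DeviceSpec, geometry=None
) -> np.ndarray:
    """Noise-free echo waveforms for all mics at one pose and gaze direction;
    returns (n_mics, n_samples)."""
    n = spec.n_samples
    out = np.tile(_call_pickup(spec), (spec.n_mics, 1))
    out = np.pad(out, ((0, 0), (0, n - out.shape[1])))
    if not scene.reflectors:
        return out
    r, refl_dirs, delays = geometry if geometry is not None else _echo_geometry(
        scene, pose, spec
    )
    offsets = great_circle(refl_dirs, np.asarray(direction, float)[None, :])
    gains = beam_gain(offsets, spec.beam_ref_freq, spec)
    gains = np.atleast_1d(gains)
    amps = scene.strengths * gains / r**2
    call = hfm_call(spec)
    m = len(call)
    active = np.flatnonzero(gains >= _GAIN_CUTOFF)
    for i in active:
        for mic in range(spec.n_mics):
            start = int(round(delays[i, mic] * spec.sample_rate))
            if start >= n:
                continue
            stop = min(start + m, n)
            out[mic, start:stop] += amps[i] * call[: stop - start]
    return out


def synthesize_echo_train(
    scene: Scene,
    pose,
    direction,
    mic_index: int,
    spec: DeviceSpec,
    rng_seed,
) -> EchoTrain:
    """Synthesize one echo train: saturating call pickup at t = 0, plus each
    reflector's call copy delayed by the two-way travel time 2r/c and scaled
    by strength × beam_gain / r² (spherical spreading both ways), plus white
    Gaussian device self-noise.  Deterministic for a fixed seed."""
    direction = np.asarray(direction, dtype=float)
    grid_dirs = spec.grid.directions
    if not np.any(np.all(np.isclose(grid_dirs, direction, atol=1e-6), axis=1)):
        raise ConfigurationError("direction does not belong to the device grid")
    w = _noiseless_echoes(scene, pose, direction, spec)[mic_index].copy()
    rng = np.random.default_rng(rng_seed)
    if spec.self_noise_level > 0:
        w += rng.normal(0.0, spec.self_noise_level, size=len(w))
    d_index = int(
        np.flatnonzero(np.all(np.isclose(grid_dirs, direction, atol=1e-6), axis=1))[0]
    )
    return EchoTrain(
        waveform=w,
        sample_rate=spec.sample_rate,
        direction_index=d_index,
        mic_index=mic_index,
    )


def _train_seed(master_seed: int, p: int, d: int, r: int, m: int):
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, p, d, r, m])


def generate_dataset(
    scene: Scene | Sequence[Scene],
    design: SamplingDesign,
    spec: DeviceSpec,
    rng_seed: int,
) -> Iterator[EchoTrain]:
    """Lazily generate the full ensonification dataset for a sampling design.

    Yields exactly |poses| × |directions| × n_repeats × n_mics echo trains in
    (position, direction, repeat, mic) order.  Repeated measurements of the
    same cell differ only in the device-noise realization.  ``scene`` may be a
    single scene shared by all poses or one scene per pose.
    """
    scenes = (
        list(scene) if isinstance(scene, (list, tuple)) else [scene] * design.n_positions
    )
    if len(scenes) != design.n_positions:
        raise ConfigurationError("need one scene per pose (or a single shared scene)")
    dirs = spec.grid.directions
    for p, pose in enumerate(design.poses):
        sc = scenes[p]
        geometry = _echo_geometry(sc, pose, spec) if sc.reflectors else None
        for d in range(len(dirs)):
            clean = _noiseless_echoes(sc, pose, dirs[d], spec, geometry=geometry)
            for rep in range(spec.n_repeats):
                for mic in range(spec.n_mics):
                    rng = np.random.default_rng(_train_seed(rng_seed, p, d, rep, mic))
                    w = clean[mic].copy()
                    if spec.self_noise_level > 0:
                        w += rng.normal(0.0, spec.self_noise_level, size=len(w))
                    yield EchoTrain(
                        waveform=w,
                        sample_rate=spec.sample_rate,
                        position_index=p,
                        direction_index=d,
                        mic_index=mic,
                        repeat_index=rep,
                    )
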