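"""Place-template construction.

A template is the place signature for one device position and gaze direction:
the dechirped cochleograms of all microphones and repeats for that cell are
onset-blanked (first 5.8 ms zeroed, ≈ 1 m of range, removing the saturated
call pickup), averaged over the 15 frequency channels and all microphones,
smoothed over the 3×3 neighbouring gaze directions, integrated into 350 µs
time bins (97 bins over the 34 ms window), and finally averaged over the 3
repeated measurements.  The pipeline order is: cochleogram → dechirp →
blank → collapse (frequency & microphone mean) → spatial average →
downsample → repeat mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .auditory import (
    CochlearParams,
    Cochleogram,
    dechirp_batch,
    filterbank_activations,
)
from .scene import ConfigurationError, DeviceSpec, DirectionGrid, EchoTrain, SamplingDesign

logger = logging.getLogger(__name__)

#: default onset blanking, seconds (≈ 1 m two-way range)
BLANK_DURATION = 5.8e-3
#: template temporal integration interval, seconds
SAMPLE_INTERVAL = 350e-6


class IncompleteDataError(ValueError):
    """A (direction, mic, repeat) cell of a position dataset is missing."""


@dataclass
class Template:
    """Per-position, per-direction place signature vector."""

    values: np.ndarray
    position_index: int = 0
    direction_index: int = 0
    sample_interval: float = SAMPLE_INTERVAL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class TemplateSet:
    """All templates of a study, with their grid and sampling design."""

    templates: list[Template]
    grid: DirectionGrid
    design: SamplingDesign | None = None

    def __post_init__(self) -> None:
        keys = [(t.position_index, t.direction_index) for t in self.templates]
        if len(set(keys)) != len(keys):
            raise ConfigurationError(
                "duplicate (position_index, direction_index) pairs in TemplateSet"
            )

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def matrix(self) -> np.ndarray:
        """(n_templates, template_length) value matrix, template order."""
        return np.stack([t.values for t in self.templates])

    @property
    def position_indices(self) -> np.ndarray:
        return np.array([t.position_index for t in self.templates])

    @property
    def direction_indices(self) -> np.ndarray:
        return np.array([t.direction_index for t in self.templates])

    def directions(self) -> np.ndarray:
        """(n_templates, 2) azimuth/elevation of each template's direction."""
        return self.grid.directions[self.direction_indices]

    def subset(self, mask: np.ndarray) -> "TemplateSet":
        sel = [t for t, m in zip(self.templates, mask) if m]
        return TemplateSet(sel, self.grid, self.design)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def _blank_mask(n_samples: int, sample_rate: float, blank_duration: float) -> np.ndarray:
    t = np.arange(n_samples) / sample_rate
    return t < blank_duration


def blank_onset(c: Cochleogram, blank_duration: float = BLANK_DURATION) -> Cochleogram:
    """Zero every channel for t < ``blank_duration`` (call-pickup removal)."""
    if not c.dechirped:
        raise ConfigurationError("blank_onset expects a dechirped cochleogram")
    if blank_duration * c.sample_rate >= c.n_samples:
        raise ConfigurationError("blank_duration covers the whole recording")
    out = c.activations.copy()
    out[:, _blank_mask(c.n_samples, c.sample_rate, blank_duration)] = 0.0
    return Cochleogram(out, c.center_frequencies, c.sample_rate, dechirped=True)


def collapse(
    cochleograms: Mapping[tuple[int, int, int], Cochleogram],
    grid: DirectionGrid,
    n_mics: int,
    n_repeats: int = 3,
) -> np.ndarray:
    """Average one position's cochleograms over frequency and microphones.

    ``cochleograms`` maps (direction_index, mic_index, repeat_index) to a
    blanked, dechirped cochleogram.  Returns raw time profiles with shape
    (n_directions, n_repeats, n_samples) — one profile per (direction,
    repeat), e.g. 217 × 3 = 651 for the full grid.
    """
    first = next(iter(cochleograms.values()))
    n = first.n_samples
    out = np.zeros((grid.n_directions, n_repeats, n))
    for d in range(grid.n_directions):
        for rep in range(n_repeats):
            acc = np.zeros(n)
            for m in range(n_mics):
                try:
                    c = cochleograms[(d, m, rep)]
                except KeyError:
                    raise IncompleteDataError(
                        f"missing cochleogram for direction={d}, mic={m}, repeat={rep}"
                    ) from None
                acc += c.activations.mean(axis=0)
            out[d, rep] = acc / n_mics
    return out


def spatial_average(profiles: np.ndarray, grid: DirectionGrid) -> np.ndarray:
    """Average each direction's profile over its 3×3 grid neighbourhood.

    Neighbourhoods are truncated at grid edges (the −150..150° azimuth range
    does not wrap).  Repeats (axis 1) are processed independently.

    Parameters
    ----------
    profiles : ndarray, (n_directions, n_repeats, n_samples), elevation-major
    """
    n_el, n_az = grid.n_elevations, grid.n_azimuths
    tail = profiles.shape[1:]
    p = profiles.reshape(n_el, n_az, *tail)
    padded = np.zeros((n_el + 2, n_az + 2) + tail)
    padded[1:-1, 1:-1] = p
    counts = np.zeros((n_el + 2, n_az + 2))
    counts[1:-1, 1:-1] = 1.0
    sums = np.zeros_like(p)
    cnt = np.zeros((n_el, n_az))
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            sums += padded[1 + di : n_el + 1 + di, 1 + dj : n_az + 1 + dj]
            cnt += counts[1 + di : n_el + 1 + di, 1 + dj : n_az + 1 + dj]
    out = sums / cnt.reshape((n_el, n_az) + (1,) * len(tail))
    return out.reshape(profiles.shape)


def downsample(
    profile: np.ndarray,
    sample_rate: float = 219000.0,
    interval: float = SAMPLE_INTERVAL,
) -> np.ndarray:
    """Integrate a raw time profile into ``interval``-wide bins (bin means).

    output[k] = mean of samples with t in [k·interval, (k+1)·interval); the
    trailing partial bin is discarded, so a 34 ms profile at 219 kS/s yields
    floor(34 ms / 350 µs) = 97 bins.  Works on (..., n_samples) batches.
    """
    x = np.asarray(profile, dtype=float)
    n = x.shape[-1]
    n_bins = int(np.floor(n / sample_rate / interval))
    # first sample index of each bin: smallest i with i/fs >= k*interval
    edges = np.ceil(np.arange(n_bins + 1) * interval * sample_rate - 1e-9).astype(int)
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    sums = csum[..., edges[1:]] - csum[..., edges[:-1]]
    widths = np.diff(edges)
    return sums / widths


def count_template_length(record_duration: float, interval: float = SAMPLE_INTERVAL) -> int:
    return int(np.floor(record_duration / interval))


# ---------------------------------------------------------------------------
# full per-position pipeline
# ---------------------------------------------------------------------------


def build_templates(
    echo_trains: Iterable[EchoTrain],
    spec: DeviceSpec,
    params: CochlearParams | None = None,
    blank_duration: float = BLANK_DURATION,
    interval: float = SAMPLE_INTERVAL,
    position_index: int = 0,
    return_stage_counts: bool = False,
):
    """Build one position's templates from its complete echo-train dataset.

    Streams through the input (directions × mics × repeats trains, e.g.
    20,181 at full scale), running cochleogram → dechirp → blank → frequency
    and microphone averaging per cell, then spatial 3×3 smoothing, 350 µs
    binning and the repeat mean, producing one template per grid direction
    (217 at full scale).

    Returns a list of :class:`Template`; with ``return_stage_counts=True``
    also returns a dict of the stage count contracts
    ``{"n_echo_trains", "n_profiles", "n_templates"}``.
    """
    if params is None:
        params = CochlearParams(sample_rate=spec.sample_rate)
    grid = spec.grid
    n = spec.n_samples
    blank = _blank_mask(n, spec.sample_rate, blank_duration)
    profiles = np.zeros((grid.n_directions, spec.n_repeats, n))
    filled = np.zeros((grid.n_directions, spec.n_repeats, spec.n_mics), dtype=bool)
    # buffer one (direction, repeat) cell of mic waveforms at a time so the
    # filterbank runs on batches
    buffers: dict[tuple[int, int], np.ndarray] = {}
    pending: dict[tuple[int, int], np.ndarray] = {}
    n_in = 0

    def _flush(key):
        d, rep = key
        mask = pending[key]
        w = buffers[key]
        act = filterbank_activations(w[mask], params)  # (k, ch, n)
        act = dechirp_batch(act)
        act[..., blank] = 0.0
        profiles[d, rep] += act.mean(axis=-2).sum(axis=0)
        del buffers[key], pending[key]

    for tr in echo_trains:
        n_in += 1
        key = (tr.direction_index, tr.repeat_index)
        if key not in buffers:
            buffers[key] = np.zeros((spec.n_mics, n))
            pending[key] = np.zeros(spec.n_mics, dtype=bool)
        buffers[key][tr.mic_index] = tr.waveform
        pending[key][tr.mic_index] = True
        filled[tr.direction_index, tr.repeat_index, tr.mic_index] = True
        if pending[key].all():
            _flush(key)
    for key in list(buffers):
        _flush(key)

    if not filled.all():
        d, rep, m = np.argwhere(~filled)[0]
        raise IncompleteDataError(
            f"missing echo train for direction={d}, mic={m}, repeat={rep}"
        )
    profiles /= spec.n_mics
    n_profiles = grid.n_directions * spec.n_repeats
    profiles = spatial_average(profiles, grid)
    binned = downsample(profiles, spec.sample_rate, interval)
    values = binned.mean(axis=1)  # repeat mean
    templates = [
        Template(values[d], position_index=position_index, direction_index=d,
                 sample_interval=interval)
        for d in range(grid.n_directions)
    ]
    counts = {
        "n_echo_trains": n_in,
        "n_profiles": n_profiles,
        "n_templates": len(templates),
    }
    logger.info("built %d templates from %d echo trains", len(templates), n_in)
    return (templates, counts) if return_stage_counts else templates


def build_template_set(
    scene,
    design: SamplingDesign,
    spec: DeviceSpec,
    rng_seed: int,
    params: CochlearParams | None = None,
) -> TemplateSet:
    """Synthesize a full dataset and build templates for every position."""
    from .scene import generate_dataset

    scenes = scene if isinstance(scene, (list, tuple)) else [scene] * design.n_positions
    all_templates: list[Template] = []
    it = generate_dataset(scenes, design, spec, rng_seed)
    per_pos = spec.grid.n_directions * spec.n_repeats * spec.n_mics

    def take(k):
        for _ in range(k):
            yield next(it)

    for p in range(design.n_positions):
        all_templates.extend(
            build_templates(take(per_pos), spec, params=params, position_index=p)
        )
    return TemplateSet(all_templates, spec.grid, design)
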