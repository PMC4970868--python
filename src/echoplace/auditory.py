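"""Bat auditory-periphery front end.

Each echo train is passed through a gammatone filterbank (centre frequencies
30–100 kHz in 5 kHz steps, 15 channels), half-wave rectified, exponentially
compressed with exponent 0.4, and low-pass filtered at 1 kHz with a
12 dB/octave (second-order Butterworth) slope.  The resulting cochleogram is
then *dechirped*: every frequency channel is shifted in time so that its
maximum activation — the pickup of the emitted FM sweep — is aligned across
channels, zero-padding at the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .scene import ConfigurationError, EchoTrain

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CochlearParams:
    """Tunable parameters of the periphery model.

    The filterbank uses 4th-order IIR gammatone filters with ERB-style
    bandwidths (Glasberg & Moore) at each ultrasonic centre frequency —
    the standard choice where the model family leaves order and bandwidth
    open.
    """

    cf_start: float = 30e3  # Hz
    cf_stop: float = 100e3  # Hz
    cf_step: float = 5e3  # Hz
    compression_exponent: float = 0.4
    lowpass_cutoff: float = 1e3  # Hz
    lowpass_order: int = 2  # 12 dB / octave
    sample_rate: float = 219000.0

    @property
    def center_frequencies(self) -> np.ndarray:
        return np.arange(self.cf_start, self.cf_stop + self.cf_step / 2, self.cf_step)


DEFAULT_PARAMS = CochlearParams()


@dataclass
class Cochleogram:
    """channel × time activation matrix of the periphery model."""

    activations: np.ndarray  # (n_channels, n_samples), non-negative
    center_frequencies: np.ndarray  # Hz
    sample_rate: float
    dechirped: bool = False

    @property
    def n_channels(self) -> int:
        return self.activations.shape[0]

    @property
    def n_samples(self) -> int:
        return self.activations.shape[1]


@lru_cache(maxsize=8)
def _filters(params: CochlearParams):
    gt = [
        signal.gammatone(cf, "iir", fs=params.sample_rate)
        for cf in params.center_frequencies
    ]
    lp = signal.butter(
        params.lowpass_order, params.lowpass_cutoff, fs=params.sample_rate, output="sos"
    )
    return gt, lp


def filterbank_activations(
    waveforms: np.ndarray, params: CochlearParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Periphery activations for a batch of waveforms.

    Applies, per channel: gammatone bandpass → half-wave rectification →
    power-law compression → low-pass smoothing, along the last axis.

    Parameters
    ----------
    waveforms : ndarray, shape (..., n_samples)
    params : CochlearParams

    Returns
    -------
    ndarray, shape (..., n_channels, n_samples)
    """
    x = np.asarray(waveforms, dtype=float)
    gt, lp = _filters(params)
    out = np.empty(x.shape[:-1] + (len(gt), x.shape[-1]))
    for ch, (b, a) in enumerate(gt):
        y = signal.lfilter(b, a, x, axis=-1)
        np.maximum(y, 0.0, out=y)
        y **= params.compression_exponent
        out[..., ch, :] = signal.sosfilt(lp, y, axis=-1)
    # the smoothing filter can ring marginally below zero; activations are
    # defined non-negative
    np.maximum(out, 0.0, out=out)
    return out


def cochleogram(
    echo: EchoTrain | np.ndarray, params: CochlearParams = DEFAULT_PARAMS
) -> Cochleogram:
    """Cochleogram of a single echo train (not yet dechirped)."""
    if isinstance(echo, EchoTrain):
        if abs(echo.sample_rate - params.sample_rate) > 1e-6:
            raise ConfigurationError(
                f"echo sample rate {echo.sample_rate} does not match the model "
                f"design rate {params.sample_rate}"
            )
        w = echo.waveform
    else:
        w = np.asarray(echo, dtype=float)
    act = filterbank_activations(w, params)
    return Cochleogram(
        activations=act,
        center_frequencies=params.center_frequencies,
        sample_rate=params.sample_rate,
        dechirped=False,
    )


def channel_shifts(activations: np.ndarray) -> np.ndarray:
    """Non-negative per-channel left shifts aligning channel argmaxes.

    The alignment target is the earliest per-channel argmax, so every shift is
    leftwards (toward t = 0) and only end-padding is ever needed.  Silent
    (all-zero) channels are left unshifted.
    """
    argmax = np.argmax(activations, axis=-1)
    silent = ~np.any(activations > 0, axis=-1)
    if np.any(silent):
        logger.warning("dechirp: %d silent channel(s) left unshifted", silent.sum())
    live = ~silent
    if not np.any(live):
        return np.zeros(activations.shape[0], dtype=int)
    target = int(argmax[live].min())
    shifts = np.where(live, argmax - target, 0)
    return shifts.astype(int)


def dechirp(c: Cochleogram) -> Cochleogram:
    """Align the per-channel maxima in time, zero-padding at the end."""
    if c.dechirped:
        raise ConfigurationError("cochleogram is already dechirped")
    shifts = channel_shifts(c.activations)
    out = np.zeros_like(c.activations)
    n = c.n_samples
    for ch, s in enumerate(shifts):
        out[ch, : n - s] = c.activations[ch, s:]
    return Cochleogram(
        activations=out,
        center_frequencies=c.center_frequencies,
        sample_rate=c.sample_rate,
        dechirped=True,
    )


def dechirp_batch(activations: np.ndarray) -> np.ndarray:
    """Dechirp a batch of cochleograms (..., n_channels, n_samples)."""
    act = np.asarray(activations)
    if act.ndim == 2:
        act = act[None]
        squeeze = True
    else:
        squeeze = False
    out = np.zeros_like(act)
    n = act.shape[-1]
    flat = out.reshape(-1, act.shape[-2], n)
    src = act.reshape(-1, act.shape[-2], n)
    for i in range(len(src)):
        shifts = channel_shifts(src[i])
        for ch, s in enumerate(shifts):
            flat[i, ch, : n - s] = src[i, ch, s:]
    return out[0] if squeeze else out
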