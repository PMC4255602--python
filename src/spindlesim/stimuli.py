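"""Deterministic muscle-stretch waveform generators.

Every generator returns a :class:`Waveform`: muscle length in units of the
resting length L0, uniformly sampled on a 1 ms grid. A stretch of 36.8% is
therefore the trajectory 1.0 -> 1.368. All generators are pure functions of
their arguments (plus an explicit seed for the filtered-noise stimulus), so
repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "GRID_DT_MS",
    "Waveform",
    "ramp_hold",
    "sinusoid",
    "tap_pulse",
    "release_ramp",
    "triangular_wave",
    "filtered_white_noise",
]

#: Sample interval of the emulation grid (one state update per millisecond).
GRID_DT_MS = 1.0


@dataclass
class Waveform:
    """Uniformly sampled normalized muscle-length time series.

    Attributes
    ----------
    samples : ndarray
        Muscle length in L0 units; strictly positive.
    dt_ms : float
        Sample interval in milliseconds.
    label : str
        Protocol name (used in file headers and experiment results).
    """

    samples: np.ndarray
    dt_ms: float = GRID_DT_MS
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("waveform samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        if np.any(self.samples <= 0):
            raise ValueError("muscle length must stay positive (L0 units)")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return (self.n - 1) * self.dt_ms


def _n_samples(duration_ms: float) -> int:
    if duration_ms <= 0:
        raise ValueError("durations must be positive")
    return int(round(duration_ms / GRID_DT_MS))


def ramp_hold(baseline: float = 1.0, amplitude: float = 0.368,
              ramp_ms: float = 200.0, hold_ms: float = 800.0,
              pre_ms: float = 0.0) -> Waveform:
    """Linear rise from ``baseline`` to ``baseline + amplitude``, then hold.

    ``pre_ms`` prepends a constant-baseline segment (useful for letting the
    spindle settle before the ramp starts).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if pre_ms < 0:
        raise ValueError("pre_ms must be >= 0")
    n_pre = int(round(pre_ms / GRID_DT_MS))
    n_ramp = _n_samples(ramp_ms)
    n_hold = _n_samples(hold_ms)
    t_ramp = np.arange(n_ramp + 1) * GRID_DT_MS
    ramp = baseline + amplitude * t_ramp / ramp_ms
    samples = np.concatenate([
        np.full(n_pre, baseline),
        ramp,
        np.full(n_hold, baseline + amplitude),
    ])
    return Waveform(samples, label="ramp_hold")


def sinusoid(baseline: float = 1.0, p2p: float = 0.026,
             freq_hz: float = 3.0, n_cycles: int = 6,
             pre_ms: float = 0.0) -> Waveform:
    """Baseline-centered sine, peak-to-peak ``p2p``, starting with positive slope."""
    if p2p < 0:
        raise ValueError("p2p must be >= 0")
    if freq_hz <= 0:
        raise ValueError("freq_hz must be positive")
    if n_cycles <= 0:
        raise ValueError("n_cycles must be positive")
    n_pre = int(round(pre_ms / GRID_DT_MS))
    period_ms = 1000.0 / freq_hz
    n = _n_samples(n_cycles * period_ms)
    t_s = np.arange(n + 1) * GRID_DT_MS / 1000.0
    wave = baseline + 0.5 * p2p * np.sin(2.0 * np.pi * freq_hz * t_s)
    return Waveform(np.concatenate([np.full(n_pre, baseline), wave]), label="sinusoid")


def tap_pulse(baseline: float = 1.0, amplitude: float = 0.05,
              width_ms: float = 20.0, pre_ms: float = 0.0,
              post_ms: float = 0.0) -> Waveform:
    """Brief raised-cosine bump of the given width and peak amplitude.

    The raised-cosine profile starts and ends with zero velocity, which is
    the smooth idealization of a tendon tap.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    n_pre = int(round(pre_ms / GRID_DT_MS))
    n_post = int(round(post_ms / GRID_DT_MS))
    n_tap = _n_samples(width_ms)
    t = np.arange(n_tap + 1) * GRID_DT_MS
    bump = baseline + 0.5 * amplitude * (1.0 - np.cos(2.0 * np.pi * t / width_ms))
    samples = np.concatenate([
        np.full(n_pre, baseline), bump, np.full(n_post, baseline),
    ])
    return Waveform(samples, label="tap")


def release_ramp(baseline: float = 1.2, drop: float = 0.2,
                 ramp_ms: float = 100.0, pre_ms: float = 0.0,
                 post_ms: float = 500.0) -> Waveform:
    """Linear shortening by ``drop`` over ``ramp_ms``, then constant.

    The ramp ends abruptly: the velocity discontinuity at the stop is
    preserved (a sudden stop acts on the spindle like a momentary
    high-velocity stretch and produces the post-release burst).
    """
    if drop < 0:
        raise ValueError("drop must be >= 0")
    if baseline - drop <= 0:
        raise ValueError("release would drive muscle length below zero")
    n_pre = int(round(pre_ms / GRID_DT_MS))
    n_ramp = _n_samples(ramp_ms)
    n_post = int(round(post_ms / GRID_DT_MS))
    t = np.arange(n_ramp + 1) * GRID_DT_MS
    ramp = baseline - drop * t / ramp_ms
    samples = np.concatenate([
        np.full(n_pre, baseline), ramp, np.full(n_post, baseline - drop),
    ])
    return Waveform(samples, label="release")


def triangular_wave(baseline: float = 1.0, amplitude: float = 0.1,
                    rise_ms: float = 500.0, fall_ms: float = 500.0,
                    n_reps: int = 25, inter_ms: float = 500.0) -> Waveform:
    """Repeated symmetric-by-default triangular stretches with baseline gaps.

    Each repetition rises linearly to ``baseline + amplitude`` over
    ``rise_ms``, falls back over ``fall_ms``, then rests at baseline for
    ``inter_ms`` before the next repetition.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if inter_ms < 0:
        raise ValueError("inter_ms must be >= 0")
    n_rise = _n_samples(rise_ms)
    n_fall = _n_samples(fall_ms)
    n_inter = int(round(inter_ms / GRID_DT_MS))
    rise = baseline + amplitude * np.arange(n_rise) * GRID_DT_MS / rise_ms
    fall = baseline + amplitude * (1.0 - np.arange(n_fall) * GRID_DT_MS / fall_ms)
    cycle = np.concatenate([rise, fall, np.full(n_inter, baseline)])
    samples = np.concatenate([np.full(n_inter, baseline)] + [cycle] * n_reps + [[baseline]])
    return Waveform(samples, label="triangular")


def filtered_white_noise(duration_s: float = 160.0, cutoff_hz: float = 5.0,
                         amplitude: float = 0.1, seed: int = 0,
                         baseline: float = 1.0, order: int = 2) -> Waveform:
    """Low-pass-filtered pseudorandom stretch rescaled to a fixed span.

    White Gaussian samples on the 1 ms grid are filtered with an
    ``order``-th-order Butterworth low-pass applied forward-backward
    (zero phase), then min-max rescaled to ``[baseline, baseline+amplitude]``.
    Deterministic given ``seed``. The low-pass removes the unrealistically
    fast components that skin and ligament damp out in a real limb.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    fs = 1000.0 / GRID_DT_MS
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff_hz must lie in (0, {fs / 2}) for the {GRID_DT_MS} ms grid")
    n = _n_samples(duration_s * 1000.0)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = _signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = _signal.sosfiltfilt(sos, white)
    span = filtered.max() - filtered.min()
    if amplitude == 0 or span == 0:
        samples = np.full(n, baseline)
    else:
        samples = baseline + amplitude * (filtered - filtered.min()) / span
    return Waveform(samples, label="filtered_white_noise")
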