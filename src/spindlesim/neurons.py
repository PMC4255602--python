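"""Spiking afferent populations: rate -> EPSC -> Izhikevich Class-1 neurons.

The spindle's Group Ia and Group II firing rates are converted to excitatory
post-synaptic currents through a calibrated monotonic map and injected into
populations of quadratic integrate-and-fire (Izhikevich) neurons::

    dv/dt = k2*v^2 + k1*v + k0 - u + I        (+ additive membrane noise)
    du/dt = a*(b*v - u)
    if v >= v_peak:  v <- c,  u <- u + d      (spike)

The default parameter set is the published Class-1 excitable configuration
(a=0.02, b=-0.1, c=-55, d=6, with membrane coefficients 0.04/4.1/108): its
noise-free f-I curve rises continuously from zero, so firing rate is a
monotonic representation of input current over a wide range and the
rate-to-current conversion is a simple curve inversion.

Per-neuron variability comes from uniform pseudorandom noise added to the
membrane potential each 1 ms update (5 mV peak-to-peak by default), generated
by one maximal-length 32-bit Galois linear-feedback shift register (LFSR) per
neuron -- the same noise source a combinational hardware design uses. The
register is clocked 32 times per sample and the full register is read out as
one 32-bit uniform word; the 32-step advance is applied through precomputed
byte lookup tables (a linear map over GF(2)), which is bit-exact with naive
stepping but vectorizes across a population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError, ConfigError

__all__ = [
    "IzhikevichParams",
    "REGULAR_SPIKING",
    "NeuronState",
    "NoiseStream",
    "SpikeRaster",
    "LFSR_MASK",
    "lfsr_noise",
    "izhikevich_step",
    "measure_fi_curve",
    "calibrate_gain",
    "GainConfig",
    "rate_to_epsc",
    "run_population",
]

#: Galois feedback mask for the maximal-length 32-bit LFSR (taps 32, 22, 2, 1).
LFSR_MASK = np.uint32(0x80200003)


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of the quadratic spiking-neuron model (mV / ms units)."""

    a: float = 0.02
    b: float = -0.1
    c: float = -55.0
    d: float = 6.0
    k2: float = 0.04
    k1: float = 4.1
    k0: float = 108.0
    v_peak: float = 30.0

    def __post_init__(self):
        if self.a <= 0:
            raise ConfigError("Izhikevich parameter a must be positive")
        if self.c >= self.v_peak:
            raise ConfigError("reset potential c must lie below v_peak")


#: Alternative preset: the standard regular-spiking (Class-2-like) set.
REGULAR_SPIKING = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0,
                                   k2=0.04, k1=5.0, k0=140.0)


@dataclass
class NeuronState:
    v: float = -60.0
    u: float = 6.0


@dataclass
class NeuronConfig:
    """Population-level configuration: neuron model, noise, and gain map."""

    params: IzhikevichParams = field(default_factory=IzhikevichParams)
    noise_amplitude_mv: float = 5.0  # peak-to-peak
    gain: "GainConfig | None" = None
    dt_ms: float = 1.0


# ---------------------------------------------------------------------------
# LFSR noise source
# ---------------------------------------------------------------------------

def _lfsr_step_scalar(state: int, mask: int = int(LFSR_MASK)) -> int:
    lsb = state & 1
    state >>= 1
    if lsb:
        state ^= mask
    return state


def _build_jump_tables(steps: int = 32, mask: int = int(LFSR_MASK)) -> list[np.ndarray]:
    """Byte-indexed lookup tables for advancing the register ``steps`` ticks.

    The LFSR transition is linear over GF(2), so the ``steps``-tick image of a
    state is the XOR of the images of its set bits; grouping bits into four
    bytes gives four 256-entry tables.
    """
    tables = []
    for byte in range(4):
        tab = np.zeros(256, dtype=np.uint32)
        for val in range(256):
            s = val << (8 * byte)
            for _ in range(steps):
                s = _lfsr_step_scalar(s, mask)
            tab[val] = s
        tables.append(tab)
    return tables


_JUMP32 = _build_jump_tables()


def _advance32(states: np.ndarray) -> np.ndarray:
    """Advance uint32 register state(s) by 32 Galois ticks (vectorized)."""
    return (_JUMP32[0][states & 0xFF]
            ^ _JUMP32[1][(states >> np.uint32(8)) & np.uint32(0xFF)]
            ^ _JUMP32[2][(states >> np.uint32(16)) & np.uint32(0xFF)]
            ^ _JUMP32[3][states >> np.uint32(24)])


@dataclass
class NoiseStream:
    """One neuron's pseudorandom noise source.

    ``amplitude_mv`` is peak-to-peak: samples are uniform on
    ``[-amplitude/2, +amplitude/2)`` mV. The register must never be all-zero
    (the zero state is a fixed point of the LFSR).
    """

    lfsr_state: int
    amplitude_mv: float = 5.0

    def __post_init__(self):
        self.lfsr_state = int(self.lfsr_state) & 0xFFFFFFFF
        if self.lfsr_state == 0:
            raise ValueError("LFSR seed must be nonzero")
        if self.amplitude_mv < 0:
            raise ValueError("noise amplitude must be >= 0")


def lfsr_noise(stream: NoiseStream) -> tuple[float, NoiseStream]:
    """Draw one uniform noise sample (mV) and return the advanced stream."""
    new_state = int(_advance32(np.asarray(stream.lfsr_state, dtype=np.uint32))[()])
    sample = (new_state / 2.0 ** 32 - 0.5) * stream.amplitude_mv
    return sample, replace(stream, lfsr_state=new_state)


def _seed_states(master_seed: int, n: int) -> np.ndarray:
    """Independent nonzero 32-bit register seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    states = ss.generate_state(n, dtype=np.uint32)
    states[states == 0] = np.uint32(0x9E3779B9)
    return states


# ---------------------------------------------------------------------------
# Neuron dynamics
# ---------------------------------------------------------------------------

def izhikevich_step(state: NeuronState, current: float, noise_mv: float = 0.0,
                    dt_ms: float = 1.0, params: IzhikevichParams | None = None,
                    ) -> tuple[NeuronState, bool]:
    """Advance one neuron by ``dt_ms``; returns the new state and a spike flag.

    The membrane equation is integrated with two half-steps (the standard
    stabilization of the quadratic model at a 1 ms grid); noise is added to
    the membrane potential, not to the current.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    p = params or IzhikevichParams()
    v, u = state.v, state.u
    for _ in range(2):
        v += 0.5 * dt_ms * (p.k2 * v * v + p.k1 * v + p.k0 - u + current)
    v += noise_mv
    u += dt_ms * p.a * (p.b * v - u)
    spiked = v >= p.v_peak
    if spiked:
        v = p.c
        u += p.d
    if not (np.isfinite(v) and np.isfinite(u)):
        raise ArithmeticError("neuron state became non-finite")
    return NeuronState(v=v, u=u), bool(spiked)


def measure_fi_curve(params: IzhikevichParams, currents, dt_ms: float = 1.0,
                     settle_ms: float = 1000.0, measure_ms: float = 3000.0) -> np.ndarray:
    """Noise-free firing rate (Hz) for each injected current (vectorized)."""
    currents = np.asarray(currents, dtype=np.float64)
    v = np.full(currents.shape, -60.0)
    u = np.full(currents.shape, params.b * -60.0)
    counts = np.zeros(currents.shape)
    n_settle = int(round(settle_ms / dt_ms))
    n_meas = int(round(measure_ms / dt_ms))
    for step in range(n_settle + n_meas):
        for _ in range(2):
            v += 0.5 * dt_ms * (params.k2 * v * v + params.k1 * v + params.k0 - u + currents)
        u += dt_ms * params.a * (params.b * v - u)
        spk = v >= params.v_peak
        v[spk] = params.c
        u[spk] += params.d
        if step >= n_settle:
            counts += spk
    return counts / (measure_ms / 1000.0)


@dataclass
class GainConfig:
    """Calibrated monotonic rate -> current map.

    ``currents``/``rates`` sample the measured noise-free f-I curve;
    ``i_silent`` is the largest probed current that produced no spikes (used
    for rate 0, guaranteeing silence at rest). ``method`` is 'interp'
    (piecewise-linear inversion, default) or 'linear' (straight-line fit to
    the inverse curve).
    """

    currents: np.ndarray
    rates: np.ndarray
    i_silent: float
    method: str = "interp"
    slope: float = 0.0
    intercept: float = 0.0


def calibrate_gain(params: IzhikevichParams, target_range: tuple[float, float] = (0.0, 300.0),
                   method: str = "interp", dt_ms: float = 1.0) -> GainConfig:
    """Fit the rate -> current map by inverting the measured f-I curve.

    Deterministic (the f-I measurement is noise-free). Raises
    :class:`CalibrationError` if the target range is degenerate or the
    measured curve is not usable (non-monotonic beyond tolerance, or the
    neuron cannot reach the requested rate).
    """
    lo, hi = target_range
    if not (hi > lo >= 0):
        raise CalibrationError(f"degenerate target range {target_range}")
    if method not in ("interp", "linear"):
        raise CalibrationError(f"unknown calibration method '{method}'")
    # extend the sweep until the top target rate is reached
    i_max = 16.0
    for _ in range(8):
        currents = np.linspace(0.0, i_max, 49)
        rates = measure_fi_curve(params, currents, dt_ms=dt_ms)
        if rates[-1] >= hi:
            break
        i_max *= 2.0
    else:
        raise CalibrationError(f"neuron cannot reach {hi} Hz (got {rates[-1]:.1f} Hz)")
    if np.any(np.diff(rates) < -1.0):  # 1 Hz tolerance for count quantization
        raise CalibrationError("measured f-I curve is not monotonic")
    rates = np.maximum.accumulate(rates)
    silent = currents[rates == 0.0]
    i_silent = float(silent[-1]) if silent.size else 0.0
    cfg = GainConfig(currents=currents, rates=rates, i_silent=i_silent, method=method)
    if method == "linear":
        sel = (rates > 0) & (rates <= hi * 1.05)
        if sel.sum() < 2:
            raise CalibrationError("too few firing points for a linear fit")
        slope, intercept = np.polyfit(rates[sel], currents[sel], 1)
        cfg.slope, cfg.intercept = float(slope), float(intercept)
    return cfg


def rate_to_epsc(rate, gain: GainConfig):
    """Map firing rate (Hz) to injected current through the calibrated curve.

    Monotonic non-decreasing; rate 0 maps to a subthreshold current, so a
    silent spindle leaves a noise-free neuron silent.
    """
    arr = np.asarray(rate, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("rate must be >= 0")
    if gain.method == "linear":
        out = np.where(arr == 0.0, gain.i_silent,
                       np.maximum(gain.i_silent, gain.intercept + gain.slope * arr))
    else:
        fire = gain.rates > 0
        # inversion grid: the silent current, then the firing part of the curve
        xs = np.concatenate([[0.0], gain.rates[fire]])
        ys = np.concatenate([[gain.i_silent], gain.currents[fire]])
        out = np.interp(arr, xs, ys)
    return float(out) if np.asarray(rate).ndim == 0 else out


# ---------------------------------------------------------------------------
# Spike containers and the population runner
# ---------------------------------------------------------------------------

@dataclass
class SpikeRaster:
    """Merged spike record of one afferent population.

    ``times_ms``/``neuron_ids`` are parallel arrays; times are non-decreasing
    within each neuron (the runner emits them globally time-sorted).
    """

    times_ms: np.ndarray
    neuron_ids: np.ndarray
    n_neurons: int
    group: str = "Ia"

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if self.times_ms.shape != self.neuron_ids.shape:
            raise ValueError("times and neuron ids must be parallel arrays")
        if self.n_neurons <= 0:
            raise ConfigError("n_neurons must be positive")
        if self.neuron_ids.size:
            if self.neuron_ids.min() < 0 or self.neuron_ids.max() >= self.n_neurons:
                raise ValueError("neuron id outside [0, n_neurons)")
            for nid in np.unique(self.neuron_ids):
                t = self.times_ms[self.neuron_ids == nid]
                if np.any(np.diff(t) < 0):
                    raise ValueError(f"spike times decrease for neuron {nid}")

    @property
    def n_spikes(self) -> int:
        return self.times_ms.size

    def spike_times(self, neuron_id: int) -> np.ndarray:
        return self.times_ms[self.neuron_ids == neuron_id]

    def binned_counts(self, bin_ms: float, t_max_ms: float) -> tuple[np.ndarray, np.ndarray]:
        """Population spike count per time bin; returns (bin_centers, counts)."""
        edges = np.arange(0.0, t_max_ms + bin_ms, bin_ms)
        counts, _ = np.histogram(self.times_ms, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, counts.astype(np.float64)


def run_population(rate_trace: np.ndarray, n_neurons: int, group: str,
                   master_seed: int, config: NeuronConfig | None = None) -> SpikeRaster:
    """Drive ``n_neurons`` identical neurons with one rate trace plus
    independent per-neuron LFSR noise; returns the merged raster.

    ``rate_trace`` must be sampled on the 1 ms grid. The EPSC timeline is the
    calibrated map of the rate trace and is shared by every neuron; the only
    per-neuron difference is the noise register seed, split off
    ``master_seed``. Bit-reproducible for a fixed (config, master_seed).
    """
    if n_neurons <= 0:
        raise ConfigError("n_neurons must be positive")
    cfg = config or NeuronConfig()
    if cfg.gain is None:
        cfg = replace(cfg, gain=calibrate_gain(cfg.params))
    rate_trace = np.asarray(rate_trace, dtype=np.float64)
    if rate_trace.ndim != 1:
        raise ValueError("rate_trace must be 1-D")
    currents = rate_to_epsc(rate_trace, cfg.gain)

    p = cfg.params
    dt = cfg.dt_ms
    amp = cfg.noise_amplitude_mv
    states = _seed_states(master_seed, n_neurons)
    v = np.full(n_neurons, -60.0)
    u = np.full(n_neurons, p.b * -60.0)
    times: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    scale = amp / 2.0 ** 32
    for step, current in enumerate(currents):
        for _ in range(2):
            v += 0.5 * dt * (p.k2 * v * v + p.k1 * v + p.k0 - u + current)
        if amp > 0.0:
            states = _advance32(states)
            v += states * scale - 0.5 * amp
        u += dt * p.a * (p.b * v - u)
        spk = v >= p.v_peak
        if spk.any():
            v[spk] = p.c
            u[spk] += p.d
            nid = np.nonzero(spk)[0]
            ids.append(nid)
            times.append(np.full(nid.size, step * dt))
    if times:
        t_all = np.concatenate(times)
        id_all = np.concatenate(ids)
    else:
        t_all = np.empty(0)
        id_all = np.empty(0, dtype=np.int64)
    return SpikeRaster(times_ms=t_all, neuron_ids=id_all, n_neurons=n_neurons, group=group)
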