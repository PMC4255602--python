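"""Three-fiber muscle-spindle rate model (bag1, bag2, chain).

Each intrafusal fiber is a second-order spring-damper: the sensory region
(spring ``k_sr``) in series with the polar region (spring ``k_pr``, nonlinear
damper, fusimotor force generator, mass ``m``). States per fiber:

* ``x0`` -- fusimotor activation in [0, 1], driven toward
  ``gamma**2 / (gamma**2 + omega**2)`` with time constant ``tau``
  (instantaneous when ``tau`` is None, as for the chain fiber);
* ``x1`` -- polar-region length (L0 units);
* ``x2`` -- polar-region velocity (L0/s).

Tensions::

    T_SR = k_sr * (L - x1 - l0_sr)
    T_B  = (b0 + b1*x0) * (x1 - r) * C * sign(x2) * |x2|**a_exp
    T_PR = k_pr * (x1 - l0_pr)
    m * dx2/dt = T_SR - T_B - T_PR - gamma_force * x0

The damping tension carries the sign of the polar-region velocity so that it
always opposes the motion; ``C`` takes one value for lengthening and a smaller
one for shortening (the classic velocity-sign asymmetry). ``1/m`` and the
activation decay factor are precomputed constants, mirroring a combinational
datapath that owns no divider.

Afferent rates: the Group Ia ending combines the per-fiber primary components
by partial occlusion (the larger of {bag1} and {bag2+chain} plus
``occlusion_factor`` times the smaller); the Group II ending sums bag2 and
chain secondary components, each mixing sensory-region and polar-region
strain. bag1 receives the dynamic fusimotor drive and contributes only to Ia;
bag2 and chain receive the static drive.

Default constants are the published cat-soleus set of the source rate model
this emulator implements; they are exposed in full through
:class:`SpindleConfig` and the run-configuration file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, NumericalInstabilityError
from .numerics import quarter_power
from .stimuli import GRID_DT_MS, Waveform

__all__ = [
    "FiberParameters",
    "FiberState",
    "SpindleInput",
    "SpindleState",
    "AfferentRates",
    "SpindleConfig",
    "SpindleTrace",
    "default_bag1",
    "default_bag2",
    "default_chain",
    "fusimotor_drive",
    "fusimotor_activation_derivative",
    "intrafusal_tensions",
    "fiber_derivatives",
    "step_fiber",
    "combine_afferents",
    "step_spindle",
    "fiber_equilibrium",
    "spindle_equilibrium",
    "simulate",
]


@dataclass
class FiberParameters:
    """Constants of one intrafusal fiber.

    Units: lengths in L0 (resting muscle length), forces in the source
    model's force units (FU), time in seconds, rates in Hz. ``gamma_force``
    scales the active fusimotor force on the polar region; ``g_primary`` and
    ``g_secondary`` convert sensory-region strain above threshold into
    afferent rate (Hz per L0 of strain).
    """

    name: str
    k_sr: float
    k_pr: float
    b0: float
    b1: float
    m: float
    l0_sr: float
    l0_pr: float
    l_n_sr: float
    gamma_force: float
    tau: float | None
    omega: float
    fusimotor_source: str  # 'dynamic' or 'static'
    g_primary: float
    g_secondary: float = 0.0
    l_n_pr: float | None = None
    c_lengthen: float = 1.0
    c_shorten: float = 0.42
    r: float = 0.46
    a_exp: float = 0.3

    def __post_init__(self):
        if self.m <= 0:
            raise ConfigError(f"{self.name}: mass m must be positive")
        if self.k_sr <= 0 or self.k_pr <= 0:
            raise ConfigError(f"{self.name}: spring constants must be positive")
        if self.g_primary < 0 or self.g_secondary < 0:
            raise ConfigError(f"{self.name}: rate gains must be >= 0")
        if self.tau is not None and self.tau <= 0:
            raise ConfigError(f"{self.name}: tau must be positive (or null for instantaneous)")
        if self.omega <= 0:
            raise ConfigError(f"{self.name}: omega must be positive")
        if self.fusimotor_source not in ("dynamic", "static"):
            raise ConfigError(f"{self.name}: fusimotor_source must be 'dynamic' or 'static'")

    @property
    def inv_m(self) -> float:
        return 1.0 / self.m

    @property
    def threshold_strain(self) -> float:
        """Sensory-region strain below which the ending stays silent."""
        return self.l_n_sr - self.l0_sr


@dataclass
class FiberState:
    """Dynamical state of one fiber: activation, polar length, polar velocity."""

    x0: float = 0.0
    x1: float = 0.9
    x2: float = 0.0

    def validate(self):
        if not (0.0 <= self.x0 <= 1.0):
            raise ValueError(f"x0={self.x0} outside [0, 1]")
        if not (math.isfinite(self.x1) and math.isfinite(self.x2)):
            raise ValueError("fiber state must be finite")


@dataclass
class SpindleInput:
    """Instantaneous muscle length (L0) and fusimotor rates (Hz)."""

    length: float
    gamma_dyn: float = 0.0
    gamma_stat: float = 0.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("muscle length must be positive (L0 units)")
        if self.gamma_dyn < 0 or self.gamma_stat < 0:
            raise ValueError("fusimotor rates must be >= 0")


@dataclass
class SpindleState:
    bag1: FiberState = field(default_factory=FiberState)
    bag2: FiberState = field(default_factory=FiberState)
    chain: FiberState = field(default_factory=FiberState)


@dataclass
class AfferentRates:
    """Group Ia and Group II firing rates (Hz, both nonnegative)."""

    ia_rate: float
    ii_rate: float


def default_bag1(a_exp: float = 0.3) -> FiberParameters:
    """Dynamic bag fiber: slow activation, strong velocity-scaled damping."""
    return FiberParameters(
        name="bag1", k_sr=10.4649, k_pr=0.15, b0=0.0605, b1=0.2592, m=0.0002,
        l0_sr=0.04, l0_pr=0.76, l_n_sr=0.0423, gamma_force=0.0289,
        tau=0.149, omega=60.0, fusimotor_source="dynamic",
        g_primary=20000.0, g_secondary=0.0, l_n_pr=None, a_exp=a_exp,
    )


def default_bag2(a_exp: float = 0.3) -> FiberParameters:
    """Static bag fiber: drives both primary and secondary endings."""
    return FiberParameters(
        name="bag2", k_sr=10.4649, k_pr=0.15, b0=0.0822, b1=-0.046, m=0.0002,
        l0_sr=0.04, l0_pr=0.76, l_n_sr=0.0423, gamma_force=0.0636,
        tau=0.205, omega=60.0, fusimotor_source="static",
        g_primary=10000.0, g_secondary=7250.0, l_n_pr=0.89, a_exp=a_exp,
    )


def default_chain(a_exp: float = 0.3) -> FiberParameters:
    """Nuclear chain fiber: effectively instantaneous activation (tau=None)."""
    return FiberParameters(
        name="chain", k_sr=10.4649, k_pr=0.15, b0=0.0822, b1=-0.069, m=0.0002,
        l0_sr=0.04, l0_pr=0.76, l_n_sr=0.0423, gamma_force=0.0954,
        tau=None, omega=90.0, fusimotor_source="static",
        g_primary=10000.0, g_secondary=7250.0, l_n_pr=0.89, a_exp=a_exp,
    )


@dataclass
class SpindleConfig:
    """Whole-spindle configuration: three fibers plus combination constants.

    ``occlusion_factor`` is the partial-occlusion weight of the smaller Ia
    component (the single most model-sensitive constant); ``x_fraction`` and
    ``l_secondary`` weight the sensory- vs polar-region contributions of the
    secondary ending. ``arithmetic_mode`` selects double precision ('exact')
    or the single-precision combinational datapath ('fpga_faithful').
    """

    bag1: FiberParameters = field(default_factory=default_bag1)
    bag2: FiberParameters = field(default_factory=default_bag2)
    chain: FiberParameters = field(default_factory=default_chain)
    occlusion_factor: float = 0.156
    x_fraction: float = 0.7
    l_secondary: float = 0.04
    arithmetic_mode: str = "exact"
    integrator: str = "rk4"
    substeps_per_ms: int = 10

    def __post_init__(self):
        if self.arithmetic_mode not in ("exact", "fpga_faithful"):
            raise ConfigError("arithmetic_mode must be 'exact' or 'fpga_faithful'")
        if self.integrator not in ("rk4", "euler"):
            raise ConfigError("integrator must be 'rk4' or 'euler'")
        if self.substeps_per_ms < 1:
            raise ConfigError("substeps_per_ms must be >= 1")
        if not (0.0 <= self.occlusion_factor <= 1.0):
            raise ConfigError("occlusion_factor must lie in [0, 1]")

    @classmethod
    def default(cls, arithmetic_mode: str = "exact") -> "SpindleConfig":
        """Default spindle; the FPGA-faithful datapath uses the 0.25 velocity
        exponent (the quarter power is what two chained inverse-square-root
        blocks provide)."""
        a = 0.25 if arithmetic_mode == "fpga_faithful" else 0.3
        return cls(bag1=default_bag1(a), bag2=default_bag2(a), chain=default_chain(a),
                   arithmetic_mode=arithmetic_mode)

    @property
    def fibers(self) -> dict[str, FiberParameters]:
        return {"bag1": self.bag1, "bag2": self.bag2, "chain": self.chain}


def fusimotor_drive(gamma: float, params: FiberParameters) -> float:
    """Steady-state activation ``gamma^2 / (gamma^2 + omega^2)``."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    g2 = gamma * gamma
    return g2 / (g2 + params.omega * params.omega)


def fusimotor_activation_derivative(x0: float, gamma: float, params: FiberParameters) -> float:
    """``dx0/dt = (gamma^2/(gamma^2+omega^2) - x0) / tau``."""
    if params.tau is None:
        raise ConfigError(f"{params.name}: activation is instantaneous (tau is null); "
                          "no derivative is defined")
    return (fusimotor_drive(gamma, params) - x0) / params.tau


def _tb_exact(x0, x1, x2, p: FiberParameters) -> float:
    if x2 == 0.0:
        return 0.0
    coeff = (p.b0 + p.b1 * x0) * (x1 - p.r)
    if x2 > 0.0:
        return coeff * p.c_lengthen * x2 ** p.a_exp
    return -coeff * p.c_shorten * (-x2) ** p.a_exp


def _tb_fpga(x0, x1, x2, p: FiberParameters) -> float:
    f = np.float32
    if x2 == 0.0:
        return 0.0
    coeff = f(f(f(p.b0) + f(f(p.b1) * f(x0))) * f(f(x1) - f(p.r)))
    mag = abs(x2)
    vel = quarter_power(mag) if p.a_exp == 0.25 else float(f(mag) ** f(p.a_exp))
    if x2 > 0.0:
        return float(f(f(coeff * f(p.c_lengthen)) * f(vel)))
    return -float(f(f(coeff * f(p.c_shorten)) * f(vel)))


def intrafusal_tensions(state: FiberState, length: float, params: FiberParameters,
                        arith: str = "exact") -> tuple[float, float, float]:
    """Sensory-region, damping, and polar-region tensions ``(T_SR, T_B, T_PR)``."""
    if length <= 0:
        raise ValueError("muscle length must be positive")
    if arith == "fpga_faithful":
        f = np.float32
        t_sr = float(f(f(params.k_sr) * f(f(f(length) - f(state.x1)) - f(params.l0_sr))))
        t_b = _tb_fpga(state.x0, state.x1, state.x2, params)
        t_pr = float(f(f(params.k_pr) * f(f(state.x1) - f(params.l0_pr))))
    else:
        t_sr = params.k_sr * (length - state.x1 - params.l0_sr)
        t_b = _tb_exact(state.x0, state.x1, state.x2, params)
        t_pr = params.k_pr * (state.x1 - params.l0_pr)
    return t_sr, t_b, t_pr


def fiber_derivatives(state: FiberState, inp: SpindleInput, params: FiberParameters,
                      arith: str = "exact") -> tuple[float, float, float]:
    """State derivatives ``(dx0, dx1, dx2)``.

    ``dx2`` uses the precomputed ``1/m``; for instantaneous-activation fibers
    ``dx0`` is reported as 0 (the activation is pinned to its drive).
    """
    gamma = inp.gamma_dyn if params.fusimotor_source == "dynamic" else inp.gamma_stat
    if params.tau is None:
        dx0 = 0.0
    else:
        dx0 = fusimotor_activation_derivative(state.x0, gamma, params)
    t_sr, t_b, t_pr = intrafusal_tensions(state, inp.length, params, arith)
    dx2 = (t_sr - t_b - t_pr - params.gamma_force * state.x0) * params.inv_m
    return dx0, state.x2, dx2


def _advance_polar(x1, x2, x0, length, h, p: FiberParameters, integrator: str, arith: str):
    """One substep of the (x1, x2) subsystem with activation and length frozen."""
    tb = _tb_fpga if arith == "fpga_faithful" else _tb_exact
    ksr, kpr, l0sr, l0pr, gf, inv_m = p.k_sr, p.k_pr, p.l0_sr, p.l0_pr, p.gamma_force, p.inv_m
    force0 = gf * x0

    def d2(a1, a2):
        t_sr = ksr * (length - a1 - l0sr)
        t_pr = kpr * (a1 - l0pr)
        return (t_sr - tb(x0, a1, a2, p) - t_pr - force0) * inv_m

    if integrator == "euler":
        return x1 + h * x2, x2 + h * d2(x1, x2)
    k1v = d2(x1, x2)
    k2x = x2 + 0.5 * h * k1v
    k2v = d2(x1 + 0.5 * h * x2, k2x)
    k3x = x2 + 0.5 * h * k2v
    k3v = d2(x1 + 0.5 * h * k2x, k3x)
    k4x = x2 + h * k3v
    k4v = d2(x1 + h * k3x, k4x)
    nx1 = x1 + h / 6.0 * (x2 + 2.0 * k2x + 2.0 * k3x + k4x)
    nx2 = x2 + h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    return nx1, nx2


def step_fiber(state: FiberState, inp: SpindleInput, params: FiberParameters,
               dt_s: float = 1e-3, arith: str = "exact", integrator: str = "rk4",
               substeps: int = 10) -> FiberState:
    """Advance one fiber by ``dt_s`` using ``substeps`` fixed substeps.

    The activation follows its linear ODE with an exact exponential update
    (a precomputed decay factor per substep); the polar-region pair is
    advanced with the configured explicit integrator. ``x0`` is clipped to
    [0, 1] and the final state is checked for finiteness.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    gamma = inp.gamma_dyn if params.fusimotor_source == "dynamic" else inp.gamma_stat
    drive = fusimotor_drive(gamma, params)
    h = dt_s / substeps
    decay = math.exp(-h / params.tau) if params.tau is not None else 0.0
    x0, x1, x2 = state.x0, state.x1, state.x2
    for _ in range(substeps):
        x0 = drive + (x0 - drive) * decay
        x1, x2 = _advance_polar(x1, x2, x0, inp.length, h, params, integrator, arith)
    x0 = min(1.0, max(0.0, x0))
    if not (math.isfinite(x1) and math.isfinite(x2)):
        raise NumericalInstabilityError(
            f"fiber '{params.name}' diverged (x1={x1}, x2={x2}); "
            "reduce the substep size or check the parameters")
    return FiberState(x0=x0, x1=x1, x2=x2)


def _primary_component(t_sr: float, p: FiberParameters) -> float:
    return max(0.0, p.g_primary * (t_sr / p.k_sr - p.threshold_strain))


def _secondary_component(t_sr: float, length: float, p: FiberParameters,
                         cfg: SpindleConfig) -> float:
    if p.g_secondary == 0.0 or p.l_n_pr is None:
        return 0.0
    sr_strain = t_sr / p.k_sr - p.threshold_strain
    polar = length - t_sr / p.k_sr - p.l0_sr - p.l_n_pr
    val = p.g_secondary * (cfg.x_fraction * (cfg.l_secondary / p.l0_sr) * sr_strain
                           + (1.0 - cfg.x_fraction) * (cfg.l_secondary / p.l0_pr) * polar)
    return max(0.0, val)


def combine_afferents(length: float, tensions: dict[str, float],
                      config: SpindleConfig) -> AfferentRates:
    """Combine per-fiber sensory-region tensions into Ia and II rates.

    ``tensions`` maps fiber name to its T_SR. The Ia ending applies partial
    occlusion between the bag1 component and the bag2+chain component; the II
    ending sums the bag2 and chain secondary components (bag1 contributes
    nothing to Group II). All rates are clipped at zero.
    """
    comp_b1 = _primary_component(tensions["bag1"], config.bag1)
    comp_static = (_primary_component(tensions["bag2"], config.bag2)
                   + _primary_component(tensions["chain"], config.chain))
    larger, smaller = max(comp_b1, comp_static), min(comp_b1, comp_static)
    ia = larger + config.occlusion_factor * smaller
    ii = (_secondary_component(tensions["bag2"], length, config.bag2, config)
          + _secondary_component(tensions["chain"], length, config.chain, config))
    return AfferentRates(ia_rate=max(0.0, ia), ii_rate=max(0.0, ii))


def step_spindle(state: SpindleState, inp: SpindleInput, dt_s: float,
                 config: SpindleConfig) -> tuple[SpindleState, AfferentRates]:
    """Advance all three fibers by ``dt_s`` and combine the afferent rates."""
    new = SpindleState(
        bag1=step_fiber(state.bag1, inp, config.bag1, dt_s, config.arithmetic_mode,
                        config.integrator, config.substeps_per_ms * max(1, round(dt_s * 1000))),
        bag2=step_fiber(state.bag2, inp, config.bag2, dt_s, config.arithmetic_mode,
                        config.integrator, config.substeps_per_ms * max(1, round(dt_s * 1000))),
        chain=step_fiber(state.chain, inp, config.chain, dt_s, config.arithmetic_mode,
                         config.integrator, config.substeps_per_ms * max(1, round(dt_s * 1000))),
    )
    tensions = {name: intrafusal_tensions(getattr(new, name), inp.length, p,
                                          config.arithmetic_mode)[0]
                for name, p in config.fibers.items()}
    return new, combine_afferents(inp.length, tensions, config)


def fiber_equilibrium(length: float, gamma: float, params: FiberParameters) -> FiberState:
    """Static equilibrium: activation at its drive, tensions balanced, x2 = 0."""
    x0 = fusimotor_drive(gamma, params)
    x1 = (params.k_sr * (length - params.l0_sr) + params.k_pr * params.l0_pr
          - params.gamma_force * x0) / (params.k_sr + params.k_pr)
    return FiberState(x0=x0, x1=x1, x2=0.0)


def spindle_equilibrium(length: float, gamma_dyn: float, gamma_stat: float,
                        config: SpindleConfig) -> SpindleState:
    return SpindleState(
        bag1=fiber_equilibrium(length, gamma_dyn, config.bag1),
        bag2=fiber_equilibrium(length, gamma_stat, config.bag2),
        chain=fiber_equilibrium(length, gamma_stat, config.chain),
    )


@dataclass
class SpindleTrace:
    """Rate-model output on the 1 ms grid."""

    time_ms: np.ndarray
    length: np.ndarray
    ia_rate: np.ndarray
    ii_rate: np.ndarray
    final_state: SpindleState


def _as_gamma_array(gamma, n: int, name: str) -> np.ndarray:
    arr = np.asarray(gamma, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be a scalar or match the waveform length")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    return arr


def _run_fiber(p: FiberParameters, L_sub: np.ndarray, g_sub: np.ndarray,
               nsub: int, h: float, integrator: str, arith: str,
               state: FiberState) -> tuple[np.ndarray, FiberState]:
    """Integrate one fiber over the whole stimulus; returns x1 at the ms grid."""
    n_int = L_sub.size // nsub  # number of sample intervals
    x1_out = np.empty(n_int + 1)
    x0, x1, x2 = state.x0, state.x1, state.x2
    x1_out[0] = x1
    om2 = p.omega * p.omega
    decay = math.exp(-h / p.tau) if p.tau is not None else 0.0
    Ls = L_sub
    gs = g_sub
    idx = 0
    for i in range(n_int):
        for _ in range(nsub):
            g = gs[idx]
            drive = g * g / (g * g + om2)
            x0 = drive if p.tau is None else drive + (x0 - drive) * decay
            x1, x2 = _advance_polar(x1, x2, x0, Ls[idx], h, p, integrator, arith)
            idx += 1
        x1_out[i + 1] = x1
    if not np.all(np.isfinite(x1_out)) or not math.isfinite(x2):
        raise NumericalInstabilityError(
            f"fiber '{p.name}' diverged during simulation; "
            "reduce the substep size or check the parameters")
    return x1_out, FiberState(x0=min(1.0, max(0.0, x0)), x1=x1, x2=x2)


def simulate(waveform: Waveform, gamma_dyn=0.0, gamma_stat=0.0,
             config: SpindleConfig | None = None,
             initial_state: SpindleState | None = None) -> SpindleTrace:
    """Run the rate model over a stretch waveform.

    ``gamma_dyn`` / ``gamma_stat`` may be scalars or per-sample arrays (Hz).
    Inputs are linearly interpolated onto the substep grid; afferent rates
    are reported at the waveform's 1 ms grid. The initial state defaults to
    the static equilibrium for the first sample. Deterministic for fixed
    inputs.
    """
    if config is None:
        config = SpindleConfig.default()
    n = waveform.n
    gd = _as_gamma_array(gamma_dyn, n, "gamma_dyn")
    gs = _as_gamma_array(gamma_stat, n, "gamma_stat")
    if initial_state is None:
        initial_state = spindle_equilibrium(waveform.samples[0], gd[0], gs[0], config)

    nsub = config.substeps_per_ms
    h = (waveform.dt_ms / 1000.0) / nsub
    # substep grid: nsub interior points per sample interval; the fiber state
    # recorded at sample i is the state at that sample's time
    t_ms = waveform.times_ms
    t_sub = np.repeat(t_ms[:-1], nsub) + np.tile(
        (np.arange(1, nsub + 1) / nsub) * waveform.dt_ms, n - 1)
    L_sub = np.interp(t_sub, t_ms, waveform.samples)
    gd_sub = np.interp(t_sub, t_ms, gd)
    gs_sub = np.interp(t_sub, t_ms, gs)

    arith = config.arithmetic_mode
    x1_traces: dict[str, np.ndarray] = {}
    final: dict[str, FiberState] = {}
    for name, p in config.fibers.items():
        g_sub = gd_sub if p.fusimotor_source == "dynamic" else gs_sub
        st = getattr(initial_state, name)
        x1_traces[name], final[name] = _run_fiber(
            p, L_sub, g_sub, nsub, h, config.integrator, arith, st)

    # vectorized afferent combination from the stored polar-region lengths
    L_ms = waveform.samples
    dtype = np.float32 if arith == "fpga_faithful" else np.float64
    comp = {}
    for name, p in config.fibers.items():
        t_sr = (p.k_sr * (L_ms - x1_traces[name] - p.l0_sr)).astype(dtype)
        comp[name] = (t_sr, p)

    def primary(name):
        t_sr, p = comp[name]
        return np.maximum(0.0, p.g_primary * (t_sr / dtype(p.k_sr) - dtype(p.threshold_strain)))

    def secondary(name):
        t_sr, p = comp[name]
        if p.g_secondary == 0.0 or p.l_n_pr is None:
            return np.zeros_like(t_sr)
        sr_strain = t_sr / dtype(p.k_sr) - dtype(p.threshold_strain)
        polar = L_ms.astype(dtype) - t_sr / dtype(p.k_sr) - dtype(p.l0_sr) - dtype(p.l_n_pr)
        val = p.g_secondary * (config.x_fraction * (config.l_secondary / p.l0_sr) * sr_strain
                               + (1.0 - config.x_fraction) * (config.l_secondary / p.l0_pr) * polar)
        return np.maximum(0.0, val)

    p_b1 = primary("bag1")
    p_st = primary("bag2") + primary("chain")
    larger = np.maximum(p_b1, p_st)
    smaller = np.minimum(p_b1, p_st)
    ia = np.maximum(0.0, larger + config.occlusion_factor * smaller)
    ii = np.maximum(0.0, secondary("bag2") + secondary("chain"))

    return SpindleTrace(
        time_ms=t_ms,
        length=waveform.samples.copy(),
        ia_rate=np.asarray(ia, dtype=np.float64),
        ii_rate=np.asarray(ii, dtype=np.float64),
        final_state=SpindleState(**final),
    )
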