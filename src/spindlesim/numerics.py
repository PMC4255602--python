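"""Combinational-logic-style floating-point approximations and the
time-multiplexing budget.

A clock-free digital datapath cannot use iterative divider or CORDIC cores, so
division and fractional powers are built from the magic-constant inverse
square root (one bit-level initial guess refined by a single Newton-Raphson
iteration) composed with itself:

* ``Q(x) = fast_inv_sqrt(x) ~ x**-0.5``
* ``a / b  ~ a * Q(|b|) * Q(|b|)`` (sign restored for negative divisors)
* ``x**0.25 ~ Q(Q(x))``

All arithmetic in these routines is carried out in IEEE-754 single precision,
rounding after every multiply/add, to mirror the hardware datapath. The rest
of the library treats these as an opt-in ``fpga_faithful`` arithmetic mode;
the default ``exact`` mode uses ordinary double precision.

``serialization_budget`` computes how many neurons a time-multiplexed update
pipeline can serialize at a given clock rate, cycles per state update,
emulation granularity, and acceleration factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LOMONT_MAGIC",
    "QUAKE_MAGIC",
    "float_to_bits",
    "bits_to_float",
    "fast_inv_sqrt",
    "approx_divide",
    "quarter_power",
    "SerializationBudget",
    "serialization_budget",
]

#: Lomont's optimized initial-guess constant (default).
LOMONT_MAGIC = 0x5F375A86
#: The constant popularized by the Quake III source, kept as an alternative.
QUAKE_MAGIC = 0x5F3759DF


def float_to_bits(x):
    """Bit pattern of ``x`` as IEEE-754 single precision (uint32)."""
    arr = np.asarray(x, dtype=np.float32)
    bits = arr.view(np.uint32)
    return bits if arr.ndim else np.uint32(bits[()])


def bits_to_float(b):
    """Interpret a uint32 bit pattern as an IEEE-754 single-precision value."""
    arr = np.asarray(b, dtype=np.uint32)
    val = arr.view(np.float32)
    return val if arr.ndim else np.float32(val[()])


def _validated(x, name: str, *, positive: bool, allow_zero: bool = False):
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite (got NaN or infinity)")
    if positive:
        bad = (arr < 0) if allow_zero else (arr <= 0)
        if np.any(bad):
            cmp = ">= 0" if allow_zero else "> 0"
            raise ValueError(f"{name} must be {cmp}")
    return arr


def fast_inv_sqrt(x, magic: int = LOMONT_MAGIC):
    """Approximate ``1/sqrt(x)`` with the magic-constant method.

    One bit-level initial guess (``magic - (bits(x) >> 1)``) followed by
    exactly one Newton-Raphson refinement ``y * (1.5 - 0.5*x*y*y)``, with
    every operation rounded to single precision. Relative error stays below
    0.2% over many decades.

    Parameters
    ----------
    x : float or array_like
        Strictly positive finite value(s).
    magic : int
        Initial-guess constant; `LOMONT_MAGIC` by default, `QUAKE_MAGIC`
        as the documented alternative.
    """
    arr = _validated(x, "x", positive=True)
    scalar = np.asarray(x).ndim == 0
    xf = arr.astype(np.float32)
    i = np.uint32(magic) - (np.atleast_1d(xf).view(np.uint32) >> np.uint32(1))
    y = i.view(np.float32)
    xf1 = np.atleast_1d(xf)
    # single-precision ops round after each multiply/add, like the datapath
    half_x = np.float32(0.5) * xf1
    y = y * (np.float32(1.5) - half_x * (y * y))
    return float(y[0]) if scalar else y.astype(np.float32)


def approx_divide(a, b, magic: int = LOMONT_MAGIC):
    """Approximate ``a / b`` as ``a * Q(|b|) * Q(|b|)`` with sign restored.

    Two concatenated inverse-square-root blocks form ``1/|b|``; the sign of a
    negative divisor is reapplied at the end, so
    ``approx_divide(a, -b) == -approx_divide(a, b)`` bit-exactly.
    Relative error stays below 0.5% over many decades.
    """
    a_arr = _validated(a, "a", positive=False)
    b_arr = np.asarray(b, dtype=np.float64)
    if not np.all(np.isfinite(b_arr)):
        raise ValueError("b must be finite (got NaN or infinity)")
    if np.any(b_arr == 0):
        raise ValueError("division by zero: b must be nonzero")
    scalar = np.asarray(a).ndim == 0 and np.asarray(b).ndim == 0
    q = np.atleast_1d(np.asarray(fast_inv_sqrt(np.abs(b_arr), magic=magic), dtype=np.float32))
    af = np.atleast_1d(a_arr.astype(np.float32))
    mag = af * (q * q)
    out = np.where(np.atleast_1d(b_arr) < 0, -mag, mag).astype(np.float32)
    return float(out[0]) if scalar else out


def quarter_power(x, magic: int = LOMONT_MAGIC):
    """Approximate ``x**0.25`` as ``Q(Q(x))`` for ``x > 0``; 0 maps to 0.

    ``(x**-0.5)**-0.5 = x**0.25``, so two chained inverse-square-root blocks
    raise to the quarter power without a divider or exponential unit. The
    magic-constant method requires a strictly positive argument; the value at
    zero is defined as 0 by continuity because the spindle damping term must
    evaluate at zero polar-region velocity.
    """
    arr = _validated(x, "x", positive=True, allow_zero=True)
    scalar = np.asarray(x).ndim == 0
    flat = np.atleast_1d(arr)
    out = np.zeros(flat.shape, dtype=np.float32)
    pos = flat > 0
    if np.any(pos):
        out[pos] = fast_inv_sqrt(
            np.atleast_1d(np.asarray(fast_inv_sqrt(flat[pos], magic=magic))), magic=magic
        )
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SerializationBudget:
    """Time-multiplexing budget for serializing neuron updates.

    ``n_serial_max`` is the largest integer count satisfying
    ``c_cycles * n * accel * f_emu <= f_fpga``; ``ratio`` is the real-valued
    bound ``f_fpga / (c_cycles * accel * f_emu)`` before flooring.
    """

    f_fpga: float
    c_cycles: float
    f_emu: float
    accel: float
    ratio: float
    n_serial_max: int


def serialization_budget(f_fpga: float, c_cycles: float, f_emu: float, accel: float) -> SerializationBudget:
    """Maximum number of neurons serializable on one shared update pipeline.

    Parameters
    ----------
    f_fpga : float
        Fastest usable central clock rate, Hz.
    c_cycles : float
        Clock cycles consumed per state-variable update (memory access bound).
    f_emu : float
        Emulation granularity rate, Hz (1 kHz for a 1 ms update step).
    accel : float
        Acceleration factor over real time.
    """
    for name, v in (("f_fpga", f_fpga), ("c_cycles", c_cycles), ("f_emu", f_emu), ("accel", accel)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite")
    ratio = f_fpga / (c_cycles * accel * f_emu)
    return SerializationBudget(
        f_fpga=f_fpga,
        c_cycles=c_cycles,
        f_emu=f_emu,
        accel=accel,
        ratio=ratio,
        n_serial_max=int(np.floor(ratio)),
    )
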