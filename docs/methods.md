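# Methods

`spindlesim` emulates the mammalian muscle spindle and its spiking afferents
in software: a rate-based three-fiber intrafusal model converts muscle length
and fusimotor drive into Group Ia and Group II firing rates, and populations
of noisy quadratic (Izhikevich) Class-1 neurons convert those rates into
spike trains. An optional *FPGA-faithful* arithmetic mode reproduces the
numeric approximations a clock-free combinational hardware datapath must use.
This note records the model, its assumptions, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## 1. Intrafusal fiber model

Each of the three intrafusal fibers (dynamic bag1, static bag2, nuclear
chain) is a second-order mechanical element: a sensory-region spring in
series with a polar region composed of a spring, a nonlinear damper, an
active fusimotor force generator, and a small mass. Per fiber, states are
the fusimotor activation `x0` in [0, 1], the polar-region length `x1` (L0
units, where L0 is the resting muscle length), and its velocity `x2` (L0/s):

    dx0/dt = ( γ² / (γ² + Ω²) − x0 ) / τ
    dx1/dt = x2
    dx2/dt = ( T_SR − T_B − T_PR − Γ·x0 ) / M

    T_SR = K_SR (L − x1 − L0_SR)                      sensory-region spring
    T_B  = (B0 + B1·x0)(x1 − R)·C·sign(x2)·|x2|^a     polar damping
    T_PR = K_PR (x1 − L0_PR)                          polar-region spring

The damping tension carries `sign(x2)` so that it always opposes polar-region
motion; `C` is 1.0 for lengthening and 0.42 for shortening (the classic
velocity-sign asymmetry; at `x2 = 0` the term vanishes so the tie is moot).
The velocity exponent is `a = 0.3` in the reference parameterization and
`a = 0.25` in the FPGA-faithful mode (section 4). `1/M` and the activation
decay factor are treated as precomputed constants, the way a combinational
datapath without a divider treats them.

Fusimotor routing: the dynamic drive γ_dyn activates bag1 only; the static
drive γ_stat activates bag2 and chain. The chain fiber has no slow activation
dynamics: its `τ` is null and `x0` is pinned to the saturation
`γ²/(γ²+Ω²)` each step (configurable to a finite τ). For bag2 and chain the
activation-scaled damping coefficient `B1` is *negative* — static drive
reduces damping — while their force constants `Γ` are larger than bag1's;
this is exactly what makes γ_stat raise tonic rates while γ_dyn raises
phasic sensitivity.

### Afferent combination

Per fiber, the primary (Ia) component is `G_p (T_SR/K_SR − (L_N_SR − L0_SR))`
clipped at zero: sensory-region strain above a threshold, scaled to Hz. The
Ia ending combines bag1 against the static pair by **partial occlusion**:

    Ia = max(b1, b2 + ch) + S · min(b1, b2 + ch),     S = 0.156

The Group II rate sums the bag2 and chain secondary components (bag1 does not
contribute to II). Each secondary component mixes sensory-region and
polar-region strain:

    II_f = G_s [ X (L_s/L0_SR) (T_SR/K_SR − (L_N_SR − L0_SR))
               + (1−X)(L_s/L0_PR) (L − T_SR/K_SR − L0_SR − L_N_PR) ]

with `X = 0.7` and `L_s = 0.04` L0. All rates are clipped at zero.

### Parameters

The defaults are the published cat-soleus constants of the rate model this
emulator implements (force units FU, lengths L0, time s, rates Hz):

| parameter | bag1 | bag2 | chain | meaning |
|---|---|---|---|---|
| K_SR | 10.4649 | 10.4649 | 10.4649 | sensory-region spring (FU/L0) |
| K_PR | 0.15 | 0.15 | 0.15 | polar-region spring (FU/L0) |
| B0 | 0.0605 | 0.0822 | 0.0822 | passive damping (FU·s/L0) |
| B1 | 0.2592 | −0.046 | −0.069 | activation-scaled damping |
| M | 0.0002 | 0.0002 | 0.0002 | polar mass term (FU·s²/L0) |
| Γ | 0.0289 | 0.0636 | 0.0954 | fusimotor force scale (FU) |
| Ω | 60 | 60 | 90 | half-activation rate (Hz) |
| τ | 0.149 | 0.205 | — (instant) | activation time constant (s) |
| L0_SR / L0_PR | 0.04 / 0.76 | same | same | rest lengths (L0) |
| L_N_SR / L_N_PR | 0.0423 / — | 0.0423 / 0.89 | 0.0423 / 0.89 | thresholds (L0) |
| G_p / G_s | 20000 / 0 | 10000 / 7250 | 10000 / 7250 | rate gains (Hz/L0) |

The occlusion factor `S = 0.156` is the single most model-sensitive constant:
it sets how much the losing branch of the Ia combination still contributes.
Every qualitative validation property in the test suite is written as an
ordering (phasic > tonic, facilitation > baseline, …), not as an absolute
rate, precisely so that conclusions are robust to modest changes in these
constants. All constants are exposed in the YAML run configuration.

### Integration

The fiber ODEs are integrated with a fixed-step explicit scheme on a substep
grid: default classical Runge-Kutta (RK4) with ten 0.1 ms substeps per 1 ms
output sample (explicit Euler is selectable, as is the substep count). The
second-order fiber equation is stiff at the 1 ms reporting grid
(`sqrt((K_SR+K_PR)/M) ≈ 230 rad/s`), which is why substeps are needed at
all. The activation ODE is linear with constant input within a substep and
is advanced exactly via a precomputed decay factor `exp(−h/τ)` — a pure
multiply-add, hence hardware-plausible.

Two numerical artifacts of the non-smooth `|x2|^a` damping are worth knowing:

* the discrete map's fixed point sits ~1e-5–1e-4 L0 away from the analytic
  force balance, so constant-input baselines creep by a few Hz over the
  first ~2 s and then hold constant. Experiments that need a clean baseline
  either start from the analytic equilibrium (the default initial state) and
  tolerate this small settling, or prepend a pre-stimulus segment;
* near `x2 = 0` the infinite slope of `|x2|^a` produces sub-Hz chatter in
  the reported rates. Both effects shrink with the substep size and neither
  affects the ordering-based validation properties.

Non-finite states abort the run with an error naming the fiber.

## 2. Spiking afferent populations

Each afferent group (128 Ia, 128 II by default) is a population of identical
quadratic integrate-and-fire neurons in the Izhikevich formulation:

    dv/dt = 0.04 v² + 4.1 v + 108 − u + I        (two half-steps per 1 ms)
    du/dt = a (b v − u),   spike & reset at v ≥ 30:  v ← c, u ← u + d

with the published Class-1 excitable set `a=0.02, b=−0.1, c=−55, d=6`. The
Class-1 property — firing rate continuous and monotone in current from 0 Hz —
is what makes the spindle-rate-to-current conversion well posed. The standard
regular-spiking set is available as a config alternative. At the 1 ms grid
the deterministic neuron shows quasi-periodic inter-spike patterns with
CV ≈ 0.1 (grid quantization); membrane noise raises this variability and
decorrelates neurons.

**Rate → EPSC calibration.** The noise-free f–I curve is measured by
simulation on a current sweep (3 s per level after a 1 s transient, sweep
extended until the top of the target range, default 0–300 Hz, is reached).
The rate→current map inverts this curve by monotone piecewise-linear
interpolation; zero rate maps to the largest probed silent current, so a
silent spindle leaves a noise-free neuron silent. A straight-line fit of the
inverse curve is available (`gain_method: linear`) but is not the default:
the Class-1 curve is strongly concave near threshold and a global line
misses low rates by more than the 20% round-trip budget the interpolating
map meets everywhere. Calibration is deterministic and cached per
configuration.

**Noise source.** Per neuron, one 32-bit maximal-length Galois LFSR
(taps 32, 22, 2, 1; period 2³²−1) is clocked 32 times per 1 ms sample and
the full register is read as a uniform 32-bit word, scaled to the configured
peak-to-peak amplitude (default 5 mV, i.e. uniform on ±2.5 mV) and added to
the membrane potential — not to the current. The 32-tick advance is applied
through four 256-entry byte lookup tables (the transition is linear over
GF(2)), which is bit-exact with serial stepping but vectorizes across the
population; a unit test asserts the bit-exactness. Register seeds are split
from a master seed via a seed-derivation tree, rejecting the all-zero state;
every experiment is therefore bit-reproducible from (config, master seed).
The "5 mV amplitude" is read as peak-to-peak; the ±5 mV reading is a config
switch away (`noise_amplitude_mv: 10`).

## 3. Stimuli and validation experiments

All stimuli are muscle-length time series in L0 units on the 1 ms grid,
generated as pure functions (ramp-and-hold, sinusoid, raised-cosine tap,
release ramp with a preserved velocity discontinuity, repeated triangular
stretch, and low-pass-filtered white noise). Protocol constants live in the
`experiments:` config block; the defaults are:

* **ramp-and-hold**: 0.368 L0 in 200 ms (the 14 mm / 38 mm cat-soleus
  stretch), 800 ms hold, dynamic index probed 500 ms after hold onset;
  "fusimotor intact" is emulated as 50 Hz tonic drive on both gammas (the
  physiological tone of an intact preparation is not a measured number;
  50 Hz is mid-range for fusimotor tone and is configurable);
* **fusimotor sinusoid**: 0.026 L0 peak-to-peak at 3 Hz, selected gamma
  stepping 0 → 80 Hz at the 3rd/4th-cycle boundary;
* **waveform battery**: linear stretch, 0.05 L0 / 20 ms raised-cosine tap
  (tap shape and width are modeling choices — the emulated hardware's tap is
  not specified), 0.2 L0 release in 100 ms from a 1.2 L0 hold, sinusoid;
* **triangular repetitions**: 25 repetitions of 0.1 L0 with 150 ms rise and
  fall, 500 ms apart — a fast rodent-style triangular stretch, chosen because
  the onset burst (in spindles and in this fiber model) is a fast-stretch
  phenomenon; at rises ≳ 0.5 s the model's rate trace shows no onset
  overshoot;
* **white noise**: 160 s of Gaussian noise low-pass filtered at 5 Hz
  (second-order Butterworth, forward-backward for zero phase), min-max
  rescaled to a 0.1 L0 span; population spike counts in 20 ms bins are
  correlated against the bin-averaged rate-model output, with the p-value
  from the standard t-transform of r. The bin width is a modeling choice;
  the conclusion is bin-robust (tests sweep 10/20/50 ms at reduced size).

Spike-train statistics: the dynamic index (ramp-peak rate minus the rate
500 ms into the hold); the trial-aligned averaged instantaneous-frequency
profile (each spike contributes the reciprocal of its preceding inter-spike
interval; samples pooled across neurons and repetitions in 10 ms bins).

## 4. FPGA-faithful arithmetic

The `fpga_faithful` mode mirrors a clock-free combinational datapath:

* all fiber-tension arithmetic is IEEE-754 single precision, rounded after
  every multiply/add;
* `Q(x) = 1/sqrt(x)` is the magic-constant method — initial guess
  `magic − (bits(x) >> 1)` plus exactly one Newton-Raphson iteration
  `y(1.5 − 0.5·x·y²)`. The default constant is Lomont's optimized
  `0x5f375a86` (the algorithm the design derives from); the Quake constant
  `0x5f3759df` is available. Measured worst-case relative error over
  x ∈ [1e-6, 1e6] is 0.18%;
* division is two concatenated blocks, `a·Q(|b|)·Q(|b|)`, with the sign of a
  negative divisor restored afterwards (bit-exact antisymmetry); worst-case
  error 0.35%;
* `x^0.25 = Q(Q(x))`, with `quarter_power(0) := 0` by continuity (the
  damping term must evaluate at zero polar velocity even though `Q`
  requires a positive argument); worst-case error 0.18%. The 0.2%/0.5%
  tolerances asserted in the tests are engineering bounds implied by the
  one-iteration Newton-Raphson error, not measured claims from the hardware;
* the velocity exponent becomes 0.25 (what two chained `Q` blocks provide)
  instead of 0.3. Both the exponent and the precision are independently
  selectable for ablation.

Over the ramp-and-hold protocol the FPGA-faithful Ia trace differs from the
exact trace by ~1% RMS of its dynamic range (the 5% acceptance bound is
generous); the dominant contribution is the 0.25-vs-0.3 exponent, not the
single-precision rounding.

`serialization_budget` computes the time-multiplexing bound
`n ≤ f_fpga / (c_cycles · accel · f_emu)` and floors it to an integer count;
the real-valued ratio is also reported, since the bound is conventionally
quoted rounded (273.97 ≈ 274 at 200 MHz, 2 cycles, 1 kHz, 365×) while the
integer count that respects the clock-budget inequality is 273.

## 5. What the synthetic experiments do and do not show

The stimulus generators emulate idealized laboratory protocols, not natural
movement: lengths are noiseless, perfectly sampled, and (except for the
filtered-noise stimulus) piecewise-analytic. The fiber model inherits the
known limits of its source: **no thixotropy** (no dependence on stretch
history), no tendon/muscle mechanics (length is imposed directly on the
spindle), and cat-soleus constants — human spindles differ (more
chain-dominated, stronger static response), so agreement here does not
certify human-scale predictions. Muscle tension is an internal variable and
is deliberately not an output. Passing the validation suite shows that the
implementation reproduces the *qualitative physiology* the rate model was
built for (Ia/II differentiation, gamma routing, velocity sensitivity,
release burst, onset burst) and the *quantitative* spike/rate coherence of
the white-noise protocol; it does not fit any new biological data.

## 6. Problem sizes and runtime choices

The full white-noise validation (160 s × 5 master seeds × 256 neurons) is
the largest computation in the repository; it is used unreduced in both the
acceptance script and the acceptance test suite. Unit and property tests use
reduced sizes chosen for speed without changing any model constant: 16-32
neurons per population, 20 s noise segments, 8 triangular repetitions.
Reported rates and correlations in the README were produced by the committed
code at the committed defaults.
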