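"""Run configuration: schema, validation, defaults, YAML round trip.

A run configuration materializes every tunable of the emulator -- arithmetic
mode, the three intrafusal fiber parameter blocks, the neuron model, the
population sizes, membrane-noise amplitude, the master seed, and the
experiment protocol constants. Loading rejects unknown keys and materializes
all defaults, so the frozen copy saved next to experiment outputs is
sufficient to regenerate them together with the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .neurons import GainConfig, IzhikevichParams, NeuronConfig, calibrate_gain
from .spindle import FiberParameters, SpindleConfig, default_bag1, default_bag2, default_chain

__all__ = ["ExperimentConfig", "RunConfig", "load_config", "save_config"]


@dataclass
class ExperimentConfig:
    """Protocol constants for the validation experiments.

    Stretch amplitudes are fractions of the resting length L0, durations in
    milliseconds, fusimotor rates in Hz. ``tonic_gamma_hz`` stands in for the
    unmeasured fusimotor tone of an intact preparation; ``bin_ms`` is the
    spike-count bin used by the raster/rate correlations.
    """

    ramp_amplitude: float = 0.368  # 14 mm on a 38 mm resting cat soleus
    ramp_ms: float = 200.0
    hold_ms: float = 800.0
    pre_ms: float = 200.0
    probe_delay_ms: float = 500.0
    tonic_gamma_hz: float = 50.0
    sin_p2p: float = 0.026  # 1 mm peak-to-peak on 38 mm
    sin_freq_hz: float = 3.0
    sin_cycles: int = 8
    gamma_step_hz: float = 80.0
    tap_amplitude: float = 0.05
    tap_width_ms: float = 20.0
    release_baseline: float = 1.2
    release_drop: float = 0.2
    release_ramp_ms: float = 100.0
    tri_amplitude: float = 0.1
    tri_rise_ms: float = 150.0
    tri_fall_ms: float = 150.0
    tri_reps: int = 25
    tri_inter_ms: float = 500.0
    freq_bin_ms: float = 10.0
    noise_duration_s: float = 160.0
    noise_cutoff_hz: float = 5.0
    noise_amplitude_l0: float = 0.1
    bin_ms: float = 20.0


@dataclass
class RunConfig:
    """Fully materialized emulator configuration."""

    arithmetic_mode: str = "exact"
    spindle: SpindleConfig = field(default_factory=SpindleConfig)
    neuron: IzhikevichParams = field(default_factory=IzhikevichParams)
    n_ia: int = 128
    n_ii: int = 128
    noise_amplitude_mv: float = 5.0
    master_seed: int = 12345
    gain_method: str = "interp"
    rate_range_hz: tuple[float, float] = (0.0, 300.0)
    experiments: ExperimentConfig = field(default_factory=ExperimentConfig)

    def __post_init__(self):
        if self.arithmetic_mode not in ("exact", "fpga_faithful"):
            raise ConfigError("arithmetic_mode must be 'exact' or 'fpga_faithful'")
        if self.n_ia <= 0 or self.n_ii <= 0:
            raise ConfigError("population sizes n_ia / n_ii must be positive")
        if self.noise_amplitude_mv < 0:
            raise ConfigError("noise_amplitude_mv must be >= 0")
        if self.spindle.arithmetic_mode != self.arithmetic_mode:
            self.spindle = replace(self.spindle, arithmetic_mode=self.arithmetic_mode)
        self._gain: GainConfig | None = None

    @classmethod
    def default(cls, arithmetic_mode: str = "exact") -> "RunConfig":
        return cls(arithmetic_mode=arithmetic_mode,
                   spindle=SpindleConfig.default(arithmetic_mode))

    def neuron_config(self) -> NeuronConfig:
        """Neuron-population configuration with a (cached) calibrated gain."""
        if self._gain is None:
            self._gain = calibrate_gain(self.neuron, tuple(self.rate_range_hz),
                                        method=self.gain_method)
        return NeuronConfig(params=self.neuron,
                            noise_amplitude_mv=self.noise_amplitude_mv,
                            gain=self._gain)


# ---------------------------------------------------------------------------
# dict / YAML round trip
# ---------------------------------------------------------------------------

_FIBER_DEFAULTS = {"bag1": default_bag1, "bag2": default_bag2, "chain": default_chain}


def _check_keys(d: dict, allowed, where: str):
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _fill_dataclass(obj, d: dict, where: str):
    """Replace fields of a dataclass instance from a plain dict."""
    names = {f.name for f in fields(obj)}
    _check_keys(d, names, where)
    return replace(obj, **d)


def _config_to_dict(cfg: RunConfig) -> dict:
    def dc(obj, skip=()):
        return {f.name: getattr(obj, f.name) for f in fields(obj) if f.name not in skip}

    return {
        "arithmetic_mode": cfg.arithmetic_mode,
        "n_ia": cfg.n_ia,
        "n_ii": cfg.n_ii,
        "noise_amplitude_mv": cfg.noise_amplitude_mv,
        "master_seed": cfg.master_seed,
        "gain_method": cfg.gain_method,
        "rate_range_hz": list(cfg.rate_range_hz),
        "neuron": dc(cfg.neuron),
        "spindle": {
            "occlusion_factor": cfg.spindle.occlusion_factor,
            "x_fraction": cfg.spindle.x_fraction,
            "l_secondary": cfg.spindle.l_secondary,
            "integrator": cfg.spindle.integrator,
            "substeps_per_ms": cfg.spindle.substeps_per_ms,
            "fibers": {name: dc(p, skip=("name",)) for name, p in cfg.spindle.fibers.items()},
        },
        "experiments": dc(cfg.experiments),
    }


def _config_from_dict(d: dict) -> RunConfig:
    if not isinstance(d, dict):
        raise ConfigError("configuration root must be a mapping")
    top = {f.name for f in fields(RunConfig)}
    _check_keys(d, top, "configuration root")
    mode = d.get("arithmetic_mode", "exact")
    cfg = RunConfig.default(mode)

    sp = dict(d.get("spindle") or {})
    _check_keys(sp, {"occlusion_factor", "x_fraction", "l_secondary", "integrator",
                     "substeps_per_ms", "fibers"}, "spindle")
    fiber_dicts = dict(sp.pop("fibers", {}) or {})
    _check_keys(fiber_dicts, _FIBER_DEFAULTS, "spindle.fibers")
    a_default = 0.25 if mode == "fpga_faithful" else 0.3
    fiber_objs = {}
    for name, make in _FIBER_DEFAULTS.items():
        base = make(a_default)
        fiber_objs[name] = _fill_dataclass(base, dict(fiber_dicts.get(name) or {}),
                                           f"spindle.fibers.{name}")
    spindle_cfg = SpindleConfig(bag1=fiber_objs["bag1"], bag2=fiber_objs["bag2"],
                                chain=fiber_objs["chain"], arithmetic_mode=mode,
                                **sp)

    neuron = _fill_dataclass(IzhikevichParams(), dict(d.get("neuron") or {}), "neuron")
    exper = _fill_dataclass(ExperimentConfig(), dict(d.get("experiments") or {}),
                            "experiments")
    scalar = {k: d[k] for k in ("n_ia", "n_ii", "noise_amplitude_mv", "master_seed",
                                "gain_method") if k in d}
    rr = d.get("rate_range_hz")
    if rr is not None:
        if len(rr) != 2:
            raise ConfigError("rate_range_hz must be a [low, high] pair")
        scalar["rate_range_hz"] = (float(rr[0]), float(rr[1]))
    return RunConfig(arithmetic_mode=mode, spindle=spindle_cfg, neuron=neuron,
                     experiments=exper, **scalar)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults are materialized.

    An empty file yields the default configuration. Unknown keys anywhere in
    the tree raise :class:`ConfigError` naming the key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    try:
        return _config_from_dict(data)
    except TypeError as exc:  # wrong structure (e.g. list where mapping expected)
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully materialized configuration (frozen provenance copy)."""
    Path(path).write_text(yaml.safe_dump(_config_to_dict(cfg), sort_keys=False))
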