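"""Scripted validation protocols and the spike-train statistics they need.

Each experiment runs a stimulus through the rate model and the spiking
afferent populations and returns an :class:`ExperimentResult` holding the
waveform, the Ia/II rate traces, the spike rasters, and derived statistics:

* stretch-and-hold -- phasic/tonic differentiation of Ia vs II, with and
  without tonic fusimotor drive (dynamic index; within-run raster/rate
  agreement);
* fusimotor sinusoid -- selective gamma-dynamic vs gamma-static activation
  during a small 3 Hz sinusoidal stretch (per-cycle modulation depth and
  cycle-mean rate, before vs after the gamma step);
* waveform battery -- linear stretch, tap, sinusoid, and release through the
  full populations (including the post-release Ia burst);
* triangular repetitions -- averaged instantaneous-frequency profile and its
  initial burst;
* white-noise system identification -- Pearson correlation between binned
  population spike counts and the rate-model output.

All experiments are bit-reproducible given (config, master seed): every
population's noise registers are seeded from the master seed through a
labelled seed-derivation tree, and the stimulus generators are pure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from . import stimuli
from .config import RunConfig
from .neurons import SpikeRaster, run_population
from .spindle import SpindleTrace, simulate
from .stimuli import Waveform

__all__ = [
    "ExperimentResult",
    "WhiteNoiseResult",
    "derive_seed",
    "binned_rate",
    "raster_rate_correlation",
    "instantaneous_frequency",
    "dynamic_index",
    "stretch_and_hold_experiment",
    "fusimotor_sinusoid_experiment",
    "waveform_battery",
    "triangular_frequency_experiment",
    "white_noise_correlation",
]


@dataclass
class ExperimentResult:
    """Outputs of one validation protocol on the shared 1 ms grid."""

    label: str
    waveform: Waveform
    time_ms: np.ndarray
    ia_rate: np.ndarray
    ii_rate: np.ndarray
    rasters: dict[str, SpikeRaster] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)


def derive_seed(master_seed: int, *key: int) -> int:
    """Stable sub-seed for a labelled purpose, below 2**31."""
    ss = np.random.SeedSequence([int(master_seed)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def binned_rate(rate: np.ndarray, bin_ms: float, dt_ms: float = 1.0) -> np.ndarray:
    """Mean of a 1 ms rate trace over consecutive bins of ``bin_ms``."""
    per = int(round(bin_ms / dt_ms))
    n_bins = rate.size // per
    return rate[: n_bins * per].reshape(n_bins, per).mean(axis=1)


def raster_rate_correlation(raster: SpikeRaster, rate: np.ndarray,
                            bin_ms: float = 20.0) -> tuple[float, float]:
    """Pearson r (and p) between binned population counts and the rate trace.

    The p-value is the standard t-transform of r. Raises if either binned
    series has zero variance (correlation undefined).
    """
    _, counts = raster.binned_counts(bin_ms, float(rate.size))
    model = binned_rate(rate, bin_ms)
    n = min(counts.size, model.size)
    counts, model = counts[:n], model[:n]
    if np.std(counts) == 0 or np.std(model) == 0:
        raise ValueError("correlation undefined: a binned series has zero variance")
    r, p = _stats.pearsonr(counts, model)
    return float(r), float(p)


def instantaneous_frequency(raster: SpikeRaster, onsets_ms, window_ms: float,
                            bin_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Trial-aligned averaged instantaneous-frequency profile.

    Each spike contributes ``1 / (preceding inter-spike interval)``; samples
    are aligned to the trial onsets and averaged within ``bin_ms`` bins
    across all trials and neurons. A raster with no ISIs yields empty arrays
    (single spikes carry no frequency).
    """
    onsets = np.atleast_1d(np.asarray(onsets_ms, dtype=np.float64))
    t_rel_all = []
    freq_all = []
    for nid in range(raster.n_neurons):
        st = raster.spike_times(nid)
        if st.size < 2:
            continue
        freq = 1000.0 / np.diff(st)  # Hz, assigned at the later spike
        times = st[1:]
        for onset in onsets:
            sel = (times >= onset) & (times < onset + window_ms)
            if sel.any():
                t_rel_all.append(times[sel] - onset)
                freq_all.append(freq[sel])
    if not t_rel_all:
        return np.empty(0), np.empty(0)
    t_rel = np.concatenate(t_rel_all)
    freqs = np.concatenate(freq_all)
    edges = np.arange(0.0, window_ms + bin_ms, bin_ms)
    idx = np.digitize(t_rel, edges) - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    sums = np.bincount(idx, weights=freqs, minlength=centers.size)[: centers.size]
    counts = np.bincount(idx, minlength=centers.size)[: centers.size]
    mask = counts > 0
    return centers[mask], sums[mask] / counts[mask]


def dynamic_index(rate: np.ndarray, time_ms: np.ndarray, ramp_start_ms: float,
                  ramp_end_ms: float, probe_delay_ms: float = 500.0) -> float:
    """Peak rate during the ramp minus the rate ``probe_delay_ms`` after hold
    onset -- the classic measure of phasic sensitivity."""
    t_probe = ramp_end_ms + probe_delay_ms
    if ramp_start_ms < time_ms[0] or t_probe > time_ms[-1]:
        raise ValueError("ramp window or hold probe lies outside the trace")
    in_ramp = (time_ms >= ramp_start_ms) & (time_ms <= ramp_end_ms)
    peak = rate[in_ramp].max()
    probe = float(np.interp(t_probe, time_ms, rate))
    return float(peak - probe)


def _populations(trace: SpindleTrace, config: RunConfig, seed_key: int,
                 master_seed: int) -> dict[str, SpikeRaster]:
    ncfg = config.neuron_config()
    return {
        "Ia": run_population(trace.ia_rate, config.n_ia, "Ia",
                             derive_seed(master_seed, seed_key, 0), ncfg),
        "II": run_population(trace.ii_rate, config.n_ii, "II",
                             derive_seed(master_seed, seed_key, 1), ncfg),
    }


def _result(label: str, wf: Waveform, trace: SpindleTrace,
            rasters: dict[str, SpikeRaster]) -> ExperimentResult:
    return ExperimentResult(label=label, waveform=wf, time_ms=trace.time_ms,
                            ia_rate=trace.ia_rate, ii_rate=trace.ii_rate,
                            rasters=rasters)


def stretch_and_hold_experiment(config: RunConfig,
                                master_seed: int | None = None,
                                ) -> dict[str, ExperimentResult]:
    """Ramp-and-hold stretch with and without tonic fusimotor drive.

    Returns results keyed 'gamma_off' and 'gamma_on'. Stats per condition:
    Ia and II dynamic indices, mean rates, and the within-run correlation
    between each raster's binned counts and its rate trace.
    """
    seed = config.master_seed if master_seed is None else master_seed
    e = config.experiments
    wf = stimuli.ramp_hold(1.0, e.ramp_amplitude, e.ramp_ms, e.hold_ms, pre_ms=e.pre_ms)
    out = {}
    for k, (label, gamma) in enumerate([("gamma_off", 0.0), ("gamma_on", e.tonic_gamma_hz)]):
        trace = simulate(wf, gamma, gamma, config.spindle)
        rasters = _populations(trace, config, 20 + k, seed)
        res = _result(label, wf, trace, rasters)
        t0, t1 = e.pre_ms, e.pre_ms + e.ramp_ms
        res.stats["ia_dynamic_index_hz"] = dynamic_index(
            trace.ia_rate, trace.time_ms, t0, t1, e.probe_delay_ms)
        res.stats["ii_dynamic_index_hz"] = dynamic_index(
            trace.ii_rate, trace.time_ms, t0, t1, e.probe_delay_ms)
        res.stats["ia_mean_rate_hz"] = float(trace.ia_rate.mean())
        res.stats["ii_mean_rate_hz"] = float(trace.ii_rate.mean())
        for grp, rate in (("Ia", trace.ia_rate), ("II", trace.ii_rate)):
            r, p = raster_rate_correlation(rasters[grp], rate, e.bin_ms)
            res.stats[f"raster_rate_r_{grp.lower()}"] = r
        out[label] = res
    return out


def fusimotor_sinusoid_experiment(config: RunConfig,
                                  master_seed: int | None = None,
                                  ) -> dict[str, ExperimentResult]:
    """Selective gamma activation during a small sinusoidal stretch.

    A 3 Hz sinusoid runs for ``sin_cycles`` cycles; the selected fusimotor
    drive steps from 0 Hz to ``gamma_step_hz`` at the boundary between the
    3rd and 4th cycle. Results are keyed 'gamma_dyn' and 'gamma_stat'. Stats:
    per-cycle Ia modulation depth (max - min) and cycle-mean rate, plus
    pre-step vs post-step aggregates (the transition cycle is excluded from
    the post-step aggregate).
    """
    seed = config.master_seed if master_seed is None else master_seed
    e = config.experiments
    wf = stimuli.sinusoid(1.0, e.sin_p2p, e.sin_freq_hz, e.sin_cycles)
    period_ms = 1000.0 / e.sin_freq_hz
    t_step = 3.0 * period_ms
    gamma_trace = np.where(wf.times_ms >= t_step, e.gamma_step_hz, 0.0)
    out = {}
    for k, label in enumerate(["gamma_dyn", "gamma_stat"]):
        gd = gamma_trace if label == "gamma_dyn" else 0.0
        gs = gamma_trace if label == "gamma_stat" else 0.0
        trace = simulate(wf, gd, gs, config.spindle)
        rasters = _populations(trace, config, 30 + k, seed)
        res = _result(label, wf, trace, rasters)
        depth, mean = [], []
        for c in range(int(e.sin_cycles)):
            sel = (trace.time_ms >= c * period_ms) & (trace.time_ms < (c + 1) * period_ms)
            depth.append(float(trace.ia_rate[sel].max() - trace.ia_rate[sel].min()))
            mean.append(float(trace.ia_rate[sel].mean()))
        res.stats["ia_cycle_depth_hz"] = np.asarray(depth)
        res.stats["ia_cycle_mean_hz"] = np.asarray(mean)
        res.stats["pre_depth_hz"] = float(np.mean(depth[:3]))
        res.stats["post_depth_hz"] = float(np.mean(depth[4:]))
        res.stats["pre_mean_hz"] = float(np.mean(mean[:3]))
        res.stats["post_mean_hz"] = float(np.mean(mean[4:]))
        out[label] = res
    return out


def waveform_battery(config: RunConfig, master_seed: int | None = None,
                     ) -> dict[str, ExperimentResult]:
    """Linear stretch, tap, sinusoid, and release through the populations.

    The release result carries burst statistics: the mean Ia population rate
    in the 150 ms after the abrupt stop versus the mean during the release
    ramp itself.
    """
    seed = config.master_seed if master_seed is None else master_seed
    e = config.experiments
    waves = {
        "linear": stimuli.ramp_hold(1.0, e.ramp_amplitude, e.ramp_ms, e.hold_ms,
                                    pre_ms=e.pre_ms),
        "tap": stimuli.tap_pulse(1.0, e.tap_amplitude, e.tap_width_ms,
                                 pre_ms=e.pre_ms, post_ms=e.hold_ms),
        "sinusoid": stimuli.sinusoid(1.0, e.sin_p2p, e.sin_freq_hz, e.sin_cycles,
                                     pre_ms=e.pre_ms),
        "release": stimuli.release_ramp(e.release_baseline, e.release_drop,
                                        e.release_ramp_ms, pre_ms=e.pre_ms,
                                        post_ms=e.hold_ms),
    }
    out = {}
    for k, (label, wf) in enumerate(waves.items()):
        trace = simulate(wf, 0.0, 0.0, config.spindle)
        rasters = _populations(trace, config, 40 + k, seed)
        res = _result(label, wf, trace, rasters)
        if label == "release":
            # compare the post-stop window against the tail of the release,
            # when unloading has already silenced the Ia ending
            stop_ms = e.pre_ms + e.release_ramp_ms
            t = trace.time_ms
            during = (t >= stop_ms - 50.0) & (t < stop_ms)
            after = (t >= stop_ms) & (t < stop_ms + 50.0)
            res.stats["ia_rate_during_release_hz"] = float(trace.ia_rate[during].mean())
            res.stats["ia_rate_after_stop_hz"] = float(trace.ia_rate[after].max())
            spikes = rasters["Ia"].times_ms
            res.stats["ia_spikes_after_stop_per_s"] = float(
                np.sum((spikes >= stop_ms) & (spikes < stop_ms + 50.0))
                / 0.050 / rasters["Ia"].n_neurons)
            res.stats["ia_spikes_during_release_per_s"] = float(
                np.sum((spikes >= stop_ms - 50.0) & (spikes < stop_ms))
                / 0.050 / rasters["Ia"].n_neurons)
        out[label] = res
    return out


def triangular_frequency_experiment(config: RunConfig,
                                    master_seed: int | None = None) -> ExperimentResult:
    """Repeated triangular stretches; averaged instantaneous-frequency profile.

    Stats: the profile (bin centers and mean frequency relative to each
    rise onset), its maximum within the first 15% of the rise, and the
    mid-rise plateau mean (40-60% of the rise).
    """
    seed = config.master_seed if master_seed is None else master_seed
    e = config.experiments
    wf = stimuli.triangular_wave(1.0, e.tri_amplitude, e.tri_rise_ms, e.tri_fall_ms,
                                 e.tri_reps, e.tri_inter_ms)
    trace = simulate(wf, 0.0, 0.0, config.spindle)
    rasters = _populations(trace, config, 50, seed)
    res = _result("triangular", wf, trace, rasters)
    cycle_ms = e.tri_rise_ms + e.tri_fall_ms + e.tri_inter_ms
    onsets = e.tri_inter_ms + cycle_ms * np.arange(e.tri_reps)
    centers, profile = instantaneous_frequency(
        rasters["Ia"], onsets, window_ms=e.tri_rise_ms + e.tri_fall_ms,
        bin_ms=e.freq_bin_ms)
    res.stats["if_profile_time_ms"] = centers
    res.stats["if_profile_hz"] = profile
    early = centers <= 0.15 * e.tri_rise_ms
    mid = (centers >= 0.4 * e.tri_rise_ms) & (centers <= 0.6 * e.tri_rise_ms)
    res.stats["initial_burst_peak_hz"] = float(profile[early].max()) if early.any() else float("nan")
    res.stats["mid_rise_mean_hz"] = float(profile[mid].mean()) if mid.any() else float("nan")
    res.stats["onsets_ms"] = onsets
    return res


@dataclass
class WhiteNoiseResult:
    """Correlation between spike-based and rate-based white-noise responses."""

    r_ia: float
    r_ii: float
    p_ia: float
    p_ii: float
    n_bins: int
    result: ExperimentResult


def white_noise_correlation(config: RunConfig, master_seed: int | None = None,
                            ) -> WhiteNoiseResult:
    """Low-pass-filtered white-noise stretch through spindle and populations.

    The stimulus seed and both populations' noise seeds derive from the
    master seed, so the whole run is reproducible from (config, seed). The
    Pearson correlation compares per-bin population spike counts against the
    bin-averaged rate-model output.
    """
    seed = config.master_seed if master_seed is None else master_seed
    e = config.experiments
    wf = stimuli.filtered_white_noise(e.noise_duration_s, e.noise_cutoff_hz,
                                      e.noise_amplitude_l0,
                                      seed=derive_seed(seed, 60))
    trace = simulate(wf, 0.0, 0.0, config.spindle)
    rasters = _populations(trace, config, 61, seed)
    res = _result("white_noise", wf, trace, rasters)
    r_ia, p_ia = raster_rate_correlation(rasters["Ia"], trace.ia_rate, e.bin_ms)
    r_ii, p_ii = raster_rate_correlation(rasters["II"], trace.ii_rate, e.bin_ms)
    n_bins = int(trace.ia_rate.size // round(e.bin_ms))
    res.stats.update({"r_ia": r_ia, "r_ii": r_ii, "p_ia": p_ia, "p_ii": p_ii,
                      "bin_ms": e.bin_ms, "n_bins": n_bins})
    return WhiteNoiseResult(r_ia=r_ia, r_ii=r_ii, p_ia=p_ia, p_ii=p_ii,
                            n_bins=n_bins, result=res)
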