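"""Seeded simulator of electrodermal activity (EDA / GSR) recordings.

The generative model is the standard decomposition of skin conductance:

* a tonic level — constant baseline plus a slow sinusoidal drift with a
  random phase per subject;
* phasic skin-conductance responses (SCRs) — events arriving as a Poisson
  process, each a bi-exponential kernel
  ``k(t) = exp(-t/decay) - exp(-t/rise)`` normalised to unit peak, with
  exponentially distributed amplitudes;
* additive Gaussian sensor noise;
* an ADC stage — clipping to the conversion range and uniform quantisation
  to ``adc_bits`` — since quantisation of the sensor noise is the physical
  carrier of the entropy the digitiser later harvests from the LSBs.

Everything is driven by one integer seed; cohorts derive per-subject seeds
deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_io import GSRRecord

__all__ = ["SimConfig", "scr_kernel", "simulate_record", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic GSR cohort (units in field names)."""

    duration_s: float = 600.0
    native_fs_hz: float = 512.0
    baseline_us: float = 2.0
    drift_amplitude_us: float = 0.3
    drift_period_s: float = 60.0
    scr_rate_per_min: float = 3.0
    scr_rise_s: float = 0.75
    scr_decay_s: float = 3.0
    scr_amp_mean_us: float = 0.4
    noise_sd_us: float = 0.01
    adc_bits: int = 10
    adc_range_us: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.native_fs_hz <= 0:
            raise ValueError("duration_s and native_fs_hz must be positive")
        if self.scr_decay_s <= self.scr_rise_s:
            raise ValueError("scr_decay_s must exceed scr_rise_s")
        if not 6 <= self.adc_bits <= 24:
            raise ValueError("adc_bits must lie in [6, 24]")
        if self.drift_period_s <= 0 or self.scr_rise_s <= 0:
            raise ValueError("periods and time constants must be positive")
        if self.drift_amplitude_us < 0 or self.noise_sd_us < 0 or self.scr_rate_per_min < 0:
            raise ValueError("amplitudes and rates must be non-negative")
        if self.adc_range_us <= 0 or self.scr_amp_mean_us <= 0:
            raise ValueError("adc_range_us and scr_amp_mean_us must be positive")

    @property
    def quantisation_step_us(self) -> float:
        return self.adc_range_us / 2**self.adc_bits


def scr_kernel(t, rise_s: float, decay_s: float):
    """Bi-exponential SCR shape, normalised to peak 1.

    ``k(t) = exp(-t/decay) - exp(-t/rise)`` peaks at
    ``t* = ln(decay/rise) * rise * decay / (decay - rise)``; values for
    ``t < 0`` are 0.
    """
    if decay_s <= rise_s:
        raise ValueError("decay_s must exceed rise_s")
    t = np.asarray(t, dtype=np.float64)
    t_peak = np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    tc = np.clip(t, 0, None)
    out = (np.exp(-tc / decay_s) - np.exp(-tc / rise_s)) / peak
    return np.where(t >= 0, out, 0.0)


def _quantise(x: np.ndarray, config: SimConfig) -> np.ndarray:
    step = config.quantisation_step_us
    levels = 2**config.adc_bits - 1
    return np.clip(np.round(x / step), 0, levels) * step


def simulate_record(config: SimConfig) -> GSRRecord:
    """Simulate one subject's recording at the native rate."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.native_fs_hz))
    t = np.arange(n) / config.native_fs_hz

    # subjects get their own drift phase and a period drawn in [0.5, 1.5]x
    # the nominal one: tonic drift has no fixed clock, and a shared coherent
    # sinusoid would make cohort records mutually correlated
    phase = rng.uniform(0, 2 * np.pi)
    period = config.drift_period_s * rng.uniform(0.5, 1.5)
    x = config.baseline_us + config.drift_amplitude_us * np.sin(
        2 * np.pi * t / period + phase
    )

    n_scr = rng.poisson(config.scr_rate_per_min / 60.0 * config.duration_s)
    onsets = np.sort(rng.uniform(0, config.duration_s, size=n_scr))
    amps = rng.exponential(config.scr_amp_mean_us, size=n_scr)
    support = int(round(10 * config.scr_decay_s * config.native_fs_hz))
    kern_t = np.arange(support) / config.native_fs_hz
    kern = scr_kernel(kern_t, config.scr_rise_s, config.scr_decay_s)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * config.native_fs_hz))
        if i0 >= n:
            continue
        seg = min(support, n - i0)
        x[i0 : i0 + seg] += amp * kern[:seg]

    if config.noise_sd_us > 0:
        x = x + rng.normal(0, config.noise_sd_us, size=n)

    x = _quantise(x, config)
    return GSRRecord(
        subject_id=f"sim-{config.seed}",
        sampling_rate_hz=config.native_fs_hz,
        samples=x,
        meta={"seed": config.seed, "n_scr": int(n_scr), "scr_onsets_s": onsets.tolist()},
    )


def derive_subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed from (master seed, subject counter)."""
    ss = np.random.SeedSequence((int(master_seed), int(index)))
    return int(ss.generate_state(1)[0])


def simulate_cohort(n_subjects: int, config: SimConfig) -> list[GSRRecord]:
    """Simulate ``n_subjects`` statistically independent recordings."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    records = []
    for i in range(n_subjects):
        sub = replace(config, seed=derive_subject_seed(config.seed, i))
        rec = simulate_record(sub)
        rec.subject_id = f"S{i:03d}"
        records.append(rec)
    return records
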