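"""Synthetic multi-subject sEMG cohort generator.

Surface EMG during an isometric contraction is well approximated by a
band-limited stochastic carrier whose instantaneous amplitude follows the
muscle-activation envelope.  Each synthetic recording is therefore

    x_c(t) = gain_{s,c} * j_trial * env_{g,c}(warp_s(t)) * carrier_c(t)
             + noise_floor * w(t)

where ``env`` is a gesture- and channel-specific activation profile in
[0, 1] (piecewise linear over normalized trial time), ``carrier`` is fresh
zero-mean Gaussian noise band-pass filtered to the configured band and
rescaled to unit variance, and ``w`` is white sensor noise.  Inter-subject
variability — the dominant obstacle in myoelectric control — is emulated by
per-subject log-normal channel gains plus a smooth time-warp of the
envelopes; trial-to-trial variability comes from fresh carrier draws and a
small log-normal trial gain.

Every recording is generated from its own seed substream derived from
(seed, subject, gesture, trial), so cohorts are bit-reproducible and
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data import Recording

BASE6_NAMES = ("hand_close", "thumb", "index", "middle", "ring", "little")
COMBO_NAMES = ("thumb_index", "thumb_middle", "thumb_ring", "thumb_little")

# (channel-0 amplitude, channel-1 amplitude, burst rate in Hz) per base gesture.
# The two channels mimic the flexor/extensor electrode pair: gestures differ
# in their channel balance (equally spaced ratio angles) and in their burst
# (amplitude-modulation) rate.  Amplitudes stay below 0.5 so that combined
# gestures — sums of two base envelopes — remain within [0, 1] and keep a
# distinct overall magnitude; the clip is then only a guard.
_BASE6_PARAMS = {
    "thumb": (0.45, 0.03, 6.0),
    "index": (0.43, 0.14, 8.0),
    "hand_close": (0.36, 0.27, 4.0),
    "middle": (0.27, 0.36, 10.0),
    "ring": (0.14, 0.43, 12.0),
    "little": (0.02, 0.45, 14.0),
}


@dataclass
class SynthConfig:
    """Full description of a synthetic cohort; same config + seed gives a
    bit-identical cohort."""

    n_subjects: int
    n_gestures: int
    n_trials: int
    fs: float
    trial_duration_s: float
    carrier_band: tuple[float, float]
    envelopes: np.ndarray            # (n_gestures, n_channels, n_breakpoints)
    gesture_names: tuple[str, ...]
    subject_shift_scale: float = 0.15
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.envelopes = np.asarray(self.envelopes, dtype=np.float64)
        if min(self.n_subjects, self.n_gestures, self.n_trials) < 1:
            raise ValueError("subject/gesture/trial counts must be positive")
        lo, hi = self.carrier_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError(
                f"carrier band {self.carrier_band} must lie within (0, fs/2)")
        if self.envelopes.ndim != 3 or self.envelopes.shape[0] != self.n_gestures:
            raise ValueError("envelopes must have shape (n_gestures, C, n_breakpoints)")
        if self.envelopes.min() < 0 or self.envelopes.max() > 1:
            raise ValueError("envelopes must be bounded in [0, 1]")
        if self.subject_shift_scale < 0 or self.noise_floor < 0:
            raise ValueError("shift scale and noise floor must be nonnegative")
        if len(self.gesture_names) != self.n_gestures:
            raise ValueError("need one gesture name per gesture")

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[1]


def _subject_params(config: SynthConfig, s_idx: int):
    """Per-subject channel gains (log-normal) and envelope time-warp."""
    rng = np.random.default_rng([config.seed % (2**31), 7919, s_idx])
    scale = config.subject_shift_scale
    gains = np.exp(rng.normal(0.0, 0.5 * scale, size=config.n_channels))
    warp_amp = 0.08 * scale * rng.uniform(0.5, 1.0)
    warp_phase = rng.uniform(0.0, 2 * np.pi)
    return gains, warp_amp, warp_phase


def _eval_envelope(env_row: np.ndarray, t_norm: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of breakpoints over [0, 1]."""
    grid = np.linspace(0.0, 1.0, env_row.shape[-1])
    return np.interp(t_norm, grid, env_row)


def _bandpass_sos(config: SynthConfig):
    return sps.butter(4, config.carrier_band, btype="bandpass", fs=config.fs,
                      output="sos")


def generate_recording(config: SynthConfig, s_idx: int, g_idx: int,
                       t_idx: int) -> Recording:
    """Generate one (subject, gesture, trial) recording."""
    L = int(round(config.fs * config.trial_duration_s))
    gains, warp_amp, warp_phase = _subject_params(config, s_idx)
    rng = np.random.default_rng(
        [config.seed % (2**31), 104729, s_idx, g_idx, t_idx])
    trial_gain = np.exp(rng.normal(0.0, 0.05))
    t_norm = np.arange(L) / L
    warped = np.clip(t_norm + warp_amp * np.sin(2 * np.pi * t_norm + warp_phase),
                     0.0, 1.0)
    sos = _bandpass_sos(config)
    samples = np.empty((L, config.n_channels))
    for c in range(config.n_channels):
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(L))
        carrier /= max(carrier.std(), 1e-12)
        env = _eval_envelope(config.envelopes[g_idx, c], warped)
        samples[:, c] = (gains[c] * trial_gain * env * carrier
                         + config.noise_floor * rng.standard_normal(L))
    return Recording(subject_id=f"S{s_idx + 1}",
                     gesture_id=config.gesture_names[g_idx],
                     trial_id=t_idx + 1, samples=samples, fs=config.fs)


def generate_cohort(config: SynthConfig) -> list[Recording]:
    """Generate the full cohort: n_subjects x n_gestures x n_trials recordings."""
    return [
        generate_recording(config, s, g, t)
        for s in range(config.n_subjects)
        for g in range(config.n_gestures)
        for t in range(config.n_trials)
    ]


# ---------------------------------------------------------------------------
# Envelope libraries and reference presets
# ---------------------------------------------------------------------------


def _burst_profile(rate_hz: float, duration_s: float, n_break: int,
                   phase: float = 0.0) -> np.ndarray:
    """Trapezoidal activation with sinusoidal burst modulation, in [0, 1]."""
    t = np.linspace(0.0, 1.0, n_break)
    ramp = 0.1
    trap = np.clip(np.minimum(t / ramp, (1.0 - t) / ramp), 0.0, 1.0)
    bursts = 0.7 + 0.3 * np.sin(2 * np.pi * rate_hz * duration_s * t + phase)
    return trap * bursts


def _base6_envelopes(duration_s: float, n_break: int) -> np.ndarray:
    env = np.zeros((6, 2, n_break))
    for g, name in enumerate(BASE6_NAMES):
        a0, a1, rate = _BASE6_PARAMS[name]
        prof = _burst_profile(rate, duration_s, n_break)
        env[g, 0] = a0 * prof
        env[g, 1] = a1 * prof
    return env


def _easy10_envelopes(duration_s: float, n_break: int) -> np.ndarray:
    base = _base6_envelopes(duration_s, n_break)
    combos = []
    thumb = base[BASE6_NAMES.index("thumb")]
    for finger in ("index", "middle", "ring", "little"):
        combo = np.clip(thumb + base[BASE6_NAMES.index(finger)], 0.0, 1.0)
        combos.append(combo)
    return np.concatenate([base, np.stack(combos)], axis=0)


def _temporal2_envelopes(duration_s: float, n_break: int,
                         burst_hz: float = 8.0) -> np.ndarray:
    """Two classes with identical per-channel amplitude distributions that
    differ only in which channel's burst train leads the other.

    Both classes use the same raised-cosine burst train on both channels;
    in class A channel 1 lags channel 0 by a quarter burst period, in class
    B it leads by the same amount.  Pooled amplitude histograms therefore
    agree while the inter-channel envelope cross-correlation peaks at
    opposite lags — any method blind to temporal structure cannot separate
    the classes.
    """
    t = np.linspace(0.0, 1.0, n_break)
    period = 1.0 / (burst_hz * duration_s)  # in normalized time

    def train(shift):
        return (0.5 * (1.0 + np.cos(2 * np.pi * burst_hz * duration_s
                                    * (t - shift)))) ** 2

    env = np.zeros((2, 2, n_break))
    env[0, 0] = train(0.0)
    env[0, 1] = train(period / 4.0)   # channel 1 lags
    env[1, 0] = train(0.0)
    env[1, 1] = train(-period / 4.0)  # channel 1 leads
    return env


def reference_cohorts(reduced: bool = False) -> dict[str, SynthConfig]:
    """Named cohort presets.

    - ``easy6``: 8 subjects x 6 gestures x 6 trials, 5 s at 4 kHz, mild
      inter-subject shift — the shape of the 6-class recording set.
    - ``shifted6``: same but with strong subject shift, to exercise few-shot
      user adaptation.
    - ``easy10``: 10 gestures where the 4 extra classes are clipped sums of
      the thumb envelope and a finger envelope (combined flexions).
    - ``temporal2``: two classes separable only through temporal structure.

    With ``reduced=True`` each preset keeps its subject/gesture/trial counts
    but uses 1 kHz sampling and 1.5-s trials, a desk-scale variant for fast
    experiments.
    """
    fs, dur = (1000.0, 1.5) if reduced else (4000.0, 5.0)
    # 200 breakpoints per second resolves the fastest (8 Hz) burst trains
    n_break = int(200 * dur) + 1
    # the reduced preset mimics 4x-decimated recordings: the carrier band
    # scales with fs so the oversampling ratio (and hence the signal's
    # compressibility) matches the full-scale setting
    band = (20.0, 110.0) if reduced else (20.0, 450.0)
    presets = {
        "easy6": SynthConfig(
            n_subjects=8, n_gestures=6, n_trials=6, fs=fs, trial_duration_s=dur,
            carrier_band=band, envelopes=_base6_envelopes(dur, n_break),
            gesture_names=BASE6_NAMES, subject_shift_scale=0.05,
            noise_floor=0.01),
        "shifted6": SynthConfig(
            n_subjects=8, n_gestures=6, n_trials=6, fs=fs, trial_duration_s=dur,
            carrier_band=band, envelopes=_base6_envelopes(dur, n_break),
            gesture_names=BASE6_NAMES, subject_shift_scale=1.0,
            noise_floor=0.015),
        "easy10": SynthConfig(
            n_subjects=8, n_gestures=10, n_trials=6, fs=fs, trial_duration_s=dur,
            carrier_band=band, envelopes=_easy10_envelopes(dur, n_break),
            gesture_names=BASE6_NAMES + COMBO_NAMES, subject_shift_scale=0.05,
            noise_floor=0.01),
        "temporal2": SynthConfig(
            n_subjects=8, n_gestures=2, n_trials=6, fs=fs, trial_duration_s=dur,
            carrier_band=band, envelopes=_temporal2_envelopes(dur, n_break),
            gesture_names=("lead_lag_a", "lead_lag_b"),
            subject_shift_scale=0.05, noise_floor=0.02),
    }
    return presets
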