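"""Synthetic bilateral treadmill gait with known ground truth.

The generator emulates 100 Hz anterior-posterior heel-marker traces of
steady treadmill walking.  Each heel follows an asymmetric two-harmonic
cyclic waveform at the stride frequency; the left limb runs near anti-phase
to the right with a slowly drifting AR(1) relative-phase process (the
inter-limb coupling knob).  On top of the cycle the model adds per-leg
stride-amplitude modulation, a common-mode low-frequency postural-sway AP
component (shared by heels and sacrum), white measurement noise, and
stride-to-stride mediolateral foot-placement variability around a
configured step width.  Marker coordinates are body-relative
(stationary-mean traces); the belt speed is metadata that re-enters in
step-length computation.

Model rationale, briefly:

* the second harmonic carries a nonzero phase (waveform asymmetry, as in
  real heel excursions with distinct swing and stance segments) — a purely
  symmetric waveform is too self-predictable and yields unrealistically
  low cross sample entropy;
* relative-phase jitter is AR(1), not white: coordination loss accumulates
  over strides, producing finite diagonal-line structure in the
  cross-recurrence plot rather than uniform blurring;
* the sway component is common to both legs, so it enriches each leg's
  state-space geometry (false-nearest-neighbor dimension 4+, as observed
  in gait) while barely disturbing the inter-limb alignment.

Two reference extremes are also provided: an identical-frequency sinusoid
pair (perfect coordination — long diagonal recurrence lines) and an
independent white-noise pair (no coordination — negligible diagonal
structure).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

from .exceptions import ConfigurationError
from .trial import GaitEvents, MarkerTrial

#: Relative amplitude of the second harmonic in the AP heel waveform.
SECOND_HARMONIC = 0.3

#: Phase (rad) of the second harmonic relative to the fundamental.  A
#: nonzero value skews the waveform (fast swing, slow stance).
HARMONIC_PHASE = 0.8

#: Amplitude (fraction of sacrum-relative heel excursion) and frequency of
#: the small sacrum AP bob at step frequency.
_SACRUM_BOB_MM = 5.0

PRESETS = ("healthy", "exo_like")


def _gait_waveform(phase: np.ndarray) -> np.ndarray:
    """Unit-amplitude asymmetric two-harmonic cyclic waveform."""
    return np.sin(phase) + SECOND_HARMONIC * np.sin(2.0 * phase + HARMONIC_PHASE)


def _peak_phase() -> float:
    """Phase in (0, pi) at which the cyclic waveform peaks (per-cycle max)."""
    grid = np.linspace(0.0, 2.0 * math.pi, 4097)
    values = _gait_waveform(grid)
    k = int(np.argmax(values))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    deriv = lambda p: math.cos(p) + 2.0 * SECOND_HARMONIC * math.cos(2.0 * p + HARMONIC_PHASE)
    return float(brentq(deriv, lo, hi))


#: Phase (rad) of the per-cycle waveform maximum; the generator's
#: heel-strike convention.
PEAK_PHASE = _peak_phase()


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Parameters of the bilateral gait generator.

    Defaults are calibrated so the full analysis pipeline on the
    ``healthy`` preset reproduces unassisted-treadmill-walking scale
    outputs: step time ~0.58 s, determinism ~90%, mean diagonal line
    ~9 points at 10 Hz, cross sample entropy ~0.15.
    """

    duration_s: float = 300.0
    sample_rate: float = 100.0          # Hz
    stride_freq: float = 0.86           # Hz; step time = 1/(2*stride_freq)
    ap_amplitude: float = 350.0         # mm, AP heel excursion scale
    phase_offset: float = math.pi       # rad, left relative to right
    phase_jitter_sd: float = 0.05       # rad, stationary SD of AR(1) drift
    jitter_corr: float = 0.992          # AR(1) coefficient per sample
    meas_noise_sd: float = 3.0          # mm, additive white measurement noise
    amp_jitter_sd: float = 0.03         # fractional per-leg amplitude modulation
    amp_jitter_corr: float = 0.995      # AR(1) coefficient of amplitude modulation
    sway_mm: float = 12.0               # mm, common-mode postural sway amplitude
    sway_freq: float = 0.10             # Hz, sway frequency (incommensurate with stride)
    belt_speed: float = 1.10            # m/s
    step_width_mean: float = 0.16       # m
    step_width_sd: float = 0.01         # m, stride-to-stride placement SD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration_s", "sample_rate", "stride_freq", "ap_amplitude",
            "phase_offset", "phase_jitter_sd", "jitter_corr", "meas_noise_sd",
            "amp_jitter_sd", "amp_jitter_corr", "sway_mm", "sway_freq",
            "belt_speed", "step_width_mean", "step_width_sd",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if self.phase_jitter_sd < 0:
            raise ConfigurationError("phase_jitter_sd must be >= 0")
        if self.meas_noise_sd < 0:
            raise ConfigurationError("meas_noise_sd must be >= 0")
        for name in ("jitter_corr", "amp_jitter_corr"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if self.sample_rate <= 0 or self.stride_freq <= 0:
            raise ConfigurationError("sample_rate and stride_freq must be positive")
        if self.stride_freq >= self.sample_rate / 2:
            raise ConfigurationError("stride_freq must be below the Nyquist rate")
        n = self.duration_s * self.sample_rate
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ConfigurationError(
                "duration_s * sample_rate must be an integer sample count >= 2, "
                f"got {n}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))


def preset(name: str, **overrides) -> SyntheticGaitConfig:
    """Return a named generator configuration.

    ``healthy`` is calibrated to unassisted-walking scale; ``exo_like``
    differs only in the coupling knob (doubled phase-jitter SD), mimicking
    the shorter coordination durations and higher asynchrony seen under
    unilateral passive assistance.  Keyword overrides (e.g. ``seed=3``)
    replace fields.
    """
    if name == "healthy":
        cfg = SyntheticGaitConfig()
    elif name == "exo_like":
        cfg = SyntheticGaitConfig(phase_jitter_sd=0.10)
    else:
        raise ConfigurationError(f"unknown preset {name!r}; available presets: {PRESETS}")
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def _ar1(n: int, corr: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with the given per-sample coefficient and SD."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - corr * corr)
    eps = rng.standard_normal(n) * innov_sd
    eps[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -corr], eps)


def _phase_crossings(phase: np.ndarray, target: float) -> np.ndarray:
    """Sample indices nearest to each upward crossing of ``target`` mod 2pi."""
    k = np.floor((phase - target) / (2.0 * math.pi))
    inc = np.where(np.diff(k) > 0)[0] + 1  # first sample at/after each crossing
    out = []
    for i in inc:
        level = target + 2.0 * math.pi * k[i]
        dphi = phase[i] - phase[i - 1]
        frac = (level - phase[i - 1]) / dphi if dphi > 0 else 1.0
        out.append(i - 1 + int(round(min(max(frac, 0.0), 1.0))))
    return np.unique(np.asarray(out, dtype=int))


def _piecewise_per_cycle(n: int, boundaries: np.ndarray, sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-cycle constant offsets: a new draw after each boundary index."""
    values = rng.standard_normal(len(boundaries) + 1) * sd
    segment = np.searchsorted(boundaries, np.arange(n), side="right")
    return values[segment]


def generate_bilateral_gait(config: SyntheticGaitConfig) -> tuple[MarkerTrial, GaitEvents]:
    """Simulate one treadmill trial: heel_L, heel_R and sacrum markers.

    Returns the trial plus ground-truth heel strikes, defined as the
    per-cycle maximum of each leg's (noise-free) cyclic AP waveform, i.e.
    the samples where the leg's phase crosses :data:`PEAK_PHASE`.
    Identical config and seed give bit-identical output.
    """
    n = config.n_samples
    fs = config.sample_rate
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs

    phase_R = 2.0 * math.pi * config.stride_freq * t
    jitter = _ar1(n, config.jitter_corr, config.phase_jitter_sd, rng)
    phase_L = phase_R + config.phase_offset + jitter

    amp_L = 1.0 + _ar1(n, config.amp_jitter_corr, config.amp_jitter_sd, rng)
    amp_R = 1.0 + _ar1(n, config.amp_jitter_corr, config.amp_jitter_sd, rng)
    sway = config.sway_mm * np.sin(
        2.0 * math.pi * config.sway_freq * t + rng.uniform(0.0, 2.0 * math.pi)
    )

    strikes_L = _phase_crossings(phase_L, PEAK_PHASE)
    strikes_R = _phase_crossings(phase_R, PEAK_PHASE)

    w_half = config.step_width_mean * 1000.0 / 2.0
    w_sd = config.step_width_sd * 1000.0 / math.sqrt(2.0)
    ml_L = w_half + _piecewise_per_cycle(n, strikes_L, w_sd, rng)
    ml_R = -w_half + _piecewise_per_cycle(n, strikes_R, w_sd, rng)

    A = config.ap_amplitude

    def noise() -> np.ndarray:
        if config.meas_noise_sd == 0.0:
            return np.zeros(n)
        return rng.standard_normal(n) * config.meas_noise_sd

    heel_L = np.column_stack([
        A * amp_L * _gait_waveform(phase_L) + sway + noise(),
        ml_L + noise(),
        30.0 + 15.0 * np.sin(phase_L) + noise(),
    ])
    heel_R = np.column_stack([
        A * amp_R * _gait_waveform(phase_R) + sway + noise(),
        ml_R + noise(),
        30.0 + 15.0 * np.sin(phase_R) + noise(),
    ])
    # The sacrum shares the common sway and bobs slightly at step frequency
    # (twice the stride frequency); subtracting it in event detection
    # removes the common-mode component without displacing heel peaks.
    sacrum = np.column_stack([
        sway + _SACRUM_BOB_MM * np.sin(2.0 * phase_R + 0.3) + noise(),
        8.0 * np.sin(phase_R) + noise(),
        900.0 + 15.0 * np.sin(2.0 * phase_R) + noise(),
    ])

    trial = MarkerTrial(
        positions={"heel_L": heel_L, "heel_R": heel_R, "sacrum": sacrum},
        sample_rate=fs,
        belt_speed=config.belt_speed,
        trial_id=f"synthetic_seed{config.seed}",
    )
    events = GaitEvents(heel_strikes_L=strikes_L, heel_strikes_R=strikes_R,
                        source="ground_truth")
    return trial, events


def generate_sinusoid_pair(freq: float, phase_lag: float, n: int,
                           sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Two identical-amplitude sinusoids at the same frequency, one lagged.

    The perfectly coordinated reference extreme: its cross-recurrence plot
    consists of long unbroken diagonals.
    """
    if n < 2:
        raise ConfigurationError(f"need n >= 2 samples, got {n}")
    if freq >= sample_rate / 2.0:
        raise ConfigurationError(
            f"freq {freq} Hz aliases at sample rate {sample_rate} Hz (Nyquist "
            f"{sample_rate / 2.0} Hz)"
        )
    t = np.arange(n) / sample_rate
    a = np.sin(2.0 * math.pi * freq * t)
    b = np.sin(2.0 * math.pi * freq * t + phase_lag)
    return a, b


def generate_random_pair(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two independent standard-normal white-noise series (seeded).

    The uncoordinated reference extreme: negligible diagonal recurrence
    structure.
    """
    if n < 2:
        raise ConfigurationError(f"need n >= 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    return rng.standard_normal(n), rng.standard_normal(n)
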