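"""Synthetic-data generators.

Two families of synthetic data are produced here:

1. *Artificial EEG trials* for the latency-distortion study: Gaussian (or
   optionally pink) noise trials in which a binary outcome is made to depend
   on the narrow-band phase at a known time and frequency, after which a
   parameterised P1/N1 event-related potential (ERP) may be added.  The ERP
   is outcome-independent by construction: it is drawn from the same process
   for both trial groups and added *after* the labels are assigned.

2. A *synthetic observer* for the white-noise (WN) reconstruction paradigm:
   a known impulse-response function (IRF), white-noise luminance sequences
   with embedded mean-gray targets, a "recorded" signal equal to
   ``IRF * stimulus + noise``, and hit/miss outcomes drawn from the phase of
   the noiseless stimulus-driven signal at a known frequency and latency.
   Because targets and their surrounding suppression windows carry exactly
   the mean-gray luminance, they are invisible to any convolution with the
   stimulus: the reconstructed signal contains no target-evoked response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import Irf, TrialTensor
from .errors import InvalidConfigError, InvalidInputError
from .spectral import hilbert_band_phase, single_freq_wavelet

__all__ = [
    "NoiseConfig",
    "ErpParams",
    "OutcomeModel",
    "SimulatedDataset",
    "ObserverConfig",
    "ObserverDataset",
    "generate_noise",
    "generate_erp_trials",
    "assign_outcomes",
    "build_simulated_dataset",
    "default_irf",
    "generate_observer",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (< 2**31) for the sequential stages of one call."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


# ---------------------------------------------------------------------------
# Noise trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Configuration of the background-noise trials.

    Defaults reproduce the artificial-EEG generation stage: 500 trials of
    3 s (t in [-1.5, 1.5] s) sampled at 500 Hz, drawn from a Gaussian with
    mean 0 and standard deviation 10 arbitrary units.
    """

    n_trials: int = 500
    n_samples: int = 1500
    sampling_rate: float = 500.0
    mean: float = 0.0
    sd: float = 10.0
    color: str = "white"
    seed: int = 0
    t0_ms: float = -1500.0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise InvalidConfigError("n_trials must be >= 2")
        if self.n_samples <= 0:
            raise InvalidConfigError("n_samples must be positive")
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.sd < 0:
            raise InvalidConfigError("sd must be non-negative")
        if self.color not in ("white", "pink"):
            raise InvalidConfigError(f"unknown noise color {self.color!r}")


def generate_noise(cfg: NoiseConfig) -> TrialTensor:
    """Draw single-channel noise trials according to ``cfg``.

    White noise is i.i.d. Gaussian.  Pink noise is produced by spectral
    shaping of white noise with a ``1/sqrt(f)`` amplitude filter (DC bin
    zeroed), then rescaled so the pooled standard deviation equals ``cfg.sd``.
    """
    rng = np.random.default_rng(cfg.seed)
    white = rng.standard_normal((cfg.n_trials, cfg.n_samples))
    if cfg.color == "white":
        data = cfg.mean + cfg.sd * white
    else:
        spec = np.fft.rfft(white, axis=-1)
        f = np.fft.rfftfreq(cfg.n_samples, d=1.0 / cfg.sampling_rate)
        shaping = np.zeros_like(f)
        shaping[1:] = 1.0 / np.sqrt(f[1:])
        pink = np.fft.irfft(spec * shaping, n=cfg.n_samples, axis=-1)
        pooled_sd = pink.std()
        if pooled_sd > 0 and cfg.sd > 0:
            pink *= cfg.sd / pooled_sd
        else:
            pink[:] = 0.0
        data = cfg.mean + pink
    return TrialTensor(data, fs=cfg.sampling_rate, t0_ms=cfg.t0_ms)


# ---------------------------------------------------------------------------
# ERP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErpParams:
    """Per-trial P1/N1 component parameters (means and SDs of normal draws).

    Amplitudes are in the same arbitrary units as the noise (whose SD is 10);
    latencies and durations are in milliseconds.  Each component is a
    raised-cosine (Hann) bump of the drawn duration centred at the drawn
    peak latency, positive for P1 and negative for N1.
    """

    p1_amp_mean: float = 20.0
    p1_amp_sd: float = 5.0
    p1_latency_mean: float = 65.0
    p1_latency_sd: float = 10.0
    p1_duration_mean: float = 50.0
    p1_duration_sd: float = 10.0
    n1_amp_mean: float = 30.0
    n1_amp_sd: float = 10.0
    n1_latency_mean: float = 155.0
    n1_latency_sd: float = 25.0
    n1_duration_mean: float = 130.0
    n1_duration_sd: float = 25.0

    def __post_init__(self) -> None:
        if self.p1_duration_mean <= 0 or self.n1_duration_mean <= 0:
            raise InvalidConfigError("component duration means must be positive")
        for name in ("p1_amp_sd", "p1_latency_sd", "p1_duration_sd",
                     "n1_amp_sd", "n1_latency_sd", "n1_duration_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   n: int) -> np.ndarray:
    """Normal draws, redrawing non-positive values (preserves the stated mean
    essentially exactly at the parameter regimes used here)."""
    if mean <= 0:
        raise InvalidConfigError("mean of a positive-valued draw must be > 0")
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise InvalidConfigError(
        f"could not draw positive values from N({mean}, {sd}) in 100 rounds"
    )


def _hann_bump(times_ms: np.ndarray, amp: np.ndarray, latency: np.ndarray,
               duration: np.ndarray) -> np.ndarray:
    """Per-trial raised-cosine bumps: trials in rows, time in columns."""
    dt = times_ms[None, :] - latency[:, None]
    half = duration[:, None] / 2.0
    inside = np.abs(dt) < half
    bump = 0.5 * (1.0 + np.cos(np.pi * dt / half))
    return amp[:, None] * np.where(inside, bump, 0.0)


def generate_erp_trials(
    params: ErpParams,
    n_trials: int,
    fs: float,
    epoch_window_ms: tuple[float, float] = (-1500.0, 1500.0),
    seed: int = 0,
) -> TrialTensor:
    """Per-trial P1/N1 waveforms built from independent parameter draws."""
    w0, w1 = epoch_window_ms
    for lat in (params.p1_latency_mean, params.n1_latency_mean):
        if not w0 < lat < w1:
            raise InvalidConfigError(
                f"epoch window {epoch_window_ms} does not cover component "
                f"latency {lat} ms"
            )
    n_samples = int(round((w1 - w0) * fs / 1000.0))
    times = w0 + np.arange(n_samples) * 1000.0 / fs
    rng = np.random.default_rng(seed)
    # zero-amplitude components are allowed (flat trials); negative means are not
    p1_amp = (np.zeros(n_trials) if params.p1_amp_mean == 0 else
              _draw_positive(rng, params.p1_amp_mean, params.p1_amp_sd, n_trials))
    n1_amp = (np.zeros(n_trials) if params.n1_amp_mean == 0 else
              _draw_positive(rng, params.n1_amp_mean, params.n1_amp_sd, n_trials))
    p1_lat = _draw_positive(rng, params.p1_latency_mean, params.p1_latency_sd,
                            n_trials)
    p1_dur = _draw_positive(rng, params.p1_duration_mean, params.p1_duration_sd,
                            n_trials)
    n1_lat = _draw_positive(rng, params.n1_latency_mean, params.n1_latency_sd,
                            n_trials)
    n1_dur = _draw_positive(rng, params.n1_duration_mean, params.n1_duration_sd,
                            n_trials)
    data = _hann_bump(times, p1_amp, p1_lat, p1_dur) \
        - _hann_bump(times, n1_amp, n1_lat, n1_dur)
    return TrialTensor(data, fs=fs, t0_ms=w0)


# ---------------------------------------------------------------------------
# Outcome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeModel:
    """Cosine dependence of a binary outcome on oscillatory phase.

    With the default ``scaled`` convention the probability of outcome A is
    ``p_mean * (1 + mod * cos(angle))`` -- 70% at phase 0 for the default
    ``p_mean = 0.5``, ``mod = 0.4``.  The ``additive`` convention uses
    ``p_mean + mod * cos(angle)`` instead (90% at phase 0 with the same
    numbers) and is kept behind this flag for completeness.
    """

    p_mean: float = 0.5
    mod: float = 0.4
    phase_freq: float = 7.08
    phase_time_ms: float = 40.0
    convention: str = "scaled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mean <= 1.0:
            raise InvalidConfigError("p_mean must lie in [0, 1]")
        if self.convention not in ("scaled", "additive"):
            raise InvalidConfigError(f"unknown convention {self.convention!r}")
        lo, hi = self.prob_a(np.array([np.pi, 0.0]))
        if not (0.0 <= lo and hi <= 1.0):
            raise InvalidConfigError(
                f"outcome probabilities leave [0, 1]: min={lo:.3f}, max={hi:.3f}"
            )

    @property
    def peak_prob(self) -> float:
        """Probability of outcome A at phase 0."""
        return float(self.prob_a(np.array(0.0)))

    def prob_a(self, angle: np.ndarray) -> np.ndarray:
        angle = np.asarray(angle, dtype=float)
        if self.convention == "scaled":
            return self.p_mean * (1.0 + self.mod * np.cos(angle))
        return self.p_mean + self.mod * np.cos(angle)


def assign_outcomes(
    phase_at_t: np.ndarray, model: OutcomeModel, seed: int = 0
) -> np.ndarray:
    """Bernoulli outcome labels (True = A) from per-trial phases."""
    phases = np.asarray(phase_at_t, dtype=float)
    if not np.all(np.isfinite(phases)):
        raise InvalidInputError("phases must be finite")
    p = model.prob_a(phases)
    rng = np.random.default_rng(seed)
    return rng.random(phases.shape) < p


# ---------------------------------------------------------------------------
# Full artificial dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """One artificial dataset: signals, labels and the generating truth."""

    signals: TrialTensor
    labels: np.ndarray
    truth: OutcomeModel
    erp_added: bool
    phases_at_injection: np.ndarray


def build_simulated_dataset(
    mod_freq: float,
    noise_cfg: NoiseConfig | None = None,
    erp_params: ErpParams | None = None,
    outcome_model: OutcomeModel | None = None,
    with_erp: bool = True,
    seed: int = 0,
    halfwidth: float = 1.0,
) -> SimulatedDataset:
    """Generate noise trials, label them by injected phase, optionally add ERPs.

    The phase driving the outcome is the analytic phase of the
    ``mod_freq +/- halfwidth`` Hz band at ``outcome_model.phase_time_ms``
    (+40 ms by default).  Labels are assigned *before* the ERP is added, and
    the ERP process is identical for both label groups.
    """
    seeds = _child_seeds(seed, 3)
    if noise_cfg is None:
        noise_cfg = NoiseConfig(seed=seeds[0])
    if mod_freq - halfwidth <= 0:
        raise InvalidConfigError(
            f"modulation frequency {mod_freq} Hz too low for a "
            f"+/-{halfwidth} Hz band"
        )
    if mod_freq + halfwidth >= noise_cfg.sampling_rate / 2:
        raise InvalidConfigError(
            f"modulation frequency {mod_freq} Hz too close to Nyquist"
        )
    if outcome_model is None:
        outcome_model = OutcomeModel(phase_freq=mod_freq)
    else:
        outcome_model = replace(outcome_model, phase_freq=mod_freq)

    noise = generate_noise(noise_cfg)
    phases = hilbert_band_phase(noise, mod_freq, halfwidth)
    idx = noise.index_of(outcome_model.phase_time_ms)
    phases_at_t = phases[:, 0, idx]
    labels = assign_outcomes(phases_at_t, outcome_model, seed=seeds[1])

    if with_erp:
        if erp_params is None:
            erp_params = ErpParams()
        window = (noise.t0_ms, noise.t0_ms + noise.n_samples * 1000.0 / noise.fs)
        erp = generate_erp_trials(erp_params, noise.n_trials, noise.fs,
                                  epoch_window_ms=window, seed=seeds[2])
        noise.data += erp.data

    return SimulatedDataset(signals=noise, labels=labels, truth=outcome_model,
                            erp_added=with_erp, phases_at_injection=phases_at_t)


# ---------------------------------------------------------------------------
# Synthetic observer (white-noise paradigm)
# ---------------------------------------------------------------------------

def default_irf(fs: float = 160.0, n_channels: int = 4,
                duration_ms: float = 750.0) -> Irf:
    """A plausible visual impulse response: an early biphasic deflection
    followed by damped ~10 Hz ringing (a "perceptual echo").

    Channels share one source waveform scaled by a decreasing gain profile
    (channel 0 strongest).  A deliberate consequence: because every channel
    is a fixed linear filter of the same stimulus, their oscillatory phases
    differ only by fixed rotations, to which phase-opposition statistics
    are blind -- the simulated scalp topography of a phase effect is
    therefore flat by construction (amplitude topographies are not).
    Channel-selective phase topographies require channel-specific
    non-stimulus sources, which this deterministic observer does not model.
    """
    t = np.arange(int(round(duration_ms * fs / 1000.0))) / fs
    base = (
        1.2 * np.exp(-((t - 0.10) / 0.03) ** 2)
        - 0.8 * np.exp(-((t - 0.16) / 0.05) ** 2)
        + 0.6 * np.exp(-t / 0.25) * np.sin(2 * np.pi * 10.0 * t)
    )
    gains = np.linspace(1.0, 0.35, n_channels)
    return Irf(kernel=gains[:, None] * base[None, :], fs=fs)


@dataclass(frozen=True)
class ObserverConfig:
    """Configuration of the synthetic observer.

    Sequence geometry mirrors the experimental protocol (6.25 s sequences at
    160 Hz, i.e. 1000 frames; 2-4 targets per sequence; 14 frames before and
    11 after each target held at the mean gray).  The detection rule is part
    of the synthetic observer, not of the analysis: a target is detected with
    probability ``det_base * (1 + det_mod * cos(phi - det_phase0))`` where
    ``phi`` is the phase of the noiseless stimulus-driven signal on
    ``det_channel`` at ``det_freq`` and ``target time + det_latency_ms``.
    """

    irf_true: Irf | None = None
    seq_duration: float = 6.25
    frame_rate: float = 160.0
    n_sequences: int = 300
    targets_per_seq: tuple[int, int] = (2, 4)
    suppress_before: int = 14
    suppress_after: int = 11
    noise_sd: float = 2.0
    det_base: float = 0.5
    det_mod: float = 0.4
    det_freq: float = 6.0
    det_latency_ms: float = 75.0
    det_channel: int = 0
    # wavelet cycles defining the detection phase; None = the 2->8 cycle
    # log schedule at det_freq, matching the analysis side so the injected
    # effect is recoverable at its nominal time and frequency
    det_cycles: float | None = None
    det_phase0: float = 0.0
    mean_gray: float = 0.5
    catch_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.suppress_before < 0 or self.suppress_after < 0:
            raise InvalidConfigError("suppression windows must be non-negative")
        lo = self.det_base * (1.0 - abs(self.det_mod))
        hi = self.det_base * (1.0 + abs(self.det_mod))
        if not (0.0 <= lo and hi <= 1.0):
            raise InvalidConfigError(
                f"detection probabilities leave [0, 1]: [{lo:.3f}, {hi:.3f}]"
            )
        if self.targets_per_seq[0] < 1 or self.targets_per_seq[0] > self.targets_per_seq[1]:
            raise InvalidConfigError("targets_per_seq must be a valid count range")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.seq_duration * self.frame_rate))


@dataclass
class ObserverDataset:
    """Synthetic-observer output: stimuli, events, recorded signal, truth."""

    sequences: np.ndarray          # (n_sequences, n_frames) luminance in [0, 1]
    events: pd.DataFrame           # sequence_id, frame_index, outcome, catch
    recorded: TrialTensor          # (n_sequences, n_channels, n_frames)
    reconstructed_truth: TrialTensor  # noiseless IRF * stimulus (same shape)
    outcomes: np.ndarray           # bool per (non-catch) event, True = hit
    config: ObserverConfig
    irf_true: Irf


def _place_targets(rng: np.random.Generator, cfg: ObserverConfig,
                   margin: int, min_gap: int) -> np.ndarray:
    """Target frame indices for one sequence; rejection-sampled so that
    suppression windows never overlap and epochs fit the sequence."""
    lo_k, hi_k = cfg.targets_per_seq
    k = int(rng.integers(lo_k, hi_k + 1))
    lo, hi = margin, cfg.n_frames - margin
    if hi - lo < (k - 1) * min_gap:
        raise InvalidConfigError(
            "sequence too short for the requested target count and spacing"
        )
    for _ in range(1000):
        pos = np.sort(rng.integers(lo, hi, size=k))
        if k == 1 or np.diff(pos).min() >= min_gap:
            return pos
    raise InvalidConfigError("could not place targets without spacing violations")


def generate_observer(cfg: ObserverConfig) -> ObserverDataset:
    """Generate the full synthetic-observer dataset.

    Luminance frames are i.i.d. uniform on [0, 1] (flat spectrum, mean gray
    0.5); target frames and their suppression windows are set bit-exactly to
    the mean gray, so the stimulus-driven signal is invariant to target
    presence.  The recorded signal is the causal convolution of the true IRF
    with the mean-centred stimulus plus Gaussian sensor noise.
    """
    irf = cfg.irf_true if cfg.irf_true is not None else default_irf(cfg.frame_rate)
    if irf.fs != cfg.frame_rate:
        raise InvalidConfigError("irf_true sampling rate must equal frame_rate")
    seeds = _child_seeds(cfg.seed, 4)
    rng_seq = np.random.default_rng(seeds[0])
    rng_place = np.random.default_rng(seeds[1])
    rng_noise = np.random.default_rng(seeds[2])
    rng_det = np.random.default_rng(seeds[3])

    n_seq, n_frames = cfg.n_sequences, cfg.n_frames
    sequences = rng_seq.uniform(0.0, 1.0, size=(n_seq, n_frames))

    margin = max(int(round(0.8 * cfg.frame_rate)) + 2,
                 cfg.suppress_before + 1, cfg.suppress_after + 1)
    min_gap = max(int(round(1.0 * cfg.frame_rate)),
                  cfg.suppress_before + cfg.suppress_after + 2)
    rows = []
    for s in range(n_seq):
        for pos in _place_targets(rng_place, cfg, margin, min_gap):
            is_catch = bool(rng_place.random() < cfg.catch_fraction)
            sequences[s, pos - cfg.suppress_before: pos + cfg.suppress_after + 1] = \
                cfg.mean_gray
            sequences[s, pos] = cfg.mean_gray
            rows.append((s, int(pos), is_catch))

    centred = sequences - cfg.mean_gray
    from scipy.signal import fftconvolve  # local import keeps module load light
    driven = fftconvolve(centred[:, None, :], irf.kernel[None, :, :],
                         axes=-1)[:, :, :n_frames]
    recorded = driven + rng_noise.normal(0.0, cfg.noise_sd, size=driven.shape)

    if cfg.det_cycles is None:
        alpha = np.log(8.0 / 2.0) / np.log(100.0 / 3.0)
        det_cycles = float(2.0 * (cfg.det_freq / 3.0) ** alpha)
    else:
        det_cycles = cfg.det_cycles
    coeffs, _ = single_freq_wavelet(driven[:, cfg.det_channel, :],
                                    cfg.frame_rate, cfg.det_freq, det_cycles)
    lat_frames = int(round(cfg.det_latency_ms * cfg.frame_rate / 1000.0))

    outcome_col, outcome_bool = [], []
    for (s, pos, is_catch) in rows:
        phi = float(np.angle(coeffs[s, pos + lat_frames]))
        p_hit = cfg.det_base * (1.0 + cfg.det_mod * np.cos(phi - cfg.det_phase0))
        hit = bool(rng_det.random() < p_hit) and not is_catch
        outcome_bool.append(hit)
        outcome_col.append("hit" if hit else "miss")

    events = pd.DataFrame(
        {
            "sequence_id": [r[0] for r in rows],
            "frame_index": [r[1] for r in rows],
            "outcome": outcome_col,
            "catch": [r[2] for r in rows],
        }
    )
    return ObserverDataset(
        sequences=sequences,
        events=events,
        recorded=TrialTensor(recorded, fs=cfg.frame_rate),
        reconstructed_truth=TrialTensor(driven, fs=cfg.frame_rate),
        outcomes=np.asarray(outcome_bool, dtype=bool),
        config=cfg,
        irf_true=irf,
    )
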