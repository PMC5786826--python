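"""Synthetic multi-subject EEG cohorts with the structure the analysis assumes.

Each subject's scalp data is

    gain(age, sex) * (mixing @ shared_sources)
        + spatially correlated 1/f background noise
        + eog_leak * (leak vectors @ EOG traces)
        + sparse gross spikes,

where the shared sources are band-limited (0.5–15 Hz) stimulus-locked time
courses common to every subject — the aperiodic evoked structure a film
drives — and the gain falls linearly with age and is offset upward for
males, planting the age and sex effects the group statistics should
recover.  The Rest condition sets the gain to zero (no stimulus, no shared
signal); Flash adds a trial-structured 25 Hz sinusoidal drive on the
occipital channels for the SSVEP stage.

Everything is reproducible from the config seed, and the ground truth
(per-subject gains, the mixing matrix, spike positions) is returned so
tests can score recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_core import Recording, ValidationError
from .ssvep import TrialSet

OCCIPITAL = ["O1", "O2", "O3", "O4", "O5"]


@dataclass
class SimConfig:
    """Cohort-generator parameters; defaults define the simulated study.

    Gains are ``baseline + age_slope * (age - age_min) + male_offset * male``
    clipped at zero; at the defaults a 6-yr-old has gain 1 and a 44-yr-old
    0.24, giving the planted negative age–ISC relation.
    """

    n_subjects: int = 16
    n_channels: int = 24  # scalp channels (occipital ones included)
    n_eog: int = 2
    duration_s: float = 120.0
    fs: float = 125.0
    n_shared_sources: int = 3
    source_band: tuple[float, float] = (0.5, 15.0)
    signal_scale: float = 0.3  # shared-signal amplitude relative to noise RMS
    gain_baseline: float = 1.0
    gain_age_slope: float = -0.02  # per year, <= 0
    gain_male_offset: float = 0.15  # >= 0
    age_range: tuple[float, float] = (6.0, 44.0)
    noise_exponent: float = 1.0  # 1/f^exponent background
    noise_scale: float = 1.0
    spatial_corr: float = 0.5  # 0 = independent channels, 1 = heavy smoothing
    eog_leak: float = 0.2
    artifact_rate: float = 2.0  # spikes per minute per subject
    artifact_amplitude: float = 20.0  # in units of channel RMS
    flicker_hz: float = 25.0
    flicker_amplitude: float = 1.0
    trial_seconds: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")
        if self.gain_age_slope > 0:
            raise ValidationError("gain_age_slope must be <= 0")
        if self.gain_male_offset < 0:
            raise ValidationError("gain_male_offset must be >= 0")
        if self.fs <= 2 * self.source_band[1]:
            raise ValidationError("fs must exceed twice the highest source frequency")
        if self.n_channels < len(OCCIPITAL):
            raise ValidationError(f"need at least {len(OCCIPITAL)} scalp channels")

    @property
    def channel_names(self) -> list[str]:
        n_generic = self.n_channels - len(OCCIPITAL)
        return [f"E{i + 1}" for i in range(n_generic)] + list(OCCIPITAL)

    @property
    def eog_names(self) -> list[str]:
        return [f"EOG{i + 1}" for i in range(self.n_eog)]


def _demographics(cfg: SimConfig, rng: np.random.Generator):
    lo, hi = cfg.age_range
    ages = np.sort(rng.uniform(lo, hi, size=cfg.n_subjects))
    sexes = np.array(["male", "female"] * cfg.n_subjects)[: cfg.n_subjects]
    rng.shuffle(sexes)
    return ages, sexes


def gain_of(cfg: SimConfig, age: float, sex: str) -> float:
    g = (
        cfg.gain_baseline
        + cfg.gain_age_slope * (age - cfg.age_range[0])
        + (cfg.gain_male_offset if sex == "male" else 0.0)
    )
    return max(g, 0.0)


def _band_limited_sources(cfg: SimConfig, n_samples: int, rng: np.random.Generator):
    src = rng.standard_normal((cfg.n_shared_sources, n_samples))
    sos = signal.butter(4, cfg.source_band, btype="bandpass", fs=cfg.fs, output="sos")
    src = signal.sosfiltfilt(sos, src, axis=1)
    src /= src.std(axis=1, keepdims=True)
    return src


def _pink_noise(shape: tuple[int, int], exponent: float, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise."""
    n_ch, n_samp = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    noise = np.fft.irfft(spec * shaping, n=n_samp, axis=1)
    noise /= noise.std(axis=1, keepdims=True)
    return noise


def _spatial_mixer(n_channels: int, corr: float, rng: np.random.Generator):
    """Mixing matrix that smears independent noise across nearby channels."""
    idx = np.arange(n_channels)
    dist = np.abs(idx[:, None] - idx[None, :])
    smooth = np.exp(-dist / max(corr * 5.0, 1e-6)) if corr > 0 else np.eye(n_channels)
    smooth /= np.linalg.norm(smooth, axis=1, keepdims=True)
    return smooth


def simulate_cohort(
    cfg: SimConfig, condition: str = "Wimpy"
) -> tuple[list[Recording], dict]:
    """Generate one cohort of recordings for ``condition`` plus ground truth."""
    # demographics and the mixing (head geometry) are shared across
    # conditions for one cfg.seed; sources and noise get a per-condition
    # substream so different stimuli drive different shared time courses
    rng = np.random.default_rng(cfg.seed)
    cond_key = zlib.crc32(condition.encode()) & 0x7FFFFFFF
    rng_cond = np.random.default_rng([cfg.seed, cond_key])
    n_samples = int(round(cfg.duration_s * cfg.fs))
    ages, sexes = _demographics(cfg, rng)

    mixing = rng.standard_normal((cfg.n_channels, cfg.n_shared_sources))
    mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
    # strongest component carries more of the shared power than the rest
    mixing[:, 0] *= 1.5
    mixing *= cfg.signal_scale
    sources = _band_limited_sources(cfg, n_samples, rng_cond)
    mixer = _spatial_mixer(cfg.n_channels, cfg.spatial_corr, rng)

    is_rest = condition == "Rest"
    names = cfg.channel_names + cfg.eog_names
    roles = ["EEG"] * cfg.n_channels + ["EOG"] * cfg.n_eog
    occ_rows = [cfg.channel_names.index(n) for n in OCCIPITAL]

    recordings: list[Recording] = []
    truth = {
        "mixing": mixing,
        "sources": sources,
        "gains": [],
        "spikes": [],
        "ages": ages,
        "sexes": list(sexes),
    }
    t_axis = np.arange(n_samples) / cfg.fs
    for k in range(cfg.n_subjects):
        gain = 0.0 if is_rest else gain_of(cfg, ages[k], sexes[k])
        noise = cfg.noise_scale * (
            mixer @ _pink_noise((cfg.n_channels, n_samples), cfg.noise_exponent,
                                cfg.fs, rng_cond)
        )
        eog = _pink_noise((cfg.n_eog, n_samples), 2.0, cfg.fs, rng_cond) * 3.0
        leak = np.abs(rng.standard_normal((cfg.n_channels, cfg.n_eog)))
        scalp = gain * (mixing @ sources) + noise + cfg.eog_leak * (leak @ eog)
        if condition == "Flash":
            drive = _trial_gated_flicker(cfg, t_axis)
            scalp[occ_rows] += gain * cfg.flicker_amplitude * drive
        spikes = _inject_spikes(cfg, scalp, rng_cond)
        data = np.vstack([scalp, eog])
        recordings.append(
            Recording(
                subject_id=f"S{k + 1:03d}",
                condition=condition,
                fs=cfg.fs,
                data=data,
                channel_names=names,
                channel_roles=roles,
                age=float(ages[k]),
                sex=str(sexes[k]),
            )
        )
        truth["gains"].append(gain)
        truth["spikes"].append(spikes)
    return recordings, truth


def _trial_gated_flicker(cfg: SimConfig, t_axis: np.ndarray) -> np.ndarray:
    """25 Hz sinusoid gated into 2.4 s-on / 1 s-off trials."""
    period = cfg.trial_seconds + 1.0
    gate = (t_axis % period) < cfg.trial_seconds
    return np.sin(2 * np.pi * cfg.flicker_hz * t_axis) * gate


def _inject_spikes(cfg: SimConfig, scalp: np.ndarray, rng: np.random.Generator):
    """Sparse single-sample gross outliers; returns their (channel, sample)."""
    n_spikes = rng.poisson(cfg.artifact_rate * scalp.shape[1] / cfg.fs / 60.0)
    positions = []
    if n_spikes:
        rows = rng.integers(0, scalp.shape[0], n_spikes)
        cols = rng.integers(0, scalp.shape[1], n_spikes)
        amp = cfg.artifact_amplitude * scalp.std()
        scalp[rows, cols] += rng.choice([-1.0, 1.0], n_spikes) * amp
        positions = list(zip(rows.tolist(), cols.tolist()))
    return positions


def simulate_flicker_trials(
    cfg: SimConfig, n_trials: int = 128, f0: float | None = None
) -> tuple[dict[str, TrialSet], dict]:
    """Per-subject SSVEP trial sets with age/sex-dependent flicker amplitude.

    Occipital channels carry ``a_k * sin(2 pi f0 t)`` with per-subject
    amplitude ``a_k`` drawn from the gain model, plus background noise on all
    channels.  The 12 contrast/background condition labels cycle over
    trials, mirroring a factorial flicker protocol.
    """
    f0 = cfg.flicker_hz if f0 is None else f0
    if not 0 < f0 < cfg.fs / 2:
        raise ValidationError("flicker frequency must lie below Nyquist")
    rng = np.random.default_rng(cfg.seed + 1)
    ages, sexes = _demographics(cfg, rng)
    n_samp = int(round(cfg.trial_seconds * cfg.fs))
    t_axis = np.arange(n_samp) / cfg.fs
    occ_rows = [cfg.channel_names.index(n) for n in OCCIPITAL]
    labels = [
        f"c{contrast}_{background}"
        for contrast in (0, 30, 60, 100)
        for background in ("par", "orth", "none")
    ]
    trial_labels = [labels[i % len(labels)] for i in range(n_trials)]

    out: dict[str, TrialSet] = {}
    amplitudes = {}
    for k in range(cfg.n_subjects):
        amp = cfg.flicker_amplitude * gain_of(cfg, ages[k], sexes[k])
        trials = cfg.noise_scale * rng.standard_normal(
            (n_trials, cfg.n_channels, n_samp)
        )
        trials[:, occ_rows, :] += amp * np.sin(2 * np.pi * f0 * t_axis)
        sid = f"S{k + 1:03d}"
        out[sid] = TrialSet(
            trials=trials,
            fs=cfg.fs,
            channel_names=cfg.channel_names,
            condition_labels=trial_labels,
        )
        amplitudes[sid] = amp
    return out, {"amplitudes": amplitudes, "ages": ages, "sexes": list(sexes)}
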