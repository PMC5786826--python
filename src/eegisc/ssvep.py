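"""Steady-state visual evoked potential (SSVEP) band power from flicker trials.

A 25 Hz flickering grating entrains an oscillatory response in visual
cortex.  Per subject, the trial tensor is cleaned (3-SD amplitude/power
rejection), the first 200 ms of each trial is dropped to skip the onset
transient, and narrow-band power at the flicker frequency is read off the
per-trial DFT, averaged over all retained trials (collapsing stimulus
contrast conditions) and over the configured occipital electrodes.

Normalization: per-bin power is ``2 |X_f|^2 / T^2`` for the one-sided
spectrum (rectangular window, no padding), so a pure sinusoid of amplitude
``a`` whose frequency falls on a bin center carries power ``a^2 / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_core import ValidationError

DEFAULT_F0 = 25.0
DEFAULT_BW = 0.5
DEFAULT_Z = 3.0
TRIAL_SECONDS = 2.4
ONSET_MS = 200.0


@dataclass
class TrialSet:
    """Trials-by-channels-by-samples tensor for one subject's flicker run."""

    trials: np.ndarray  # (n_trials, D, T)
    fs: float
    channel_names: list[str]
    condition_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValidationError("trials must be n_trials x channels x samples")
        if self.trials.shape[0] < 1:
            raise ValidationError("need at least one trial")
        if len(self.channel_names) != self.trials.shape[1]:
            raise ValidationError("channel_names length does not match trials")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def reject_trials(ts: TrialSet, z: float = DEFAULT_Z) -> TrialSet:
    """Drop trials whose power or peak amplitude is an outlier on any electrode.

    Per electrode, per-trial mean-square power and max |amplitude| are
    compared against mean + z*SD across trials (statistics per electrode);
    exceeding either on any electrode removes the trial.  With zero SD the
    threshold is infinite, so identical trials are never rejected.
    """
    if not z > 0:
        raise ValidationError("z must be positive")
    if np.isinf(z):
        return ts
    power = np.mean(ts.trials**2, axis=2)  # (n_trials, D)
    peak = np.abs(ts.trials).max(axis=2)
    keep = np.ones(ts.n_trials, dtype=bool)
    for stat in (power, peak):
        mean = stat.mean(axis=0)
        sd = stat.std(axis=0, ddof=0)
        thresh = np.where(sd > 0, mean + z * sd, np.inf)
        keep &= ~(stat > thresh).any(axis=1)
    if not keep.any():
        raise ValidationError("trial rejection removed every trial")
    labels = (
        [ts.condition_labels[i] for i in np.flatnonzero(keep)]
        if ts.condition_labels is not None
        else None
    )
    return replace(ts, trials=ts.trials[keep], condition_labels=labels)


def trim_onset(ts: TrialSet, ms: float = ONSET_MS) -> TrialSet:
    """Drop the first ``ms`` milliseconds of every trial (onset transient)."""
    n_drop = int(round(ms * ts.fs / 1000.0))
    if n_drop >= ts.trials.shape[2]:
        raise ValidationError(
            f"onset trim of {ms} ms >= trial duration "
            f"({ts.trials.shape[2] / ts.fs * 1000:.0f} ms)"
        )
    if n_drop == 0:
        return ts
    return replace(ts, trials=ts.trials[:, :, n_drop:])


def band_power(
    ts: TrialSet,
    f0: float = DEFAULT_F0,
    bw: float = DEFAULT_BW,
    electrodes: list[str] | None = None,
) -> float:
    """Mean narrow-band power at ``f0`` over trials and named electrodes.

    Per trial and electrode the rectangular-window DFT is taken without
    padding; one-sided per-bin power is summed over bins whose centers fall
    in ``[f0 - bw/2, f0 + bw/2]``, then averaged across all retained trials
    and across ``electrodes`` (default: all channels).
    """
    if f0 + bw / 2 >= ts.fs / 2:
        raise ValidationError("band extends beyond the Nyquist frequency")
    if electrodes is None:
        idx = list(range(len(ts.channel_names)))
    else:
        missing = [e for e in electrodes if e not in ts.channel_names]
        if missing:
            raise ValidationError(f"electrodes not in trial set: {missing}")
        idx = [ts.channel_names.index(e) for e in electrodes]
    x = ts.trials[:, idx, :]
    t = x.shape[2]
    spec = np.fft.rfft(x, axis=2)
    freqs = np.fft.rfftfreq(t, d=1.0 / ts.fs)
    scale = np.full(freqs.shape, 2.0 / t**2)
    scale[0] = 1.0 / t**2  # DC carries no conjugate twin
    if t % 2 == 0:
        scale[-1] = 1.0 / t**2  # nor does Nyquist
    power = np.abs(spec) ** 2 * scale
    in_band = (freqs >= f0 - bw / 2) & (freqs <= f0 + bw / 2)
    if not in_band.any():
        raise ValidationError("no DFT bin falls inside the requested band")
    return float(power[:, :, in_band].sum(axis=2).mean())


def subject_band_power(
    ts: TrialSet,
    f0: float = DEFAULT_F0,
    bw: float = DEFAULT_BW,
    electrodes: list[str] | None = None,
    z: float = DEFAULT_Z,
    onset_ms: float = ONSET_MS,
) -> tuple[float, int]:
    """Full per-subject SSVEP chain: reject, trim, band power.

    Returns the power and the number of trials retained.
    """
    kept = reject_trials(ts, z=z)
    trimmed = trim_onset(kept, ms=onset_ms)
    return band_power(trimmed, f0=f0, bw=bw, electrodes=electrodes), kept.n_trials
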