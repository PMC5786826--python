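"""Signal conditioning: downsampling, filtering, and EOG regression.

The chain mirrors a standard evoked-response pipeline: polyphase
downsampling to 125 Hz, a 1 Hz Butterworth high-pass, a 59–61 Hz Butterworth
band-stop for line noise (both order 4, applied forward–backward so the
phase of fast evoked structure is untouched), then least-squares regression
of the EOG channels out of every scalp channel.

Filters are zero-phase: intersubject correlation compares fine temporal
structure across subjects, and causal group delay would deflate it.  "Order
4" refers to the prototype filter before the forward–backward pass doubles
the magnitude response.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .io_core import Recording, ValidationError

FS_TARGET = 125.0
HP_HZ = 1.0
NOTCH = (59.0, 61.0)
BUTTER_ORDER = 4


def resample_recording(rec: Recording, fs_target: float = FS_TARGET) -> Recording:
    """Polyphase anti-aliased downsampling to ``fs_target`` Hz."""
    if fs_target > rec.fs:
        raise ValidationError(
            f"fs_target {fs_target} exceeds recording rate {rec.fs}"
        )
    if fs_target == rec.fs:
        return rec
    frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    out = rec.with_data(data)
    out.fs = fs_target
    return out


def filter_recording(
    rec: Recording,
    hp_hz: float = HP_HZ,
    notch: tuple[float, float] = NOTCH,
    order: int = BUTTER_ORDER,
) -> Recording:
    """High-pass then band-stop notch, Butterworth order ``order``, zero-phase."""
    nyq = rec.fs / 2.0
    lo, hi = notch
    if not (0 < hp_hz < lo < hi < nyq):
        raise ValidationError(
            f"band edges must satisfy 0 < {hp_hz} < {lo} < {hi} < {nyq}"
        )
    sos_hp = signal.butter(order, hp_hz, btype="highpass", fs=rec.fs, output="sos")
    sos_notch = signal.butter(order, [lo, hi], btype="bandstop", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos_hp, rec.data, axis=1)
    data = signal.sosfiltfilt(sos_notch, data, axis=1)
    return rec.with_data(data)


def regress_out_eog(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Remove the least-squares EOG contribution from every scalp channel.

    Both matrices are mean-removed in time; the returned residual
    ``eeg_c - B @ eog_c`` (with ``B`` the joint least-squares solution) is
    zero-mean and orthogonal in time to every EOG channel.
    """
    eeg = np.asarray(eeg, dtype=float)
    eog = np.asarray(eog, dtype=float)
    if eeg.shape[1] != eog.shape[1]:
        raise ValidationError("EEG and EOG must share the time axis length")
    if eog.shape[0] < 1:
        raise ValidationError("need at least one EOG channel")
    eeg_c = eeg - eeg.mean(axis=1, keepdims=True)
    eog_c = eog - eog.mean(axis=1, keepdims=True)
    if not np.any(np.abs(eog_c) > 0):
        warnings.warn("EOG channels carry no variance; returning EEG unchanged")
        return eeg
    # B solves min ||eeg_c - B eog_c||_F^2  <=>  eog_c^T B^T ~ eeg_c^T
    b_t, *_ = np.linalg.lstsq(eog_c.T, eeg_c.T, rcond=None)
    return eeg_c - b_t.T @ eog_c


def apply_eog_regression(rec: Recording) -> Recording:
    """Regress the recording's EOG channels out of its EEG/BAD scalp rows."""
    eog_idx = rec.channels_with_role("EOG")
    if not eog_idx:
        warnings.warn(f"{rec.subject_id}: no EOG channels; skipping regression")
        return rec
    scalp_idx = [
        i for i, role in enumerate(rec.channel_roles) if role in ("EEG", "BAD")
    ]
    data = rec.data.copy()
    data[scalp_idx] = regress_out_eog(rec.data[scalp_idx], rec.data[eog_idx])
    # visual-inspection-flagged channels must stay exactly zero
    data[[i for i in scalp_idx if rec.channel_roles[i] == "BAD"]] = 0.0
    return rec.with_data(data)


def preprocess_recording(
    rec: Recording,
    fs_target: float = FS_TARGET,
    hp_hz: float = HP_HZ,
    notch: tuple[float, float] = NOTCH,
    order: int = BUTTER_ORDER,
) -> Recording:
    """Full conditioning chain: downsample, high-pass, notch, EOG regression."""
    out = resample_recording(rec, fs_target)
    out = filter_recording(out, hp_hz=hp_hz, notch=notch, order=order)
    return apply_eog_regression(out)
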