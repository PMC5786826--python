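"""Domain containers and recording I/O.

A :class:`Recording` is one subject in one condition: a channels-by-samples
voltage matrix plus the channel roles (EEG / EOG / DISCARD / BAD), the
sampling rate, and the subject's age and sex.  A :class:`CohortMatrix` stacks
the cleaned EEG channels of every subject in a condition into an
``N x D x T`` tensor — the object the intersubject-correlation stage
consumes.

Recordings are read from EDF/EDF+ (via :mod:`mne`) or from a simple HDF5
layout (dataset ``/data`` channels x samples float64, string array
``/channels``, attrs ``fs``/``subject_id``/``condition``).  Subject metadata
and channel roles arrive as CSV tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

ROLES = ("EEG", "EOG", "DISCARD", "BAD")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class CohortError(ValueError):
    """Raised when a cohort cannot be assembled (e.g. fewer than 2 subjects)."""


@dataclass
class Recording:
    """One subject's channels-by-samples EEG matrix with metadata.

    ``data`` is in microvolts, one row per channel; ``channel_roles`` labels
    each row EEG, EOG, DISCARD or BAD.  BAD channels carry zero-valued
    samples so they contribute nothing to covariance computations.
    """

    subject_id: str
    condition: str
    fs: float
    data: np.ndarray
    channel_names: list[str]
    channel_roles: list[str]
    age: float = float("nan")
    sex: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        n = self.data.shape[0]
        if len(self.channel_names) != n or len(self.channel_roles) != n:
            raise ValidationError(
                f"channel metadata length ({len(self.channel_names)} names, "
                f"{len(self.channel_roles)} roles) does not match {n} data rows"
            )
        bad_roles = set(self.channel_roles) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown channel roles: {sorted(bad_roles)}")
        if "EEG" not in self.channel_roles:
            raise ValidationError("recording has no EEG channels")
        if not np.isfinite(self.data).all():
            raise ValidationError("data contains NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channels_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == role]

    def eeg_data(self) -> np.ndarray:
        """EEG-role rows only, in recording order."""
        return self.data[self.channels_with_role("EEG")]

    def eog_data(self) -> np.ndarray:
        return self.data[self.channels_with_role("EOG")]

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with ``data`` replaced (same channels)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class CohortMatrix:
    """Time-aligned stack of cleaned EEG matrices for one condition.

    ``tensor`` has shape (N subjects, D channels, T samples); all subjects
    share the channel order given by ``channel_names``.
    """

    condition: str
    subjects: list[str]
    tensor: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValidationError("cohort tensor must be N x D x T")
        if self.tensor.shape[0] < 2:
            raise CohortError("a cohort needs at least 2 subjects")
        if len(self.subjects) != self.tensor.shape[0]:
            raise ValidationError("subject list length does not match tensor")

    @property
    def n_subjects(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[2]


def load_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a ``subject_id,age,sex`` CSV and validate it."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    return validate_subject_table(table)


def validate_subject_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "age", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"subject table missing columns: {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject_id in subject table")
    if (table["age"] <= 0).any():
        raise ValidationError("ages must be positive")
    bad_sex = set(table["sex"]) - {"male", "female"}
    if bad_sex:
        raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
    return table


def load_role_table(path: str | Path) -> pd.DataFrame:
    """Read a ``channel,role`` CSV."""
    roles = pd.read_csv(path, dtype=str)
    if not {"channel", "role"} <= set(roles.columns):
        raise ValidationError("role table must have columns channel,role")
    bad = set(roles["role"]) - set(ROLES)
    if bad:
        raise ValidationError(f"unknown roles in role table: {sorted(bad)}")
    return roles


# --------------------------------------------------------------------------
# recording read / write
# --------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    roles: pd.DataFrame,
    meta: pd.DataFrame,
) -> Recording:
    """Read an EDF or HDF5 recording, apply channel roles and metadata.

    DISCARD channels are dropped; BAD and EOG channels are retained with
    their role so downstream stages can zero or regress them.  ``roles`` is a
    channel→role table covering every stored channel; ``meta`` maps
    subject_id to age and sex.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        data, names, fs, subject_id, condition = _read_hdf5(path)
    else:
        data, names, fs, subject_id, condition = _read_edf(path)

    role_map = dict(zip(roles["channel"], roles["role"]))
    missing = [n for n in names if n not in role_map]
    if missing or len(role_map) != len(names):
        raise ValidationError(
            f"role table does not match recording channels "
            f"({len(role_map)} roles for {len(names)} channels; "
            f"unlabelled: {missing[:5]})"
        )
    chan_roles = [role_map[n] for n in names]
    keep = [i for i, r in enumerate(chan_roles) if r != "DISCARD"]
    data = data[keep]
    names = [names[i] for i in keep]
    chan_roles = [chan_roles[i] for i in keep]

    meta = validate_subject_table(meta)
    row = meta.loc[meta["subject_id"] == subject_id]
    if row.empty:
        raise ValidationError(f"subject {subject_id!r} missing from metadata table")
    return Recording(
        subject_id=subject_id,
        condition=condition,
        fs=fs,
        data=data,
        channel_names=names,
        channel_roles=chan_roles,
        age=float(row["age"].iloc[0]),
        sex=str(row["sex"].iloc[0]),
    )


def _read_hdf5(path: Path):
    try:
        with h5py.File(path, "r") as f:
            data = np.asarray(f["/data"], dtype=float)
            names = [
                n.decode() if isinstance(n, bytes) else str(n) for n in f["/channels"][()]
            ]
            fs = float(f["/data"].attrs["fs"])
            subject_id = str(f["/data"].attrs["subject_id"])
            condition = str(f["/data"].attrs["condition"])
    except OSError as exc:
        raise OSError(f"cannot read HDF5 recording {path}: {exc}") from exc
    return data, names, fs, subject_id, condition


def _read_edf(path: Path):
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for broken files
        raise OSError(f"cannot read EDF recording {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts; recordings are in uV
    names = list(raw.ch_names)
    fs = float(raw.info["sfreq"])
    # subject/condition are encoded in the filename: <subject>__<condition>.edf
    stem = path.stem
    if "__" in stem:
        subject_id, condition = stem.split("__", 1)
    else:
        subject_id, condition = stem, ""
    return data, names, fs, subject_id, condition


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as HDF5 (lossless) or EDF (16-bit quantized)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        _write_hdf5(rec, path)
    elif path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    else:
        raise ValidationError(f"unsupported recording extension: {path.suffix}")
    return path


def _write_hdf5(rec: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("/data", data=rec.data.astype(np.float64))
        d.attrs["fs"] = rec.fs
        d.attrs["subject_id"] = rec.subject_id
        d.attrs["condition"] = rec.condition
        f.create_dataset(
            "/channels", data=np.array(rec.channel_names, dtype=h5py.string_dtype())
        )


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal plain-EDF writer: one data record, 16-bit samples.

    Physical scaling per channel covers the observed range, so round-trips
    are exact only up to 16-bit quantization.
    """
    data = rec.data
    n_ch, n_samp = data.shape
    duration = n_samp / rec.fs

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            pad("0", 8),
            pad(rec.subject_id, 80),
            pad(rec.condition, 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad("1", 8),  # one data record
            pad(f"{duration:.6f}"[:8], 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(n, 16) for n in rec.channel_names],
        [pad("", 80)] * n_ch,  # transducer
        [pad("uV", 8)] * n_ch,
        [pad(f"{v:.6g}"[:8], 8) for v in phys_min],
        [pad(f"{v:.6g}"[:8], 8) for v in phys_max],
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,  # prefiltering
        [pad(str(n_samp), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(col) for col in fields)

    # re-read physical min/max exactly as an EDF reader will parse them, so
    # the digital scaling matches the header to the last printed digit
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(digital.tobytes())  # record layout: channel-major within record


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def build_cohort(
    recordings: Sequence[Recording],
    condition: str,
    channel_order: Sequence[str] | None = None,
) -> CohortMatrix:
    """Stack EEG channels of all recordings of ``condition`` into a tensor.

    Channel rows follow ``channel_order`` (default: the first recording's
    EEG channel list); assembly fails rather than silently reorders when a
    recording's EEG channel set differs.  Recordings are truncated to the
    minimum common length, and BAD channels are zeroed.
    """
    recs = [r for r in recordings if r.condition == condition]
    if len(recs) < 2:
        raise CohortError(
            f"need at least 2 recordings of condition {condition!r}, got {len(recs)}"
        )
    fss = {r.fs for r in recs}
    if len(fss) > 1:
        raise ValidationError(f"sampling rates differ across recordings: {sorted(fss)}")

    # BAD channels are scalp channels flagged by visual inspection: they keep
    # their row in the tensor but carry zeros, contributing nothing to any
    # covariance downstream
    def scalp_names(r: Recording) -> list[str]:
        return [
            n for n, role in zip(r.channel_names, r.channel_roles)
            if role in ("EEG", "BAD")
        ]

    order = list(channel_order) if channel_order is not None else scalp_names(recs[0])
    t_min = min(r.n_samples for r in recs)
    if any(r.n_samples != t_min for r in recs):
        warnings.warn(
            f"recordings of {condition!r} have unequal lengths; "
            f"truncating all to {t_min} samples",
            stacklevel=2,
        )

    slabs = []
    for r in recs:
        names = scalp_names(r)
        if set(names) != set(order):
            raise CohortError(
                f"subject {r.subject_id}: scalp channels {sorted(names)[:5]}... do "
                f"not match the configured channel order"
            )
        name_to_row = {n: i for i, n in enumerate(r.channel_names)}
        slab = r.data[[name_to_row[n] for n in order], :t_min].copy()
        role_of = dict(zip(r.channel_names, r.channel_roles))
        bad_rows = [i for i, n in enumerate(order) if role_of[n] == "BAD"]
        slab[bad_rows] = 0.0
        slabs.append(slab)

    tensor = np.stack(slabs, axis=0)
    return CohortMatrix(
        condition=condition,
        subjects=[r.subject_id for r in recs],
        tensor=tensor,
        fs=recs[0].fs,
        channel_names=order,
    )
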