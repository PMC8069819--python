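"""Core EEG containers, validation, and portable on-disk I/O.

The central container is :class:`EpochsSet`: a ``(R, C, T)`` tensor of
epoched multichannel EEG (R trials, C channels, T samples) together with
the sampling rate, binary trial labels, channel names and an optional 2D
scalp montage.  Data are stored and round-tripped through a single HDF5
file per subject so that whole-subject workflows stay portable.

Units are deliberately not interpreted (no µV/V conversion): every
measure downstream is either scale-free or scale-aware only through a
data-driven kernel bandwidth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "Montage",
    "EpochsSet",
    "circular_montage",
    "save_epochs",
    "load_epochs",
    "validate_epochs",
]


@dataclass(frozen=True)
class Montage:
    """2D scalp layout: channel name -> (x, y) inside the unit head circle."""

    positions: dict[str, tuple[float, float]]
    name: str = "custom"

    def as_array(self, channel_names: list[str]) -> np.ndarray:
        """Positions as a (C, 2) array in the order of ``channel_names``."""
        try:
            return np.asarray(
                [self.positions[ch] for ch in channel_names], dtype=float
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"montage has no position for channel {exc}") from exc


def circular_montage(channel_names: list[str], radius: float = 0.8) -> Montage:
    """Evenly spaced synthetic montage on a circle (for simulated cohorts)."""
    n = len(channel_names)
    angles = 2.0 * np.pi * np.arange(n) / max(n, 1)
    pos = {
        ch: (radius * float(np.cos(a)), radius * float(np.sin(a)))
        for ch, a in zip(channel_names, angles)
    }
    return Montage(positions=pos, name="circular-synthetic")


@dataclass
class EpochsSet:
    """Labeled epoched EEG: ``data`` is (R trials, C channels, T samples)."""

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: list[str]
    montage: Montage | None = None
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = [str(c) for c in self.channel_names]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def validate_epochs(e: EpochsSet) -> list[str]:
    """Check every :class:`EpochsSet` invariant; return the violations.

    Reporting, not raising: an empty list means the set is well formed.
    """
    report: list[str] = []
    if e.data.ndim != 3:
        report.append(f"data must be 3D (R, C, T); got ndim={e.data.ndim}")
        return report
    r, c, t = e.data.shape
    if not np.isfinite(e.data).all():
        report.append("data contains non-finite samples")
    if not e.fs > 0:
        report.append(f"fs must be positive; got {e.fs}")
    if len(e.channel_names) != c:
        report.append(
            f"channel_names length {len(e.channel_names)} != C={c}"
        )
    if len(set(e.channel_names)) != len(e.channel_names):
        report.append("channel names are not unique")
    if e.labels.shape != (r,):
        report.append(f"labels shape {e.labels.shape} != (R,)=({r},)")
    else:
        classes = set(np.unique(e.labels).tolist())
        if not classes <= {0, 1}:
            report.append(f"labels outside {{0,1}}: {sorted(classes)}")
        elif r < 2 or len(classes) < 2:
            report.append("supervised use needs R >= 2 with both classes present")
    if t < 2:
        report.append(f"trials must hold at least 2 samples; got T={t}")
    if e.montage is not None:
        missing = [ch for ch in e.channel_names if ch not in e.montage.positions]
        if missing:
            report.append(f"montage lacks positions for channels {missing}")
        else:
            xy = e.montage.as_array(e.channel_names)
            if (np.hypot(xy[:, 0], xy[:, 1]) > 1.0 + 1e-9).any():
                report.append("montage positions fall outside the unit head circle")
    return report


def _require_valid(e: EpochsSet) -> EpochsSet:
    problems = validate_epochs(e)
    if problems:
        raise ValueError("invalid EpochsSet: " + "; ".join(problems))
    return e


def save_epochs(e: EpochsSet, path) -> None:
    """Write one subject to a single HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=e.data.astype(np.float64))
        f.create_dataset("fs", data=float(e.fs))
        f.create_dataset("labels", data=e.labels.astype(np.int8))
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset(
            "channel_names", data=np.array(e.channel_names, dtype=object), dtype=str_dt
        )
        f.attrs["subject_id"] = e.subject_id
        if e.montage is not None:
            f.create_dataset("montage", data=e.montage.as_array(e.channel_names))
            f.attrs["montage_name"] = e.montage.name


def load_epochs(path, format_hint: str = "hdf5") -> EpochsSet:
    """Load and validate a subject container written by :func:`save_epochs`."""
    if format_hint not in ("hdf5", "h5"):
        raise ValueError(f"unsupported format hint: {format_hint!r}")
    with h5py.File(path, "r") as f:
        for name in ("data", "fs", "labels", "channel_names"):
            if name not in f:
                raise KeyError(f"{name} absent from container {path}")
        data = np.asarray(f["data"], dtype=np.float64)
        fs = float(np.asarray(f["fs"]))
        labels = np.asarray(f["labels"], dtype=np.int64)
        names = [
            s.decode("utf-8") if isinstance(s, bytes) else str(s)
            for s in f["channel_names"][()]
        ]
        montage = None
        if "montage" in f:
            xy = np.asarray(f["montage"], dtype=float)
            if xy.shape != (len(names), 2):
                raise ValueError(
                    f"montage shape {xy.shape} mismatches C={len(names)} channels"
                )
            montage = Montage(
                positions={ch: (float(x), float(y)) for ch, (x, y) in zip(names, xy)},
                name=str(f.attrs.get("montage_name", "custom")),
            )
        subject_id = str(f.attrs.get("subject_id", "S00"))
    e = EpochsSet(
        data=data,
        fs=fs,
        labels=labels,
        channel_names=names,
        montage=montage,
        subject_id=subject_id,
    )
    return _require_valid(e)
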