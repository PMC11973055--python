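"""Multichannel EEG recording container and plain-text I/O.

An :class:`EEGRecording` holds one subject's signal as a ``channels x samples``
float array together with its sampling rate, group label and 10-20-system
channel names.  Recordings are written to and read from a simple CSV dialect:
one row per channel, first column the channel name, preceded by comment lines
``# fs=<Hz>`` and ``# group=<label>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Electrode labels of the 19-channel international 10-20 montage.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


@dataclass
class EEGRecording:
    """One subject's multichannel EEG signal.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    group : str
        Group label (e.g. ``"control"``, ``"mci"``, ``"ad"``).
    fs : float
        Sampling rate in Hz; must be positive.
    data : ndarray, shape (n_channels, n_samples)
        Signal in arbitrary amplitude units; all samples finite.
    channel_names : list of str
        One 10-20 label per row of ``data``.
    """

    subject_id: str
    group: str
    fs: float
    data: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        self.channel_names = list(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of this recording with new samples (and optionally a new rate)."""
        return replace(self, data=np.asarray(data, dtype=float),
                       fs=self.fs if fs is None else fs)


def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as channel-per-row CSV with ``# fs=`` / ``# group=`` header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write(f"# group={rec.group}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        for name, row in zip(rec.channel_names, rec.data):
            fh.write(name + "," + ",".join(f"{v:.10g}" for v in row) + "\n")


def read_recording_csv(path: str | Path) -> EEGRecording:
    """Read a recording written by :func:`write_recording_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    names: list[str] = []
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            name, _, rest = line.partition(",")
            names.append(name)
            rows.append(np.array(rest.split(","), dtype=float))
    if "fs" not in meta:
        raise ValueError(f"{path}: missing '# fs=' header line")
    return EEGRecording(
        subject_id=meta.get("subject_id", path.stem),
        group=meta.get("group", "unknown"),
        fs=float(meta["fs"]),
        data=np.vstack(rows),
        channel_names=names,
    )


def read_plain_matrix_csv(path: str | Path, fs: float, *, subject_id: str | None = None,
                          group: str = "unknown",
                          channel_names: list[str] | None = None) -> EEGRecording:
    """Read a headerless channels x samples CSV with the sampling rate supplied."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return EEGRecording(
        subject_id=subject_id or path.stem,
        group=group,
        fs=fs,
        data=data,
        channel_names=channel_names or [f"ch{i}" for i in range(data.shape[0])],
    )
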