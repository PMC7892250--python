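"""Multichannel recording containers and on-disk formats.

A :class:`Recording` is a channels x samples matrix at a fixed sampling rate,
with per-channel labels and roles. MEG channels hold field values in tesla;
auxiliary channels (audio, stim trigger, bipolar EOG/ECG) hold volts.

On disk a recording is an HDF5 file with datasets ``/data``, ``/rate``,
``/labels``, ``/roles`` and optionally ``/sensor_positions`` (aligned with the
MEG channels). Event lists are 2-column text files ``time_s<TAB>kind``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

#: Channel roles understood by the pipeline.
ROLES = ("meg", "audio", "stim", "eog_v", "eog_h", "ecg")

EVENT_KINDS = ("stimulus", "blink", "cardiac")


@dataclass
class Recording:
    """Multichannel time series at a fixed sampling rate.

    Parameters
    ----------
    data : (channels, samples) ndarray
        MEG channels in tesla, auxiliary channels in volts.
    rate : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel labels.
    roles : list of str
        Per-channel role, each in :data:`ROLES`.
    sensor_positions : (n_meg, 3) ndarray, optional
        Positions of the MEG channels, aligned with their order in ``data``.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    roles: list[str]
    sensor_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0] or len(self.roles) != self.data.shape[0]:
            raise ValueError("labels/roles must align with data rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        for r in self.roles:
            if r not in ROLES:
                raise ValueError(f"unknown channel role {r!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def meg_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.roles) == "meg")

    @property
    def meg_labels(self) -> list[str]:
        return [self.labels[i] for i in self.meg_indices]

    def channel(self, role_or_label: str) -> np.ndarray:
        """Return the single channel with the given role or label."""
        if role_or_label in self.labels:
            return self.data[self.labels.index(role_or_label)]
        idx = [i for i, r in enumerate(self.roles) if r == role_or_label]
        if len(idx) != 1:
            raise KeyError(f"no unique channel with role/label {role_or_label!r}")
        return self.data[idx[0]]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            data=data,
            rate=self.rate,
            labels=list(self.labels),
            roles=list(self.roles),
            sensor_positions=None if self.sensor_positions is None else self.sensor_positions.copy(),
        )


@dataclass
class EventList:
    """Tagged event times, in seconds from recording start."""

    times: np.ndarray
    kinds: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.kinds) != self.times.size:
            raise ValueError("times and kinds must align")
        for k in self.kinds:
            if k not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {k!r}")
        for kind in set(self.kinds):
            t = self.of_kind(kind)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{kind} event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def of_kind(self, kind: str) -> np.ndarray:
        mask = np.asarray(self.kinds) == kind
        return self.times[mask]

    @staticmethod
    def concat(*lists: "EventList") -> "EventList":
        times = np.concatenate([ev.times for ev in lists]) if lists else np.empty(0)
        kinds = [k for ev in lists for k in ev.kinds]
        return EventList(times=times, kinds=kinds)


@dataclass
class TrialSegment:
    """Fixed-length post-stimulus window of the MEG channels.

    ``data`` has shape (channels, L) with ``L = round(duration * rate)``.
    """

    data: np.ndarray
    onset: float
    duration: float
    rate: float
    trial_id: str = ""
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        L = int(round(self.duration * self.rate))
        if self.data.shape[1] != L:
            raise ValueError(f"segment length {self.data.shape[1]} != round(duration*rate) = {L}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def save_recording(path, rec: Recording) -> None:
    """Write a recording to the HDF5 container format."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("rate", data=float(rec.rate))
        f.create_dataset("labels", data=np.array(rec.labels, dtype="S"))
        f.create_dataset("roles", data=np.array(rec.roles, dtype="S"))
        if rec.sensor_positions is not None:
            f.create_dataset("sensor_positions", data=rec.sensor_positions)


def load_recording(path) -> Recording:
    """Read a recording from the HDF5 container format."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        rate = float(f["rate"][()])
        labels = [s.decode() for s in f["labels"][()]]
        roles = [s.decode() for s in f["roles"][()]]
        pos = f["sensor_positions"][()] if "sensor_positions" in f else None
    return Recording(data=data, rate=rate, labels=labels, roles=roles, sensor_positions=pos)


def write_events(path, events: EventList) -> None:
    """Write events as a 2-column text file (time_s, kind)."""
    order = np.argsort(events.times, kind="stable")
    with open(path, "w") as fh:
        for i in order:
            fh.write(f"{events.times[i]:.9g}\t{events.kinds[i]}\n")


def read_events(path) -> EventList:
    """Read events from the 2-column text format."""
    times: list[float] = []
    kinds: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t, k = line.split("\t")
            times.append(float(t))
            kinds.append(k)
    return EventList(times=np.array(times), kinds=kinds)
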