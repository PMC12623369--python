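"""Multichannel LFP recordings and their on-disk container.

A :class:`Recording` is the substrate of every analysis stage: a channels x
samples array in microvolts, a sampling rate, ordered channel labels and a
channel -> region map (two cortical regions, ``S1`` and ``RFA``, in the
intended application).

The native on-disk format is a raw little-endian float32 binary (one file per
session, channel-major) with a JSON sidecar holding ``rate``, ``channels``,
``region_of``, ``units`` and ``start_time``.  EDF files can be *read* through
:mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["Recording", "read_recording", "write_recording"]


@dataclass
class Recording:
    """Continuous multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling frequency in Hz; must be positive.
    channels : sequence of str
        Ordered channel labels, one per row of ``data``.
    region_of : mapping str -> str
        Region label for every channel (e.g. ``"S1"`` or ``"RFA"``).
    start_time : float
        Session-relative start of the first sample, in seconds.
    """

    data: np.ndarray
    rate: float
    channels: Sequence[str]
    region_of: Mapping[str, str]
    start_time: float = 0.0
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channels = list(self.channels)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} "
                "channel labels"
            )
        missing = [c for c in self.channels if c not in self.region_of]
        if missing:
            raise ValueError(f"channels without region assignment: {missing}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    @property
    def regions(self) -> list[str]:
        """Distinct regions in channel order."""
        seen: dict[str, None] = {}
        for c in self.channels:
            seen.setdefault(self.region_of[c], None)
        return list(seen)

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def get(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        return self.data[self.channel_index(label)]

    def channels_in(self, region: str) -> list[str]:
        return [c for c in self.channels if self.region_of[c] == region]

    def copy_with(self, **kwargs) -> "Recording":
        base = dict(
            data=self.data,
            rate=self.rate,
            channels=self.channels,
            region_of=dict(self.region_of),
            start_time=self.start_time,
            units=self.units,
        )
        base.update(kwargs)
        return Recording(**base)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` as ``<path>.bin`` + ``<path>.json`` sidecar.

    The binary part is channel-major float32, little-endian.  Returns the
    sidecar path.
    """
    path = Path(path)
    if path.suffix in {".bin", ".json"}:
        path = path.with_suffix("")
    bin_path = path.with_suffix(".bin")
    sidecar = path.with_suffix(".json")
    rec.data.astype("<f4").tofile(bin_path)
    meta = {
        "rate": rec.rate,
        "channels": list(rec.channels),
        "region_of": {c: rec.region_of[c] for c in rec.channels},
        "units": rec.units,
        "start_time": rec.start_time,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "order": "channel-major",
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def _read_container(path: Path) -> Recording:
    if path.suffix in {".bin", ".json"}:
        path = path.with_suffix("")
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = np.fromfile(path.with_suffix(".bin"), dtype=meta.get("dtype", "<f4"))
    n_ch = len(meta["channels"])
    data = raw.reshape(n_ch, -1)
    return Recording(
        data=data.astype(float),
        rate=float(meta["rate"]),
        channels=meta["channels"],
        region_of=meta["region_of"],
        start_time=float(meta.get("start_time", 0.0)),
        units=meta.get("units", "uV"),
    )


def _read_edf(path: Path, region_of: Mapping[str, str] | None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    channels = list(raw.ch_names)
    if region_of is None:
        # fall back to a prefix convention like "S1_ch01"
        region_of = {c: c.split("_")[0] for c in channels}
    return Recording(data=data, rate=float(raw.info["sfreq"]), channels=channels,
                     region_of=region_of)


def read_recording(path: str | Path,
                   region_of: Mapping[str, str] | None = None) -> Recording:
    """Read a session from the binary container (or an EDF file).

    ``path`` may point at the ``.bin``/``.json`` pair (either extension, or
    the common stem) or at a ``.edf`` file.  For EDF input a ``region_of``
    map may be supplied; otherwise channel-name prefixes are used.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, region_of)
    return _read_container(path)
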