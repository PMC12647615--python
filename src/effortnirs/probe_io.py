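"""Probe geometry, raw-recording data model, and SNIRF-style container I/O.

The montage mirrors a prefrontal continuous-wave band: eight LED emitters and
two photodiode detectors forming six long (~3.5 cm) measurement channels — two
per subregion (left lateral, lower medial, right lateral) — plus two
short-separation channels that sample scalp/systemic physiology only.

Recordings are stored as SNIRF (HDF5) files with one data block per
wavelength. Only the subset of the SNIRF layout needed for this analysis is
read and written; files written here round-trip bit-identically on intensity,
events, and montage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .constants import WAVELENGTHS_NM

SUBREGIONS = ("left_lateral", "lower_medial", "right_lateral")
SHORT = "short"

EVENT_COLUMNS = ["onset", "duration", "condition", "context", "n_sentences", "block", "practice"]
CONDITIONS = ("standard", "dnn")


class SnirfParseError(ValueError):
    """Structured parse failure naming the offending HDF5 group or field."""

    def __init__(self, group: str, message: str):
        self.group = group
        super().__init__(f"{group}: {message}")


@dataclass(frozen=True)
class Channel:
    index: int
    name: str
    emitter: int  # 0-based emitter id
    detector: int  # 0-based detector id
    is_short: bool
    subregion: str


@dataclass
class ProbeMontage:
    """Optode geometry plus the long/short channel map.

    Positions are 2-D scalp-plane coordinates in cm. A channel's position for
    distance computations is the midpoint of its emitter and detector.
    """

    emitter_positions: np.ndarray
    detector_positions: np.ndarray
    channels: list[Channel]
    wavelengths: tuple[int, int] = WAVELENGTHS_NM

    def __post_init__(self):
        self.emitter_positions = np.asarray(self.emitter_positions, dtype=float)
        self.detector_positions = np.asarray(self.detector_positions, dtype=float)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def long_channels(self) -> list[Channel]:
        return [c for c in self.channels if not c.is_short]

    @property
    def short_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.is_short]

    def midpoint(self, channel: Channel) -> np.ndarray:
        e = self.emitter_positions[channel.emitter]
        d = self.detector_positions[channel.detector]
        return (e + d) / 2.0

    def separation(self, channel: Channel) -> float:
        e = self.emitter_positions[channel.emitter]
        d = self.detector_positions[channel.detector]
        return float(np.linalg.norm(e - d))

    def subregion_channels(self, subregion: str) -> list[Channel]:
        return [c for c in self.channels if c.subregion == subregion]

    def validate(self) -> None:
        if len(self.long_channels) != 6:
            raise ValueError(f"expected 6 long channels, found {len(self.long_channels)}")
        if len(self.short_channels) != 2:
            raise ValueError(f"expected 2 short channels, found {len(self.short_channels)}")
        for sub in SUBREGIONS:
            n = len(self.subregion_channels(sub))
            if n != 2:
                raise ValueError(f"subregion {sub} has {n} channels, expected 2")
        for c in self.short_channels:
            if c.subregion != SHORT:
                raise ValueError(f"short channel {c.name} mapped to {c.subregion}")
        min_long = min(self.separation(c) for c in self.long_channels)
        max_short = max(self.separation(c) for c in self.short_channels)
        if not min_long > max_short:
            raise ValueError("long-channel separation must exceed short-channel separation")


def default_montage(short_separation_cm: float = 1.0, long_separation_cm: float = 3.5) -> ProbeMontage:
    """Prefrontal-band montage with invented but invariant-satisfying coordinates.

    The device the montage emulates does not publish optode coordinates; these
    2-D positions are approximations chosen to satisfy the geometry the
    analysis relies on (subregion grouping, long > short separation, left/right
    symmetry).
    """
    d_left = np.array([-2.0, 0.0])
    d_right = np.array([2.0, 0.0])
    r = long_separation_cm

    def polar(center, deg):
        a = np.deg2rad(deg)
        return center + r * np.array([np.cos(a), np.sin(a)])

    emitters = np.array(
        [
            polar(d_left, 150.0),   # E0 left lateral upper
            polar(d_left, 210.0),   # E1 left lateral lower
            polar(d_left, -60.0),   # E2 lower medial left
            polar(d_right, 240.0),  # E3 lower medial right
            polar(d_right, 30.0),   # E4 right lateral upper
            polar(d_right, -30.0),  # E5 right lateral lower
            d_left + np.array([short_separation_cm, 0.0]),   # E6 short left
            d_right + np.array([-short_separation_cm, 0.0]),  # E7 short right
        ]
    )
    detectors = np.stack([d_left, d_right])
    channels = [
        Channel(0, "LL1", 0, 0, False, "left_lateral"),
        Channel(1, "LL2", 1, 0, False, "left_lateral"),
        Channel(2, "LM1", 2, 0, False, "lower_medial"),
        Channel(3, "LM2", 3, 1, False, "lower_medial"),
        Channel(4, "RL1", 4, 1, False, "right_lateral"),
        Channel(5, "RL2", 5, 1, False, "right_lateral"),
        Channel(6, "SL", 6, 0, True, SHORT),
        Channel(7, "SR", 7, 1, True, SHORT),
    ]
    m = ProbeMontage(emitters, detectors, channels)
    m.validate()
    return m


def nearest_short_channel(montage: ProbeMontage, channel: Channel | int) -> Channel:
    """Short channel minimising Euclidean midpoint distance to a long channel.

    Ties break to the lowest channel index.
    """
    if isinstance(channel, int):
        channel = montage.channels[channel]
    if channel.is_short:
        raise ValueError(f"{channel.name} is a short channel")
    shorts = montage.short_channels
    if not shorts:
        raise ValueError("montage has no short channels")
    mid = montage.midpoint(channel)
    best = min(shorts, key=lambda s: (float(np.linalg.norm(montage.midpoint(s) - mid)), s.index))
    return best


# ---------------------------------------------------------------------------
# events


def make_event_table(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=EVENT_COLUMNS)
    return validate_events(df)


def validate_events(events: pd.DataFrame, recording_duration_s: float | None = None) -> pd.DataFrame:
    """Check ordering, overlap, and the low-context design constraints."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    ev = events.reset_index(drop=True)
    if len(ev) == 0:
        return ev
    onsets = ev["onset"].to_numpy(float)
    durs = ev["duration"].to_numpy(float)
    if np.any(durs <= 0):
        raise ValueError("event durations must be positive")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("events must be strictly time-ordered")
    offsets = onsets + durs
    if np.any(onsets[1:] < offsets[:-1]):
        raise ValueError("events overlap")
    bad_cond = set(ev["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
    low = ev["context"] == "low"
    if np.any(ev.loc[low, "n_sentences"].to_numpy() < 3):
        raise ValueError("low-context events must have >= 3 sentences")
    if np.any(ev.loc[low, "duration"].to_numpy(float) < 18.0):
        raise ValueError("low-context events must last >= 18 s")
    if recording_duration_s is not None and np.any(offsets > recording_duration_s + 1e-9):
        raise ValueError("event window extends beyond the recording")
    return ev


# ---------------------------------------------------------------------------
# recordings


@dataclass
class RawRecording:
    """Dual-wavelength intensity time series with event markers.

    intensity has shape (n_times, n_channels, n_wavelengths) in arbitrary
    device units and must be strictly positive; channel order follows
    ``montage.channels`` (left to right, long before short).
    """

    intensity: np.ndarray
    fs: float
    events: pd.DataFrame
    montage: ProbeMontage
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)

    @property
    def n_times(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.intensity.ndim != 3 or self.intensity.shape[2] != len(self.montage.wavelengths):
            raise ValueError("intensity must be (time, channel, wavelength)")
        if self.intensity.shape[1] != self.montage.n_channels:
            raise ValueError("channel count mismatch between intensity and montage")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite samples")
        if np.any(self.intensity <= 0):
            raise ValueError("intensity must be strictly positive")
        validate_events(self.events, self.duration_s)
        self.montage.validate()


# ---------------------------------------------------------------------------
# SNIRF I/O

_FORMAT_VERSION = "1.0"


def _write_str(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def _read_str(obj) -> str:
    v = obj[()]
    if isinstance(v, bytes):
        return v.decode()
    return str(v)


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as a SNIRF/HDF5 file, one data block per wavelength."""
    rec.validate()
    path = Path(path)
    m = rec.montage
    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", _FORMAT_VERSION)
        nirs = f.create_group("nirs")
        tags = nirs.create_group("metaDataTags")
        _write_str(tags, "SubjectID", str(rec.meta.get("participant", "unknown")))
        _write_str(tags, "handedness", str(rec.meta.get("handedness", "right")))
        _write_str(tags, "session", str(rec.meta.get("session", "")))
        _write_str(tags, "LengthUnit", "cm")
        _write_str(tags, "TimeUnit", "s")
        _write_str(tags, "FrequencyUnit", "Hz")
        _write_str(tags, "MeasurementDate", "unknown")
        _write_str(tags, "MeasurementTime", "unknown")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(m.wavelengths, dtype=float))
        probe.create_dataset("sourcePos2D", data=m.emitter_positions)
        probe.create_dataset("detectorPos2D", data=m.detector_positions)
        probe.create_dataset(
            "channelLabels", data=np.array([c.name for c in m.channels], dtype="S")
        )
        probe.create_dataset(
            "channelSubregions", data=np.array([c.subregion for c in m.channels], dtype="S")
        )
        probe.create_dataset(
            "channelIsShort", data=np.array([c.is_short for c in m.channels], dtype=np.int8)
        )

        time = np.arange(rec.n_times) / rec.fs
        for wi in range(len(m.wavelengths)):
            data = nirs.create_group(f"data{wi + 1}")
            data.create_dataset("dataTimeSeries", data=rec.intensity[:, :, wi])
            data.create_dataset("time", data=time)
            for ci, ch in enumerate(m.channels):
                ml = data.create_group(f"measurementList{ci + 1}")
                ml.create_dataset("sourceIndex", data=np.int32(ch.emitter + 1))
                ml.create_dataset("detectorIndex", data=np.int32(ch.detector + 1))
                ml.create_dataset("wavelengthIndex", data=np.int32(wi + 1))
                ml.create_dataset("dataType", data=np.int32(1))  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=np.int32(1))

        labels = ["onset", "duration", "n_sentences", "context_low", "block", "practice"]
        for si, cond in enumerate(CONDITIONS):
            sub = rec.events[rec.events["condition"] == cond]
            stim = nirs.create_group(f"stim{si + 1}")
            _write_str(stim, "name", cond)
            arr = np.column_stack(
                [
                    sub["onset"].to_numpy(float),
                    sub["duration"].to_numpy(float),
                    sub["n_sentences"].to_numpy(float),
                    (sub["context"] == "low").to_numpy(float),
                    sub["block"].to_numpy(float),
                    sub["practice"].to_numpy(float),
                ]
            ) if len(sub) else np.zeros((0, len(labels)))
            stim.create_dataset("data", data=arr)
            stim.create_dataset("dataLabels", data=np.array(labels, dtype="S"))


def read_recording(path: str | Path) -> RawRecording:
    """Read a SNIRF/HDF5 file written by :func:`write_recording`.

    Channels are returned in canonical order (left to right, long before
    short). Raises :class:`SnirfParseError` naming the offending group on a
    malformed file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise SnirfParseError("/nirs", "group missing")
        nirs = f["nirs"]
        if "probe" not in nirs:
            raise SnirfParseError("/nirs/probe", "group missing")
        probe = nirs["probe"]
        wavelengths = tuple(int(w) for w in probe["wavelengths"][()])
        for w in WAVELENGTHS_NM:
            if w not in wavelengths:
                raise SnirfParseError("/nirs/probe/wavelengths", f"missing wavelength {w} nm")
        emitters = probe["sourcePos2D"][()]
        detectors = probe["detectorPos2D"][()]

        data_keys = sorted(k for k in nirs if k.startswith("data"))
        if len(data_keys) != len(wavelengths):
            raise SnirfParseError(
                "/nirs", f"expected {len(wavelengths)} data blocks, found {len(data_keys)}"
            )

        # channel table from the first data block's measurement list
        d1 = nirs[data_keys[0]]
        ml_keys = sorted(
            (k for k in d1 if k.startswith("measurementList")),
            key=lambda k: int(k.removeprefix("measurementList")),
        )
        n_ch = len(ml_keys)
        pairs = []
        for k in ml_keys:
            ml = d1[k]
            pairs.append((int(ml["sourceIndex"][()]) - 1, int(ml["detectorIndex"][()]) - 1))

        if "channelSubregions" in probe:
            subregions = [s.decode() for s in probe["channelSubregions"][()]]
            labels = [s.decode() for s in probe["channelLabels"][()]]
            is_short = probe["channelIsShort"][()].astype(bool)
        else:
            raise SnirfParseError("/nirs/probe/channelSubregions", "dataset missing")

        wl_order = np.argsort([wavelengths.index(w) for w in WAVELENGTHS_NM])
        intensity = np.empty((d1["dataTimeSeries"].shape[0], n_ch, len(wavelengths)))
        time = d1["time"][()]
        for wi_file, key in enumerate(data_keys):
            blk = nirs[key]
            ts = blk["dataTimeSeries"][()]
            if ts.shape[1] != n_ch:
                raise SnirfParseError(f"/nirs/{key}/dataTimeSeries", "channel count mismatch")
            wl_idx = int(blk["measurementList1/wavelengthIndex"][()]) - 1
            intensity[:, :, WAVELENGTHS_NM.index(wavelengths[wl_idx])] = ts
        if np.any(~np.isfinite(intensity)) or np.any(intensity <= 0):
            raise SnirfParseError("/nirs/data1/dataTimeSeries", "non-positive or non-finite samples")
        fs = 1.0 / float(np.median(np.diff(time)))

        channels = [
            Channel(i, labels[i], pairs[i][0], pairs[i][1], bool(is_short[i]), subregions[i])
            for i in range(n_ch)
        ]
        montage = ProbeMontage(emitters, detectors, channels)

        # canonical order: long before short, then left-to-right midpoints
        def sort_key(c: Channel):
            mid = montage.midpoint(c)
            return (c.is_short, round(float(mid[0]), 6), round(float(mid[1]), 6), c.index)

        order = sorted(range(n_ch), key=lambda i: sort_key(channels[i]))
        channels = [dataclasses.replace(channels[i], index=new) for new, i in enumerate(order)]
        intensity = intensity[:, order, :]
        montage = ProbeMontage(emitters, detectors, channels)

        rows = []
        for k in sorted(k for k in nirs if k.startswith("stim")):
            stim = nirs[k]
            cond = _read_str(stim["name"])
            arr = stim["data"][()]
            if arr.ndim != 2 or (arr.size and arr.shape[1] != 6):
                raise SnirfParseError(f"/nirs/{k}/data", "malformed stimulus table")
            for row in arr:
                rows.append(
                    {
                        "onset": float(row[0]),
                        "duration": float(row[1]),
                        "condition": cond,
                        "context": "low" if row[3] > 0.5 else "high",
                        "n_sentences": int(row[2]),
                        "block": int(row[4]),
                        "practice": bool(row[5] > 0.5),
                    }
                )
        events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        if len(events):
            events = events.sort_values("onset").reset_index(drop=True)

        tags = nirs["metaDataTags"]
        meta = {
            "participant": _read_str(tags["SubjectID"]),
            "handedness": _read_str(tags["handedness"]),
            "session": _read_str(tags["session"]),
        }

    rec = RawRecording(intensity=intensity, fs=fs, events=events, montage=montage, meta=meta)
    try:
        rec.validate()
    except ValueError as exc:  # surface validation as a parse error with context
        raise SnirfParseError("/nirs", str(exc)) from exc
    return rec


# ---------------------------------------------------------------------------
# YAML montage round-trip (config-file interface)


def montage_to_yaml(montage: ProbeMontage, path: str | Path) -> None:
    doc = {
        "wavelengths_nm": list(montage.wavelengths),
        "emitter_positions_cm": montage.emitter_positions.tolist(),
        "detector_positions_cm": montage.detector_positions.tolist(),
        "channels": [
            {
                "name": c.name,
                "emitter": c.emitter,
                "detector": c.detector,
                "is_short": c.is_short,
                "subregion": c.subregion,
            }
            for c in montage.channels
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def montage_from_yaml(path: str | Path) -> ProbeMontage:
    doc = yaml.safe_load(Path(path).read_text())
    channels = [
        Channel(i, c["name"], int(c["emitter"]), int(c["detector"]), bool(c["is_short"]), c["subregion"])
        for i, c in enumerate(doc["channels"])
    ]
    m = ProbeMontage(
        np.asarray(doc["emitter_positions_cm"], float),
        np.asarray(doc["detector_positions_cm"], float),
        channels,
        tuple(doc.get("wavelengths_nm", WAVELENGTHS_NM)),
    )
    m.validate()
    return m
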