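"""Recording and table I/O.

Three-channel ECoG sessions (focus electrode plus electrodes 1 mm and
2 mm away) are carried as :class:`EcogRecording`.  Sessions round-trip
through three on-disk formats: European Data Format (EDF, 16-bit),
delimited text with a JSON metadata sidecar, and a NumPy ``.npz``
binary-array container.  Event tables are plain CSV written losslessly
(17 significant digits).

Conventions used throughout the package:

* amplitudes are µV, internally and in every file format;
* time is sample indices internally, seconds at interfaces;
* event intervals are half-open ``[start, end)`` in 0-based samples;
* channel identity is carried by the labels ``focus``, ``d1mm``,
  ``d2mm``, never by channel order.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNEL_ROLES = ("focus", "d1mm", "d2mm")

GROUPS = (
    "epilepsy_control",
    "epilepsy_laser_cut_single",
    "epilepsy_laser_cut_close_double",
    "epilepsy_laser_cut_wide_double",
    "laser_cut_control",
    "surgical_control",
)

#: groups that received a circumscribing laser cut around the focus
LASER_CUT_GROUPS = (
    "epilepsy_laser_cut_single",
    "epilepsy_laser_cut_close_double",
    "epilepsy_laser_cut_wide_double",
)

EVENT_TYPES = ("seizure", "polyspike", "interictal_spike")
REGIMES = ("propagated", "attenuated", "nonpropagated")


class RecordingError(ValueError):
    """Base class for recording validation / I/O failures."""


class UnreadableFileError(RecordingError):
    """The file does not exist or cannot be parsed as the declared format."""


class ChannelCountError(RecordingError):
    """The file does not contain exactly the three expected channels."""


class SamplingRateError(RecordingError):
    """Non-positive or missing sampling rate."""


class NonFiniteSampleError(RecordingError):
    """NaN or infinite samples in a channel."""


class ChannelLengthError(RecordingError):
    """Channels of unequal length."""


class RailError(RecordingError):
    """Non-positive rail, or samples exceeding the rail."""


@dataclass
class EcogRecording:
    """One recording session: three labelled channels plus metadata.

    Parameters
    ----------
    animal_id : str
        Subject identifier.
    group : str
        One of :data:`GROUPS`.
    week : int
        Weeks since the first recording (>= 0).
    sampling_rate : float
        Hz, strictly positive.
    channels : dict
        Maps each of ``focus``, ``d1mm``, ``d2mm`` to a float array in µV.
    rail : float
        Amplifier saturation magnitude in µV; every |sample| <= rail.
    """

    animal_id: str
    group: str
    week: int
    sampling_rate: float
    channels: dict[str, np.ndarray]
    rail: float

    @property
    def n_samples(self) -> int:
        return len(self.channels["focus"])

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.n_samples / self.sampling_rate

    def validate(self) -> "EcogRecording":
        if self.group not in GROUPS:
            raise RecordingError(f"unknown group {self.group!r}")
        if self.week < 0:
            raise RecordingError(f"negative week {self.week}")
        if not self.sampling_rate > 0:
            raise SamplingRateError(
                f"sampling rate must be > 0, got {self.sampling_rate}"
            )
        if set(self.channels) != set(CHANNEL_ROLES):
            raise ChannelCountError(
                f"expected channels {CHANNEL_ROLES}, got {sorted(self.channels)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ChannelLengthError(f"unequal channel lengths {lengths}")
        if not self.rail > 0:
            raise RailError(f"rail must be > 0, got {self.rail}")
        for name, x in self.channels.items():
            if not np.all(np.isfinite(x)):
                raise NonFiniteSampleError(f"non-finite samples in channel {name!r}")
            if np.max(np.abs(x), initial=0.0) > self.rail * (1 + 1e-9):
                raise RailError(f"samples in {name!r} exceed the rail {self.rail}")
        return self


@dataclass
class RunConfig:
    """All tunable analysis parameters with their defaults.

    Detection: the focus channel is rectified and thresholded at
    median + ``threshold_k`` robust SDs (1.4826 × MAD); sub-threshold
    gaps up to ``merge_gap_s`` are merged and intervals shorter than
    ``min_duration_s`` dropped.

    Classification: 1–2 spikes and < ``polyspike_max_s`` → interictal
    spike; >= 3 spikes and < ``seizure_min_s`` → polyspike;
    >= ``seizure_min_s`` with sustained spiking (>= ``seizure_min_rate``
    spikes/s) → seizure.

    Power metrics use Hann-tapered windows of ``bp_window_s`` seconds
    with hop ``bp_hop_s`` over the 0–``band_high_hz`` Hz band.  Events
    with a saturated focus-sample fraction strictly greater than
    ``saturation_exclusion_fraction`` are excluded from power metrics.
    """

    # detection
    threshold_k: float = 6.0
    merge_gap_s: float = 1.0
    min_duration_s: float = 0.03
    # classification
    spike_refractory_s: float = 0.06
    polyspike_max_s: float = 1.0
    seizure_min_s: float = 10.0
    seizure_min_rate: float = 1.0  # spikes/s
    # band power
    bp_window_s: float = 1.0
    bp_hop_s: float = 0.5
    band_low_hz: float = 0.0
    band_high_hz: float = 50.0
    # clustering
    cluster_k: int = 3
    cluster_seed: int = 0
    cluster_max_iter: int = 100
    cluster_reg_eps: float = 1e-6
    cluster_init: str = "farthest_first"  # or "percentile"
    # saturation bookkeeping
    saturation_exclusion_fraction: float = 0.10
    rail_tolerance: float = 0.999
    # weekly centroid tracks
    weekly_min_seizures: int = 10
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("saturation_exclusion_fraction", "rail_tolerance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cluster_k < 2:
            raise ValueError(f"cluster_k must be >= 2, got {self.cluster_k}")
        for name in ("bp_window_s", "bp_hop_s", "min_duration_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# recording readers / writers

_FORMATS = ("edf", "delimited", "binary-array")


def _meta_dict(rec: EcogRecording) -> dict:
    return {
        "animal_id": rec.animal_id,
        "group": rec.group,
        "week": int(rec.week),
        "sampling_rate": float(rec.sampling_rate),
        "rail": float(rec.rail),
    }


def write_recording(rec: EcogRecording, path: str | Path, format: str) -> Path:
    """Write a validated recording in the requested format."""
    rec.validate()
    path = Path(path)
    if format == "binary-array":
        np.savez(
            path,
            meta=json.dumps(_meta_dict(rec)),
            **{k: rec.channels[k] for k in CHANNEL_ROLES},
        )
    elif format == "delimited":
        df = pd.DataFrame({k: rec.channels[k] for k in CHANNEL_ROLES})
        df.to_csv(path, index=False, float_format="%.17g")
        Path(str(path) + ".json").write_text(json.dumps(_meta_dict(rec)))
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return path


def read_recording(path: str | Path, format: str) -> EcogRecording:
    """Read and validate a recording; samples returned in µV."""
    path = Path(path)
    if not path.exists():
        raise UnreadableFileError(f"no such file: {path}")
    if format == "binary-array":
        try:
            with np.load(path, allow_pickle=False) as z:
                meta = json.loads(str(z["meta"]))
                keys = [k for k in z.files if k != "meta"]
                channels = {k: np.asarray(z[k], dtype=float) for k in keys}
        except Exception as exc:  # zip/format damage
            raise UnreadableFileError(f"cannot parse {path}: {exc}") from exc
    elif format == "delimited":
        try:
            df = pd.read_csv(path)
            meta = json.loads(Path(str(path) + ".json").read_text())
        except FileNotFoundError as exc:
            raise UnreadableFileError(f"missing sidecar for {path}") from exc
        except Exception as exc:
            raise UnreadableFileError(f"cannot parse {path}: {exc}") from exc
        channels = {c: df[c].to_numpy(dtype=float) for c in df.columns}
    elif format == "edf":
        meta, channels = _read_edf(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")

    if set(channels) != set(CHANNEL_ROLES):
        raise ChannelCountError(
            f"{path}: expected channels {CHANNEL_ROLES}, got {sorted(channels)}"
        )
    if "rail" not in meta or meta["rail"] is None:
        # fall back to the file's physical maximum
        meta["rail"] = float(max(np.max(np.abs(v)) for v in channels.values()))
    rec = EcogRecording(
        animal_id=str(meta["animal_id"]),
        group=str(meta["group"]),
        week=int(meta["week"]),
        sampling_rate=float(meta["sampling_rate"]),
        channels=channels,
        rail=float(meta["rail"]),
    )
    return rec.validate()


# ---------------------------------------------------------------------------
# minimal EDF layer
#
# No EDF writer ships with the scientific stack used here, so the writer
# below implements the (simple) EDF container directly: a 256-byte ASCII
# header, 256 bytes of per-signal header fields, then little-endian int16
# data records of one second each.  Reading goes through MNE, which also
# serves as the independent check that the writer emits valid EDF.


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def _write_edf(rec: EcogRecording, path: Path) -> None:
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9 or spr <= 0:
        raise SamplingRateError(
            f"EDF writer uses 1-s records; sampling rate must be a positive "
            f"integer Hz, got {fs}"
        )
    n = rec.n_samples
    n_rec = int(np.ceil(n / spr))
    ns = len(CHANNEL_ROLES)
    phys_max = float(rec.rail)
    dig_min, dig_max = -32768, 32767
    scale = 2 * phys_max / (dig_max - dig_min)

    rid = (
        f"animal={rec.animal_id} group={rec.group} week={rec.week} "
        f"rail={phys_max:.6g} nsamp={n}"
    )
    hdr = b"".join(
        [
            _pad("0", 8),
            _pad("X", 80),
            _pad(rid, 80),
            _pad("01.01.01", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    fields = [
        (16, list(CHANNEL_ROLES)),
        (80, [""] * ns),
        (8, ["uV"] * ns),
        (8, [f"{-phys_max:.6g}"] * ns),
        (8, [f"{phys_max:.6g}"] * ns),
        (8, [str(dig_min)] * ns),
        (8, [str(dig_max)] * ns),
        (80, [""] * ns),
        (8, [str(spr)] * ns),
        (32, [""] * ns),
    ]
    sig_hdr = b"".join(b"".join(_pad(v, w) for v in vals) for w, vals in fields)

    padded = np.zeros((ns, n_rec * spr))
    for i, role in enumerate(CHANNEL_ROLES):
        padded[i, :n] = rec.channels[role]
    dig = np.clip(
        np.round((padded + phys_max) / scale) + dig_min, dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as f:
        f.write(hdr + sig_hdr)
        for r in range(n_rec):
            f.write(dig[:, r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path) -> tuple[dict, dict[str, np.ndarray]]:
    import mne  # heavy import, deferred

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise UnreadableFileError(f"cannot parse {path} as EDF: {exc}") from exc

    # metadata travels in the 80-byte recording-id header field
    with open(path, "rb") as f:
        f.seek(88)
        rid = f.read(80).decode("ascii", "replace").strip()
    meta: dict = {"animal_id": "unknown", "group": GROUPS[0], "week": 0}
    for tok in rid.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[{"animal": "animal_id"}.get(k, k)] = v
    meta["week"] = int(meta.get("week", 0))
    meta["sampling_rate"] = float(raw.info["sfreq"])
    meta["rail"] = float(meta["rail"]) if "rail" in meta else None

    data = raw.get_data() * 1e6  # MNE yields volts; internal unit is µV
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    if "nsamp" in meta:  # drop the zero padding of the last record
        nsamp = int(meta.pop("nsamp"))
        channels = {k: v[:nsamp].copy() for k, v in channels.items()}
    return meta, channels


# ---------------------------------------------------------------------------
# event tables

#: canonical event-table column order (stable across writes)
TABLE_COLUMNS = [
    "event_id",
    "animal_id",
    "group",
    "week",
    "type",
    "start",
    "end",
    "duration_s",
    "r_1mm",
    "r_2mm",
    "sat_frac_focus",
    "sat_frac_d1",
    "sat_frac_d2",
    "metrics_excluded",
    "cluster_label",
    "max_band_power",
    "auc",
    "norm_duration_d1",
    "norm_duration_d2",
    "norm_max_power_d1",
    "norm_max_power_d2",
    "norm_auc_d1",
    "norm_auc_d2",
    "arrival_focus_s",
    "arrival_d1_s",
    "arrival_d2_s",
    "delay_d1_s",
    "delay_d2_s",
]


def write_tables(events: pd.DataFrame, path: str | Path) -> Path:
    """Write an event table as CSV with a stable column order.

    Known columns come first in :data:`TABLE_COLUMNS` order; any extra
    columns follow alphabetically.  Numeric fields survive a round-trip
    losslessly (17 significant digits).
    """
    path = Path(path)
    df = events.copy()
    if "event_id" in df.columns and df["event_id"].duplicated().any():
        raise ValueError("duplicated event_id values")
    known = [c for c in TABLE_COLUMNS if c in df.columns]
    extra = sorted(c for c in df.columns if c not in TABLE_COLUMNS)
    df = df[known + extra]
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise UnreadableFileError(f"cannot write {path}: {exc}") from exc
    return path


def read_tables(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise UnreadableFileError(f"no such file: {path}")
    return pd.read_csv(path)
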