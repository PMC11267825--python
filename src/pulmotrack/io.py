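"""Dataset containers and the on-disk layout.

Each subject directory holds a reconstructed EIT pixel-frame sequence
(``eit_frames.bin``: little-endian float32, time x height x width, row-major,
with dimensions pinned in ``eit_meta.json``), the lung mask grid
(``lung_mask.csv``), the airway signal table (``airway.csv``) and the event
table (``events.csv``).  Round-trips are lossless for metadata and signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "EITSequence",
    "AirwaySignals",
    "EventLog",
    "Breath",
    "write_subject",
    "read_subject",
    "read_dataset",
    "write_features",
]

#: Orientation convention: row 0 is the most ventral pixel row (the sheep is
#: prone, so ventral is gravitationally dependent), rows increase dorsally;
#: column 0 is the subject's right, columns increase leftward.
ORIENTATION = "row0=ventral,col0=right"


class DatasetError(ValueError):
    """A dataset file is missing or inconsistent with its metadata."""


@dataclass
class EITSequence:
    """Time-ordered reconstructed impedance frames with lung mask."""

    frames: np.ndarray  # (time, height, width), arbitrary units
    frame_rate: float  # Hz
    lung_mask: np.ndarray  # boolean (height, width)
    orientation: str = ORIENTATION

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        if self.frames.ndim != 3:
            raise DatasetError("frames must be a 3-D (time, height, width) array")
        if self.frame_rate <= 0:
            raise DatasetError("frame_rate must be > 0")
        if self.lung_mask.shape != self.frames.shape[1:]:
            raise DatasetError(
                f"lung_mask shape {self.lung_mask.shape} does not match frame "
                f"shape {self.frames.shape[1:]}"
            )
        if not self.lung_mask.any():
            raise DatasetError("lung_mask is empty")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AirwaySignals:
    """Synchronized airway-opening signals on a uniform time grid."""

    time: np.ndarray  # s
    flow: np.ndarray  # L/s, positive = inspiration
    paw: np.ndarray  # cmH2O
    pco2: np.ndarray  # mmHg
    sample_rate: float  # Hz

    def __post_init__(self) -> None:
        for name in ("time", "flow", "paw", "pco2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        if any(len(getattr(self, s)) != n for s in ("flow", "paw", "pco2")):
            raise DatasetError("airway signal arrays must have equal length")
        if self.sample_rate <= 0:
            raise DatasetError("sample_rate must be > 0")
        if n > 1:
            dt = np.diff(self.time)
            # tolerance admits text round-tripping of the time column
            if dt.min() <= 0 or not np.allclose(dt, 1.0 / self.sample_rate, atol=1e-4):
                raise DatasetError("time must be strictly increasing and uniform")


@dataclass
class EventLog:
    """Experiment landmarks, in the airway timebase (s)."""

    apnea_start: float
    apnea_end: float
    injection_start: float
    injection_end: float

    def __post_init__(self) -> None:
        if self.apnea_end > self.injection_start:
            raise DatasetError("apnea must end before the injection starts")


@dataclass
class Breath:
    """Per-breath landmarks.  Breath 1 is the first after the apnea."""

    ordinal: int
    insp_start: int  # sample indices in the airway timebase
    insp_end: int
    exp_end: int
    frame_insp_start: int | None = None  # EIT frame indices
    frame_insp_end: int | None = None
    t_mid: float | None = None  # s relative to injection start
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.insp_start < self.insp_end < self.exp_end):
            raise ValueError("breath landmarks must satisfy insp_start < insp_end < exp_end")

    @property
    def excluded(self) -> bool:
        return any(self.flags.get(k) for k in ("spontaneous_effort", "leak", "incomplete"))


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------


def write_subject(path: str | Path, eit: EITSequence, airway: AirwaySignals, events: EventLog) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = np.ascontiguousarray(eit.frames, dtype="<f4")
    frames.tofile(path / "eit_frames.bin")
    meta = {
        "n_frames": int(eit.n_frames),
        "height": int(eit.frames.shape[1]),
        "width": int(eit.frames.shape[2]),
        "frame_rate": float(eit.frame_rate),
        "orientation": eit.orientation,
        "dtype": "<f4",
        "t0": float(airway.time[0]),
    }
    (path / "eit_meta.json").write_text(json.dumps(meta, indent=1))
    np.savetxt(path / "lung_mask.csv", eit.lung_mask.astype(int), fmt="%d", delimiter=",")
    pd.DataFrame(
        {
            "time_s": airway.time,
            "flow_lps": airway.flow,
            "paw_cmh2o": airway.paw,
            "pco2_mmhg": airway.pco2,
        }
    ).to_csv(path / "airway.csv", index=False, float_format="%.6f")
    pd.DataFrame(
        {
            "event": ["apnea_start", "apnea_end", "injection_start", "injection_end"],
            "time_s": [
                events.apnea_start,
                events.apnea_end,
                events.injection_start,
                events.injection_end,
            ],
        }
    ).to_csv(path / "events.csv", index=False)
    return path


def read_subject(path: str | Path) -> tuple[EITSequence, AirwaySignals, EventLog]:
    path = Path(path)
    meta_file = path / "eit_meta.json"
    if not meta_file.exists():
        raise DatasetError(f"missing file {meta_file}")
    meta = json.loads(meta_file.read_text())
    for key in ("n_frames", "height", "width", "frame_rate"):
        if key not in meta:
            raise DatasetError(f"{meta_file}: missing field {key!r}")
    frames_file = path / "eit_frames.bin"
    if not frames_file.exists():
        raise DatasetError(f"missing file {frames_file}")
    raw = np.fromfile(frames_file, dtype=meta.get("dtype", "<f4"))
    expected = meta["n_frames"] * meta["height"] * meta["width"]
    if raw.size != expected:
        raise DatasetError(
            f"{frames_file}: found {raw.size} values, metadata field 'n_frames' "
            f"implies {expected}"
        )
    frames = raw.reshape(meta["n_frames"], meta["height"], meta["width"])
    mask_file = path / "lung_mask.csv"
    if not mask_file.exists():
        raise DatasetError(f"missing file {mask_file}")
    mask = np.loadtxt(mask_file, delimiter=",", dtype=int, ndmin=2).astype(bool)
    if mask.shape != (meta["height"], meta["width"]):
        raise DatasetError(
            f"{mask_file}: field 'lung_mask' has shape {mask.shape}, expected "
            f"({meta['height']}, {meta['width']})"
        )
    eit = EITSequence(
        frames=frames,
        frame_rate=meta["frame_rate"],
        lung_mask=mask,
        orientation=meta.get("orientation", ORIENTATION),
    )
    airway_file = path / "airway.csv"
    if not airway_file.exists():
        raise DatasetError(f"missing file {airway_file}")
    adf = pd.read_csv(airway_file)
    for col in ("time_s", "flow_lps", "paw_cmh2o", "pco2_mmhg"):
        if col not in adf.columns:
            raise DatasetError(f"{airway_file}: missing column {col!r}")
    dt = np.diff(adf["time_s"].to_numpy())
    sr = 1.0 / np.median(dt) if len(dt) else 1.0
    airway = AirwaySignals(
        time=adf["time_s"].to_numpy(),
        flow=adf["flow_lps"].to_numpy(),
        paw=adf["paw_cmh2o"].to_numpy(),
        pco2=adf["pco2_mmhg"].to_numpy(),
        sample_rate=round(sr, 6),
    )
    events_file = path / "events.csv"
    if not events_file.exists():
        raise DatasetError(f"missing file {events_file}")
    edf = pd.read_csv(events_file).set_index("event")["time_s"]
    try:
        events = EventLog(
            apnea_start=float(edf["apnea_start"]),
            apnea_end=float(edf["apnea_end"]),
            injection_start=float(edf["injection_start"]),
            injection_end=float(edf["injection_end"]),
        )
    except KeyError as exc:
        raise DatasetError(f"{events_file}: missing event {exc}") from exc
    return eit, airway, events


def read_dataset(root: str | Path) -> dict[str, tuple[EITSequence, AirwaySignals, EventLog]]:
    """Read every subject directory under ``root`` (those with eit_meta.json)."""
    root = Path(root)
    subjects = sorted(p for p in root.iterdir() if (p / "eit_meta.json").exists())
    if not subjects:
        raise DatasetError(f"no subject directories found under {root}")
    return {p.name: read_subject(p) for p in subjects}


def write_features(tables: dict[str, pd.DataFrame], out_path: str | Path) -> dict[str, Path]:
    """Write feature tables (breaths, features_eit, ...) as CSV files."""
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
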