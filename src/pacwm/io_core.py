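"""Data model, fixture I/O, configuration and epoch extraction.

The unit of analysis is a :class:`Session`: one recording with a trial table,
per-channel LFP epochs and per-unit spike trains.  All times are in seconds;
trial-relative time 0 is the onset of the working-memory maintenance period and
sample windows are half-open ``[start, end)``.

Fixture sessions are stored as a directory with ``trials.csv``, ``spikes.csv``,
``lfp.h5`` and ``meta.json`` so that everything round-trips losslessly through
plain-text plus HDF5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

REGIONS = ("hippocampus", "amygdala", "preSMA", "dACC", "vmPFC")

#: sampling rate (Hz) of preprocessed LFP
FS_LFP = 400.0

#: analysis window of the maintenance period, seconds relative to its onset
MAINTENANCE_WINDOW = (0.0, 2.5)

#: epoch window used for filtering (edges trimmed afterwards)
EPOCH_WINDOW = (-0.5, 3.0)


class SchemaError(ValueError):
    """A fixture or NWB file does not match the expected layout."""


class ValidationError(ValueError):
    """Loaded data violate a structural invariant (bad region label, etc.)."""


def make_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a numpy Generator; pass Generators through unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def load_config(path: str | Path) -> dict:
    """Read a YAML stage-parameter file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "trial_id", "load", "encoded_categories", "correct", "rt",
    "maintenance_onset", "picture_onsets", "probe_onset",
]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table invariants and return the frame unchanged.

    Loads are 1 or 3, a load-3 trial carries three *distinct* categories,
    reaction times are positive and event times increase within a trial.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table is missing columns: {missing}")
    for _, row in trials.iterrows():
        cats = list(row["encoded_categories"])
        if row["load"] not in (1, 3):
            raise ValidationError(f"trial {row['trial_id']}: load must be 1 or 3")
        if len(cats) != row["load"]:
            raise ValidationError(
                f"trial {row['trial_id']}: {len(cats)} categories for load {row['load']}")
        if len(set(cats)) != len(cats):
            raise ValidationError(f"trial {row['trial_id']}: repeated category")
        if row["rt"] <= 0:
            raise ValidationError(f"trial {row['trial_id']}: rt must be positive")
        onsets = list(row["picture_onsets"])
        times = onsets + [row["maintenance_onset"], row["probe_onset"]]
        if not np.all(np.diff(times) > 0):
            raise ValidationError(f"trial {row['trial_id']}: event times not increasing")
    return trials


@dataclass
class LFPEpochs:
    """Epoched LFP of one microwire channel (trials x time, microvolts)."""

    channel_id: str
    region: str
    fs: float
    samples: np.ndarray           # (n_trials, n_samples)
    window: tuple[float, float]   # seconds relative to maintenance onset
    valid_trials: np.ndarray      # bool per trial

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region label {self.region!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        self.valid_trials = np.asarray(self.valid_trials, dtype=bool)
        if self.samples.shape[0] != self.valid_trials.shape[0]:
            raise ValidationError("valid_trials length does not match samples")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, relative to maintenance onset."""
        n = self.samples.shape[1]
        return self.window[0] + np.arange(n) / self.fs


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one unit on the session clock."""

    unit_id: str
    region: str
    channel_id: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region label {self.region!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise ValidationError(f"unit {self.unit_id}: timestamps not sorted")


@dataclass
class Session:
    """One recording session: trials + LFP epochs + spike trains."""

    trials: pd.DataFrame
    lfp: list[LFPEpochs]
    units: list[SpikeTrain]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_trials(self.trials)
        n = len(self.trials)
        for ep in self.lfp:
            if ep.valid_trials.shape[0] != n:
                raise ValidationError(
                    f"channel {ep.channel_id}: mask length {ep.valid_trials.shape[0]} != {n} trials")

    def channels(self, region: str | None = None) -> list[LFPEpochs]:
        return [c for c in self.lfp if region is None or c.region == region]

    def get_channel(self, channel_id: str) -> LFPEpochs:
        for c in self.lfp:
            if c.channel_id == channel_id:
                return c
        raise KeyError(channel_id)

    def get_unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def _encode_list(values: Sequence[float]) -> str:
    return ";".join(repr(float(v)) for v in values)


def _decode_list(text: str) -> list[float]:
    if text == "":
        return []
    return [float(tok) for tok in str(text).split(";")]


def save_session(session: Session, path: str | Path) -> Path:
    """Write a Session to the fixture layout (CSV + HDF5 + JSON sidecar)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    trials = session.trials.copy()
    trials["encoded_categories"] = [
        ";".join(str(int(c)) for c in cats) for cats in trials["encoded_categories"]]
    trials["picture_onsets"] = [_encode_list(t) for t in trials["picture_onsets"]]
    trials["correct"] = trials["correct"].astype(int)
    trials.to_csv(path / "trials.csv", index=False, float_format="%.17g")

    rows = []
    for u in session.units:
        for t in u.timestamps:
            rows.append((u.unit_id, u.region, u.channel_id, repr(float(t))))
    pd.DataFrame(rows, columns=["unit_id", "region", "channel_id", "timestamp"]).to_csv(
        path / "spikes.csv", index=False)

    with h5py.File(path / "lfp.h5", "w") as fh:
        for ep in session.lfp:
            g = fh.create_group(ep.channel_id)
            g.attrs["region"] = ep.region
            g.attrs["fs"] = ep.fs
            g.attrs["window"] = ep.window
            g.create_dataset("samples", data=ep.samples)
            g.create_dataset("valid_trials", data=ep.valid_trials)

    with open(path / "meta.json", "w") as fh:
        json.dump(session.metadata, fh, indent=1, default=float)
    return path


def _load_fixture(path: Path) -> Session:
    for name in ("trials.csv", "spikes.csv", "lfp.h5", "meta.json"):
        if not (path / name).exists():
            raise SchemaError(f"fixture at {path} is missing {name}")

    trials = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trials.csv is missing columns: {missing}")
    trials["encoded_categories"] = [
        [int(tok) for tok in str(s).split(";")] for s in trials["encoded_categories"]]
    trials["picture_onsets"] = [_decode_list(s) for s in trials["picture_onsets"]]
    trials["correct"] = trials["correct"].astype(bool)

    spikes = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    units = []
    if len(spikes):
        for (uid, region, chan), grp in spikes.groupby(
                ["unit_id", "region", "channel_id"], sort=False):
            units.append(SpikeTrain(
                unit_id=str(uid), region=str(region), channel_id=str(chan),
                timestamps=np.sort(grp["timestamp"].astype(float).to_numpy())))

    lfp = []
    with h5py.File(path / "lfp.h5", "r") as fh:
        for chan in sorted(fh.keys()):
            g = fh[chan]
            lfp.append(LFPEpochs(
                channel_id=chan, region=str(g.attrs["region"]),
                fs=float(g.attrs["fs"]), samples=g["samples"][()],
                window=tuple(float(w) for w in g.attrs["window"]),
                valid_trials=g["valid_trials"][()].astype(bool)))

    with open(path / "meta.json") as fh:
        metadata = json.load(fh)
    return Session(trials=trials, lfp=lfp, units=units, metadata=metadata)


def load_session(path: str | Path, format: str = "fixture") -> Session:
    """Load a session from disk.

    ``format="fixture"`` reads the package's own CSV/HDF5 layout.
    ``format="nwb"`` reads an NWB file via :mod:`pynwb` when that package is
    installed; the reader is tolerant to acquisition-naming variants.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fixture":
        return _load_fixture(path)
    if format == "nwb":
        return _load_nwb(path)
    raise ValueError(f"unknown format {format!r}")


def _load_nwb(path: Path) -> Session:  # pragma: no cover - optional interface
    try:
        import pynwb  # noqa: F401
    except ImportError as exc:
        raise SchemaError(
            "reading NWB sessions requires the optional dependency pynwb") from exc
    from pynwb import NWBHDF5IO

    with NWBHDF5IO(str(path), "r") as io:
        nwbfile = io.read()
        lfp_series = None
        for name, acq in nwbfile.acquisition.items():
            if "lfp" in name.lower():
                lfp_series = acq
        if lfp_series is None:
            raise SchemaError("NWB file lacks an LFP series")
        raise NotImplementedError(
            "full NWB ingestion is layout-specific; convert to the fixture format")


# ---------------------------------------------------------------------------
# epoch extraction
# ---------------------------------------------------------------------------

def epoch(trace: np.ndarray, fs: float, events: np.ndarray,
          window: tuple[float, float] = EPOCH_WINDOW, *,
          channel_id: str = "ch0", region: str = "hippocampus") -> LFPEpochs:
    """Cut a continuous trace into trial epochs around event times.

    The sample at trial-relative time 0 is the one aligned to the event; the
    window is half-open, so a 3.5-s window at 400 Hz yields 1400 samples.
    Events whose window exceeds the recording are flagged invalid rather than
    raising.
    """
    trace = np.asarray(trace, dtype=float)
    events = np.atleast_1d(np.asarray(events, dtype=float))
    n_samp = int(round((window[1] - window[0]) * fs))
    out = np.zeros((len(events), n_samp))
    valid = np.ones(len(events), dtype=bool)
    for i, ev in enumerate(events):
        start = int(round((ev + window[0]) * fs))
        stop = start + n_samp
        if start < 0 or stop > trace.size:
            valid[i] = False
            continue
        out[i] = trace[start:stop]
    return LFPEpochs(channel_id=channel_id, region=region, fs=fs,
                     samples=out, window=window, valid_trials=valid)


def maintenance_slice(window: tuple[float, float], fs: float,
                      analysis: tuple[float, float] = MAINTENANCE_WINDOW) -> slice:
    """Index slice selecting the [0, 2.5) s analysis window inside an epoch."""
    i0 = int(round((analysis[0] - window[0]) * fs))
    i1 = int(round((analysis[1] - window[0]) * fs))
    return slice(i0, i1)
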