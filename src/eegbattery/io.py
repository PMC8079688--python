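"""File I/O: EDF and delimited-text recordings, event tables, hypnograms,
position traces, zone geometry and YAML analysis configuration.

EDF reading goes through MNE.  EDF *writing* is a small self-contained
implementation of the classic EDF layout (16-bit samples, 1-second data
records) sufficient for round-tripping the synthetic sessions this package
generates; amplitudes survive the round trip to within the 16-bit
quantisation step of the channel's physical range.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EventTrack, Hypnogram, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_hypnogram",
    "write_hypnogram",
    "read_positions",
    "write_positions",
    "read_zones",
    "write_zones",
    "AnalysisConfig",
]


class FormatError(ValueError):
    """File parsed but violates the expected structure."""


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(path, rec: Recording, fmt: str = "edf") -> None:
    """Write a Recording as EDF (16-bit) or as a delimited csv (exact).

    EDF uses 1-second data records; the recording is zero-padded to a whole
    number of seconds (the synthetic generators emit whole-second sessions,
    so in practice nothing is padded).
    """
    path = Path(path)
    if fmt == "csv":
        pd.DataFrame(rec.samples.T, columns=rec.channel_names).to_csv(path, index=False)
        return
    if fmt != "edf":
        raise ValueError(f"unknown format {fmt!r}")
    spr = int(round(rec.rate))
    if abs(spr - rec.rate) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_ch = len(rec.channel_names)
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.samples
    phys_max = max(1.0, float(np.max(np.abs(data)) * 1.0001))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.round((data + phys_max) * scale) + dig_min,
                      dig_min, dig_max).astype("<i2")
    header = b""
    header += _edf_ascii("0", 8)
    header += _edf_ascii("X X X X", 80)          # patient
    header += _edf_ascii("Startdate X X X X", 80)  # recording
    header += _edf_ascii("01.01.00", 8)
    header += _edf_ascii("00.00.00", 8)
    header += _edf_ascii(256 * (1 + n_ch), 8)
    header += _edf_ascii("", 44)
    header += _edf_ascii(n_rec, 8)
    header += _edf_ascii(1, 8)                   # record duration, s
    header += _edf_ascii(n_ch, 4)
    for name in rec.channel_names:
        header += _edf_ascii(name, 16)
    header += b"".join(_edf_ascii("EEG electrode", 80) for _ in range(n_ch))
    header += b"".join(_edf_ascii("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_ascii(f"{-phys_max:.6g}", 8) for _ in range(n_ch))
    header += b"".join(_edf_ascii(f"{phys_max:.6g}", 8) for _ in range(n_ch))
    header += b"".join(_edf_ascii(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_edf_ascii(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_ascii("", 80) for _ in range(n_ch))
    header += b"".join(_edf_ascii(spr, 8) for _ in range(n_ch))
    header += b"".join(_edf_ascii("", 32) for _ in range(n_ch))
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(digital[ch, r * spr : (r + 1) * spr].tobytes())


def read_recording(path, fmt: str | None = None, rate: float | None = None) -> Recording:
    """Read continuous EEG from EDF (header rate) or csv (``rate`` required)."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "edf":
        import mne

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # noqa: BLE001 - normalise reader failures
            raise FormatError(f"unreadable EDF file {path}: {exc}") from exc
        if len(raw.ch_names) == 0:
            raise FormatError("EDF file contains zero channels")
        data = raw.get_data(units="uV")
        return Recording(samples=data, rate=float(raw.info["sfreq"]),
                         channel_names=list(raw.ch_names))
    if fmt == "csv":
        if rate is None or rate <= 0:
            raise FormatError("csv recordings require a positive configured rate")
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"unreadable csv recording {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError("csv recording has zero channels")
        return Recording(samples=df.to_numpy().T, rate=rate,
                         channel_names=[str(c) for c in df.columns])
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def write_events(path, events: EventTrack) -> None:
    events.events.to_csv(path, index=False)


def read_events(path) -> EventTrack:
    return EventTrack(pd.read_csv(path))


def write_hypnogram(path, hyp: Hypnogram) -> None:
    pd.DataFrame({
        "epoch_index": np.arange(hyp.states.size),
        "state": hyp.states,
        "period": hyp.periods,
    }).to_csv(path, index=False)


def read_hypnogram(path, epoch_length: float = 10.0) -> Hypnogram:
    df = pd.read_csv(path)
    for col in ("epoch_index", "state", "period"):
        if col not in df.columns:
            raise FormatError(f"hypnogram missing column {col!r}")
    df = df.sort_values("epoch_index")
    return Hypnogram(states=df["state"].to_numpy(), epoch_length=epoch_length,
                     periods=df["period"].to_numpy())


def write_positions(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_positions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("t_s", "x_cm", "y_cm"):
        if col not in df.columns:
            raise FormatError(f"positions missing column {col!r}")
    return df


def write_zones(path, zones: dict) -> None:
    with open(path, "w") as fh:
        json.dump(zones, fh, indent=2)


def read_zones(path) -> dict:
    with open(path) as fh:
        zones = json.load(fh)
    if "chambers" not in zones or "cages" not in zones:
        raise FormatError("zones JSON needs 'chambers' and 'cages'")
    return zones


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "low_gamma": (25.0, 58.0),
    "evoked_gamma": (30.0, 80.0),
    "spindle": (9.0, 16.0),
}


@dataclass
class AnalysisConfig:
    """Battery configuration: bands, windows, estimator parameters, paths.

    Defaults mirror the battery's analysis conventions; any field can be
    overridden from YAML.  ``paths`` names the per-stage input files and
    ``stages`` lists the biomarkers a battery run should compute.
    """

    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    channel: str = "frontal"
    seed: int = 0
    multitaper_nw: float = 3.0
    multitaper_k: int = 5
    morlet_cycles: float = 7.0
    # social-gamma inclusion rules (seconds)
    min_investigation_gap: float = 5.0
    min_investigation_duration: float = 1.0
    # optional amplitude-threshold epoch rejection (uV); off by default
    artifact_threshold_uv: float | None = None
    gating_s1_time: float = 1.0     # epoch-local S1 onset
    gating_isi: float = 0.5
    assr_f0: float = 40.0
    spindle_threshold_sd: float = 2.5
    hypnogram_epoch_s: float = 10.0
    stages: list = field(default_factory=list)
    paths: dict = field(default_factory=dict)
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} has low >= high")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["bands"] = {k: list(v) for k, v in d["bands"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)
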