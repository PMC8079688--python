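"""Domain types and epoch extraction.

Conventions used everywhere in the package:

* time is in seconds with t = 0 at the start of the recording;
* amplitudes are in microvolts;
* intervals are half-open [start, end) and the sample holding time t is
  ``floor(t * rate)``;
* epoch-local time starts at 0 at the first sample of the epoch, so an epoch
  cut with ``window=(pre, post)`` has its event onset at epoch-local ``pre``
  seconds (``EpochSet.event_time``).  For the paired-tone task this puts S1
  at 1.0 s when epochs are cut with a 1 s pre-window, making the published
  scoring windows (1-1.05 s, 1.5-1.55 s) literal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EventTrack",
    "EpochSet",
    "Hypnogram",
    "extract_epochs",
    "sample_index",
]

STATE_ALPHABET = ("wake", "NREM", "REM")


def sample_index(t: float, rate: float) -> int:
    """Index of the sample holding time ``t``: floor(t * rate)."""
    return int(np.floor(t * rate + 1e-9))


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts.

    ``samples`` is (n_channels, n_samples); all channels share ``rate`` (Hz)
    and length.  ``start_time`` anchors t = 0 (seconds).
    """

    samples: np.ndarray
    rate: float
    channel_names: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match sample rows")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.samples[idx]


@dataclass
class EventTrack:
    """Timestamped labeled events: columns onset_s, duration_s, label, block."""

    events: pd.DataFrame

    COLUMNS = ("onset_s", "duration_s", "label", "block")

    def __post_init__(self) -> None:
        df = self.events
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"event table missing columns {sorted(missing)}")
        if np.any(np.diff(df["onset_s"].to_numpy()) < 0):
            raise ValueError("event onsets must be non-decreasing")
        if (df["duration_s"] < 0).any():
            raise ValueError("event durations must be >= 0")
        self.events = df.reset_index(drop=True)

    @classmethod
    def from_lists(cls, onsets, durations, labels, blocks=None) -> "EventTrack":
        n = len(onsets)
        return cls(pd.DataFrame({
            "onset_s": np.asarray(onsets, float),
            "duration_s": np.asarray(durations, float),
            "label": list(labels),
            "block": np.asarray(blocks if blocks is not None else np.arange(n)),
        }))

    def select(self, label: str) -> pd.DataFrame:
        return self.events[self.events["label"] == label].reset_index(drop=True)

    def labels(self) -> list[str]:
        return sorted(self.events["label"].unique())

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class EpochSet:
    """Time-locked trial matrix (trials x samples, uV).

    ``time`` is the epoch-local axis starting at 0; ``event_time`` is the
    epoch-local instant of the event onset the epochs are locked to.
    """

    data: np.ndarray
    rate: float
    event_time: float
    baseline_window: tuple[float, float] | None = None
    event_labels: list = field(default_factory=list)
    event_onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.data.shape[0] < 1:
            raise ValueError("EpochSet needs at least one trial")
        if self.baseline_window is not None:
            b0, b1 = self.baseline_window
            if not (0 <= b0 < b1 <= self.data.shape[1] / self.rate):
                raise ValueError("baseline window must lie inside the epoch")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.rate

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class Hypnogram:
    """Vigilance state per fixed-length scoring epoch, with lighting period."""

    states: np.ndarray
    epoch_length: float
    periods: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        bad = set(self.states) - set(STATE_ALPHABET)
        if bad:
            raise ValueError(f"unknown states {sorted(bad)}; expected {STATE_ALPHABET}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.periods is None:
            self.periods = np.asarray(["light"] * self.states.size, dtype=object)
        else:
            self.periods = np.asarray(self.periods, dtype=object)
            if self.periods.size != self.states.size:
                raise ValueError("periods must match states length")

    @property
    def duration(self) -> float:
        return self.states.size * self.epoch_length

    def state_mask(self, rate: float, n_samples: int, state: str,
                   period: str | None = None) -> np.ndarray:
        """Boolean per-sample mask of a vigilance state (optionally one period)."""
        mask = np.zeros(n_samples, dtype=bool)
        for i, s in enumerate(self.states):
            if s != state:
                continue
            if period is not None and self.periods[i] != period:
                continue
            a = sample_index(i * self.epoch_length, rate)
            b = min(sample_index((i + 1) * self.epoch_length, rate), n_samples)
            mask[a:b] = True
        return mask

    def intervals(self, state: str, period: str | None = None) -> list[tuple[float, float]]:
        """Merged [start, end) intervals (seconds) of contiguous state epochs."""
        out: list[tuple[float, float]] = []
        for i, s in enumerate(self.states):
            if s != state or (period is not None and self.periods[i] != period):
                continue
            t0, t1 = i * self.epoch_length, (i + 1) * self.epoch_length
            if out and abs(out[-1][1] - t0) < 1e-9:
                out[-1] = (out[-1][0], t1)
            else:
                out.append((t0, t1))
        return out

    def bout_summary(self, period: str | None = None) -> pd.DataFrame:
        """Run-length bout statistics per state: percent time, mean bout, rate."""
        if period is None:
            keep = np.ones(self.states.size, bool)
        else:
            keep = self.periods == period
        states = self.states[keep]
        total = states.size * self.epoch_length
        rows = []
        # run-length encode
        bouts: dict[str, list[float]] = {s: [] for s in STATE_ALPHABET}
        i = 0
        while i < states.size:
            j = i
            while j < states.size and states[j] == states[i]:
                j += 1
            bouts[states[i]].append((j - i) * self.epoch_length)
            i = j
        for s in STATE_ALPHABET:
            b = bouts[s]
            time_in = float(sum(b))
            rows.append({
                "state": s,
                "percent_time": 100.0 * time_in / total if total else np.nan,
                "n_bouts": len(b),
                "mean_bout_s": float(np.mean(b)) if b else np.nan,
                "bouts_per_hour": len(b) / (total / 3600.0) if total else np.nan,
            })
        return pd.DataFrame(rows)


class EmptySelectionError(ValueError):
    """No events survived selection/edge rules."""


def extract_epochs(
    rec: Recording,
    events: EventTrack,
    label: str,
    window: tuple[float, float],
    channel: str,
    baseline_window: tuple[float, float] | None = None,
) -> EpochSet:
    """Cut fixed-length epochs around every event with the given label.

    ``window=(pre_s, post_s)`` spans [onset - pre, onset + post); events whose
    full window falls outside the recording are dropped (and counted in the
    log).  Epoch samples are exact copies of the recording samples.
    """
    pre, post = window
    if pre + post <= 0:
        raise ValueError("window must span a positive duration")
    sel = events.select(label)
    if len(sel) == 0:
        raise EmptySelectionError(f"no events labeled {label!r}")
    sig = rec.channel(channel)
    n_len = int(round((pre + post) * rec.rate))
    rows, labels, onsets = [], [], []
    dropped = 0
    for _, ev in sel.iterrows():
        t0 = ev["onset_s"] - rec.start_time
        a = sample_index(t0 - pre, rec.rate)
        b = a + n_len
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        rows.append(sig[a:b])
        labels.append(ev["label"])
        onsets.append(ev["onset_s"])
    if dropped:
        logger.info("extract_epochs: dropped %d/%d %r events at record edges",
                    dropped, len(sel), label)
    if not rows:
        raise EmptySelectionError(
            f"all {len(sel)} {label!r} events fall outside the recording"
        )
    return EpochSet(
        data=np.vstack(rows), rate=rec.rate, event_time=pre,
        baseline_window=baseline_window, event_labels=labels,
        event_onsets=np.asarray(onsets),
    )
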