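"""Social-investigation gamma pipeline and three-chamber behaviour scoring.

Elicited gamma: epochs of [-4, +4] s around each investigation onset are
Morlet-transformed, normalised per epoch to the 4 s pre-onset baseline, and
the 25-58 Hz band mean is reported in two post-onset bins ([0, 0.5) and
[0.5, 1.0) s).  Background gamma: multitaper PSD of each [-4, 0) s
pre-investigation window, with 25-58 Hz power expressed as percent of the
1-100 Hz total.  The inverse relation between the two is quantified with the
repeated-measures correlation across investigations (subject as the repeated
factor).

Investigations are filtered before analysis: a minimum duration and a
minimum gap since the previous investigation's end guarantee that no other
investigation contaminates the baseline window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .core import EventTrack, Recording, extract_epochs
from .spectral import (
    TimeFrequencyMap,
    morlet_tfr,
    multitaper_psd,
    normalize_percent_baseline,
    percent_of_total_power,
)
from .stats import RmcorrResult, rmcorr

logger = logging.getLogger(__name__)

__all__ = [
    "filter_investigations",
    "elicited_gamma_timecourse",
    "background_gamma",
    "elicited_vs_background_correlation",
    "grand_average_spectrogram",
    "score_three_chamber",
]

GAMMA_BAND = (25.0, 58.0)
BINS = ((0.0, 0.5), (0.5, 1.0))  # s post-onset


def filter_investigations(
    events: EventTrack,
    label: str,
    min_duration: float = 1.0,
    min_gap: float = 5.0,
) -> pd.DataFrame:
    """Investigations passing the inclusion rules.

    Kept events last at least ``min_duration`` s and start at least
    ``min_gap`` s after the previous same-label investigation ended, so the
    4 s baseline window cannot overlap a prior investigation when
    ``min_gap >= 4``.
    """
    sel = events.select(label)
    keep = []
    prev_end = -np.inf
    for _, ev in sel.iterrows():
        ok = ev["duration_s"] >= min_duration and ev["onset_s"] - prev_end >= min_gap
        if ok:
            keep.append(ev)
        prev_end = ev["onset_s"] + ev["duration_s"]
    if len(keep) < len(sel):
        logger.info("filter_investigations: %d/%d %r events excluded",
                    len(sel) - len(keep), len(sel), label)
    return pd.DataFrame(keep).reset_index(drop=True)


def _epochs_from_filtered(rec: Recording, filtered: pd.DataFrame, channel: str):
    track = EventTrack(filtered.assign(block=np.arange(len(filtered)))
                       if "block" not in filtered else filtered)
    return extract_epochs(rec, track, filtered["label"].iloc[0],
                          window=(4.0, 4.0), channel=channel)


def elicited_gamma_timecourse(
    rec: Recording,
    events: EventTrack,
    label: str = "investigation_novel",
    band: tuple[float, float] = GAMMA_BAND,
    channel: str = "frontal",
    subject: str = "s1",
    group: str = "WT",
    min_duration: float = 1.0,
    min_gap: float = 5.0,
    cycles: float = 7.0,
    decim: int = 10,
    return_maps: bool = False,
):
    """Per-investigation elicited gamma (% of 4 s baseline) in 0.5 s bins.

    Returns a long DataFrame with one row per (investigation, bin); with
    ``return_maps`` also the per-epoch percent-baseline maps for grand
    averaging.
    """
    filtered = filter_investigations(events, label, min_duration, min_gap)
    if len(filtered) == 0:
        raise ValueError(f"no {label!r} investigations survive the inclusion rules")
    epochs = _epochs_from_filtered(rec, filtered, channel)
    freqs = np.arange(band[0], band[1] + 1e-9, 2.0)
    raw = morlet_tfr(epochs, freqs=freqs, cycles=cycles, decim=decim, keep_phase=False)
    norm = normalize_percent_baseline(raw, baseline=(0.0, epochs.event_time))
    rows = []
    maps = []
    t = norm.times - epochs.event_time  # onset-relative
    for i in range(epochs.n_trials):
        for b0, b1 in BINS:
            tmask = (t >= b0) & (t < b1)
            val = float(norm.power[i][:, tmask].mean())
            rows.append({"subject": subject, "group": group, "label": label,
                         "investigation": i, "bin_start_s": b0, "bin_end_s": b1,
                         "elicited_pct_baseline": val})
        if return_maps:
            maps.append(replace(norm, power=norm.power[i], phase=None))
    df = pd.DataFrame(rows)
    return (df, maps) if return_maps else df


def background_gamma(
    rec: Recording,
    events: EventTrack,
    label: str = "investigation_novel",
    band: tuple[float, float] = GAMMA_BAND,
    total: tuple[float, float] = (1.0, 100.0),
    channel: str = "frontal",
    subject: str = "s1",
    group: str = "WT",
    min_duration: float = 1.0,
    min_gap: float = 5.0,
    nw: float = 3.0,
    k: int = 5,
) -> pd.DataFrame:
    """Pre-investigation 25-58 Hz power as percent of 1-100 Hz total power."""
    filtered = filter_investigations(events, label, min_duration, min_gap)
    if len(filtered) == 0:
        raise ValueError(f"no {label!r} investigations survive the inclusion rules")
    epochs = _epochs_from_filtered(rec, filtered, channel)
    pre = int(round(epochs.event_time * epochs.rate))
    rows = []
    for i in range(epochs.n_trials):
        psd = multitaper_psd(epochs.data[i, :pre], epochs.rate, nw=nw, k=k)
        pct = percent_of_total_power(psd, band, total).value
        rows.append({"subject": subject, "group": group, "label": label,
                     "investigation": i, "background_pct_total": pct})
    return pd.DataFrame(rows)


def elicited_vs_background_correlation(
    elicited: pd.DataFrame,
    background: pd.DataFrame,
    min_obs_per_subject: int = 3,
) -> RmcorrResult:
    """Repeated-measures correlation between background and elicited gamma.

    Elicited gamma per investigation is the mean over the two post-onset
    bins (the analysed first second).  Investigations are matched on
    (subject, investigation); subjects with fewer than
    ``min_obs_per_subject`` matched observations are dropped with a warning.
    """
    el = (elicited.groupby(["subject", "investigation"], as_index=False)
          ["elicited_pct_baseline"].mean())
    merged = el.merge(background[["subject", "investigation", "background_pct_total"]],
                      on=["subject", "investigation"], validate="one_to_one")
    counts = merged.groupby("subject")["investigation"].count()
    small = counts[counts < min_obs_per_subject].index.tolist()
    if small:
        warnings.warn(f"dropping subjects with < {min_obs_per_subject} investigations: {small}")
        merged = merged[~merged["subject"].isin(small)]
    if merged["subject"].nunique() < 2:
        raise ValueError("rmcorr needs at least 2 subjects after filtering")
    return rmcorr(merged.rename(columns={
        "background_pct_total": "x", "elicited_pct_baseline": "y"}))


def grand_average_spectrogram(maps: list[TimeFrequencyMap]) -> TimeFrequencyMap:
    """Elementwise mean of per-epoch percent-baseline maps pooled over animals."""
    if not maps:
        raise ValueError("no maps to average")
    ref = maps[0]
    for m in maps[1:]:
        if m.normalization != ref.normalization:
            raise ValueError("mixed normalisations in grand average")
        if not (np.array_equal(m.freqs, ref.freqs) and np.array_equal(m.times, ref.times)):
            raise ValueError("maps must share frequency and time axes")
    if ref.normalization != "percent_baseline":
        raise ValueError("grand averages expect percent_baseline maps")
    stack = np.stack([m.average().power for m in maps])
    return replace(ref, power=stack.mean(axis=0), phase=None)


# ---------------------------------------------------------------------------
# Three-chamber behaviour
# ---------------------------------------------------------------------------

def score_three_chamber(
    positions: pd.DataFrame,
    zones: dict,
    zone_radius_cm: float = 5.0,
) -> dict:
    """Chamber occupancy, 5 cm zone entries, ratios, distance and velocity.

    ``positions`` has columns t_s, x_cm, y_cm at a fixed sampling rate.
    ``zones`` is {'chambers': {name: [[x, y], ...] polygon}, 'cages':
    {name: [x, y] centre}}.  An entry is an outside-to-inside transition of
    the circle of ``zone_radius_cm`` around a cage centre.  Points outside
    every chamber are logged and excluded from the occupancy percentages.
    """
    t = positions["t_s"].to_numpy(float)
    xy = positions[["x_cm", "y_cm"]].to_numpy(float)
    polys = {name: Polygon(v) for name, v in zones["chambers"].items()}
    arena = None
    for p in polys.values():
        arena = p if arena is None else arena.union(p)
    in_chamber = {name: np.array([poly.covers(Point(p)) for p in xy])
                  for name, poly in polys.items()}
    anywhere = np.logical_or.reduce(list(in_chamber.values()))
    n_out = int((~anywhere).sum())
    if n_out:
        logger.info("score_three_chamber: %d/%d positions outside all chambers",
                    n_out, len(xy))
    n_in = max(int(anywhere.sum()), 1)
    pct_time = {name: 100.0 * mask.sum() / n_in for name, mask in in_chamber.items()}

    entries = {}
    for name, centre in zones["cages"].items():
        d = np.hypot(xy[:, 0] - centre[0], xy[:, 1] - centre[1])
        inside = d <= zone_radius_cm
        entries[name] = int(np.sum(inside[1:] & ~inside[:-1]) + int(inside[0]))

    steps = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    distance = float(steps.sum())
    total_t = float(t[-1] - t[0]) if t.size > 1 else np.nan
    return {
        "percent_time": pct_time,
        "entries": entries,
        "distance_cm": distance,
        "mean_velocity_cm_s": distance / total_t if total_t else np.nan,
        "n_outside": n_out,
    }


def preference_ratio(metrics: dict, target: str, reference: str) -> dict:
    """novel/object- or novel/familiar-style ratios for time and entries."""
    out = {}
    pt = metrics["percent_time"]
    en = metrics["entries"]
    out["time_ratio"] = pt[target] / pt[reference] if pt.get(reference) else np.nan
    out["entry_ratio"] = en[target] / en[reference] if en.get(reference) else np.nan
    return out
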