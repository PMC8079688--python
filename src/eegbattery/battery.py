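"""Battery orchestration: run the configured biomarker stages over a
session's files and collect one long-format report.

Each stage reads its inputs from ``config.paths``, runs the corresponding
pipeline module, writes a per-stage table, and appends rows to the combined
BiomarkerReport.  Runs are deterministic given the config (all randomness in
the battery lives in the simulators, which take explicit seeds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assr_sleep, gating, social
from .core import EventTrack, Recording, extract_epochs
from .io import AnalysisConfig, read_events, read_hypnogram, read_recording

logger = logging.getLogger(__name__)

__all__ = ["BiomarkerReport", "run_battery", "ConfigurationError"]


class ConfigurationError(ValueError):
    """A requested stage is missing a required input."""


@dataclass
class BiomarkerReport:
    """Long-format biomarker rows; unique on (subject, biomarker, condition, time_bin)."""

    rows: pd.DataFrame

    COLUMNS = ("subject", "group", "biomarker", "condition", "time_bin", "value", "units")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"report missing columns {sorted(missing)}")
        key = ["subject", "biomarker", "condition", "time_bin"]
        if self.rows.duplicated(subset=key).any():
            raise ValueError("duplicate (subject, biomarker, condition, time_bin) keys")

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.10g")


def _require(config: AnalysisConfig, stage: str, *keys: str) -> list:
    vals = []
    for key in keys:
        if key not in config.paths:
            raise ConfigurationError(
                f"stage {stage!r} requires config.paths[{key!r}]"
            )
        vals.append(config.paths[key])
    return vals


def _rows(subject, group, biomarker, condition, pairs, units) -> list[dict]:
    return [{"subject": subject, "group": group, "biomarker": biomarker,
             "condition": condition, "time_bin": tb, "value": v, "units": units}
            for tb, v in pairs]


def run_battery(config: AnalysisConfig, subject: str = "s1", group: str = "WT") -> BiomarkerReport:
    """Run every stage in ``config.stages`` and return the combined report."""
    if not config.stages:
        raise ConfigurationError("config.stages is empty: nothing to run")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise ConfigurationError(f"unknown stage {stage!r}")
        logger.info("battery: running stage %r", stage)
        stage_rows = fn(config, subject, group, out_dir)
        rows.extend(stage_rows)
    report = BiomarkerReport(pd.DataFrame(rows, columns=list(BiomarkerReport.COLUMNS)))
    report.to_csv(out_dir / "biomarker_report.csv")
    return report


def _load_session(config: AnalysisConfig, stage: str) -> tuple[Recording, EventTrack]:
    rec_path, ev_path = _require(config, stage, f"{stage}_recording", f"{stage}_events")
    rec = read_recording(rec_path)
    return rec, read_events(ev_path)


def _stage_gating(config, subject, group, out_dir) -> list[dict]:
    rec, events = _load_session(config, "gating")
    epochs = extract_epochs(rec, events, "tone_S1",
                            window=(config.gating_s1_time, 4.0),
                            channel=config.channel)
    erp = gating.average_erp(epochs)
    c1 = gating.score_erp_components(erp, tone_onset=config.gating_s1_time)
    c2 = gating.score_erp_components(erp, tone_onset=config.gating_s1_time + config.gating_isi)
    gg = gating.evoked_power_gating(epochs, band=config.bands["evoked_gamma"],
                                    isi=config.gating_isi)
    pairs = []
    for comp in ("P20", "N40", "P20_N40"):
        m = gating.gating_metrics(c1, c2, comp)
        pairs += [(f"{comp}_s1", c1.amplitude(comp)), (f"{comp}_s2", c2.amplitude(comp)),
                  (f"{comp}_s2_over_s1", m.s2_over_s1), (f"{comp}_s1_minus_s2", m.s1_minus_s2)]
    pairs += [("evoked_gamma_s1", gg.evoked_power_s1),
              ("evoked_gamma_s2", gg.evoked_power_s2),
              ("evoked_gamma_pct_reduction", gg.percent_reduction)]
    df = pd.DataFrame(pairs, columns=["metric", "value"])
    df.to_csv(out_dir / "gating.csv", index=False, float_format="%.10g")
    return _rows(subject, group, "gating", "paired_tones", pairs, "mixed")


def _stage_social_gamma(config, subject, group, out_dir) -> list[dict]:
    rec, events = _load_session(config, "social")
    out = []
    for label in sorted(set(events.events["label"])):
        el = social.elicited_gamma_timecourse(
            rec, events, label=label, band=config.bands["low_gamma"],
            channel=config.channel, subject=subject, group=group,
            min_duration=config.min_investigation_duration,
            min_gap=config.min_investigation_gap)
        bg = social.background_gamma(
            rec, events, label=label, band=config.bands["low_gamma"],
            channel=config.channel, subject=subject, group=group,
            min_duration=config.min_investigation_duration,
            min_gap=config.min_investigation_gap,
            nw=config.multitaper_nw, k=config.multitaper_k)
        el.to_csv(out_dir / f"elicited_gamma_{label}.csv", index=False,
                  float_format="%.10g")
        bg.to_csv(out_dir / f"background_gamma_{label}.csv", index=False,
                  float_format="%.10g")
        mean_bins = el.groupby("bin_start_s")["elicited_pct_baseline"].mean()
        out += _rows(subject, group, "elicited_gamma", label,
                     [(f"{b:g}-{b + 0.5:g}s", v) for b, v in mean_bins.items()],
                     "%baseline")
        out += _rows(subject, group, "background_gamma", label,
                     [("pre_-4-0s", bg["background_pct_total"].mean())], "%total")
    return out


def _stage_assr(config, subject, group, out_dir) -> list[dict]:
    rec, events = _load_session(config, "assr")
    epochs = extract_epochs(rec, events, "assr_train", window=(1.0, 2.0),
                            channel=config.channel)
    m = assr_sleep.assr_metrics(epochs, f0=config.assr_f0)
    pairs = [("evoked_power", m.evoked_power), ("induced_power", m.induced_power),
             ("total_power", m.total_power), ("plf", m.plf)]
    pd.DataFrame(pairs, columns=["metric", "value"]).to_csv(
        out_dir / "assr.csv", index=False, float_format="%.10g")
    return _rows(subject, group, "assr", f"{config.assr_f0:g}Hz", pairs, "mixed")


def _stage_spindles(config, subject, group, out_dir) -> list[dict]:
    rec_path, hyp_path = _require(config, "spindles", "sleep_recording", "sleep_hypnogram")
    rec = read_recording(rec_path)
    hyp = read_hypnogram(hyp_path, epoch_length=config.hypnogram_epoch_s)
    st = assr_sleep.detect_spindles(rec, hyp, channel=config.channel,
                                    band=config.bands["spindle"],
                                    threshold_sd=config.spindle_threshold_sd)
    st.events.to_csv(out_dir / "spindle_events.csv", index=False,
                     float_format="%.10g")
    pairs = [("density_per_min", st.density_per_min),
             ("mean_amplitude", st.mean_amplitude_uV),
             ("mean_duration", st.mean_duration_s),
             ("median_duration", st.median_duration_s),
             ("median_frequency", st.median_frequency_hz)]
    return _rows(subject, group, "spindles", "NREM", pairs, "mixed")


def _stage_state_psd(config, subject, group, out_dir) -> list[dict]:
    rec_path, hyp_path = _require(config, "state-psd", "sleep_recording", "sleep_hypnogram")
    rec = read_recording(rec_path)
    hyp = read_hypnogram(hyp_path, epoch_length=config.hypnogram_epoch_s)
    out = []
    for period in sorted(set(hyp.periods)):
        res = assr_sleep.state_psd(rec, hyp, period=period, channel=config.channel,
                                   nw=config.multitaper_nw, k=config.multitaper_k)
        bouts = res.pop("bouts")
        bouts.to_csv(out_dir / f"bouts_{period}.csv", index=False,
                     float_format="%.10g")
        for state, sp in res.items():
            np.savetxt(out_dir / f"psd_{period}_{state}.csv",
                       np.column_stack([sp.psd.freqs, sp.psd.power]),
                       delimiter=",", header="freq_hz,power_uV2_per_hz")
            for band_name, band in config.bands.items():
                lo, hi = band
                mask = (sp.psd.freqs >= lo) & (sp.psd.freqs <= hi)
                out += _rows(subject, group, "state_psd", f"{period}_{state}",
                             [(band_name, float(sp.psd.power[mask].mean()))],
                             "uV^2/Hz")
        for _, b in bouts.iterrows():
            out += _rows(subject, group, "sleep_architecture",
                         f"{period}_{b['state']}",
                         [("percent_time", b["percent_time"]),
                          ("mean_bout_s", b["mean_bout_s"]),
                          ("bouts_per_hour", b["bouts_per_hour"])], "mixed")
    return out


_STAGES = {
    "gating": _stage_gating,
    "social-gamma": _stage_social_gamma,
    "assr": _stage_assr,
    "spindles": _stage_spindles,
    "state-psd": _stage_state_psd,
}
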