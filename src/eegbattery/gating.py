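"""Paired-tone sensory-gating pipeline.

Per subject: average the ~100 paired-tone epochs into an ERP (100 ms
pre-stimulus baseline correction), score the P20 (max positive deflection
15-30 ms post-tone) and N40 (max negative deflection 25-55 ms) components for
S1 and for S2 (offset by the 500 ms inter-stimulus interval within the same
epoch), and form the gating metrics S2/S1 and S1-S2.  A parallel gating
measure uses evoked gamma power (30-80 Hz): Morlet power of the trial-averaged
waveform in the two 50 ms stimulus windows.

Epochs are expected to be locked to S1 with a 1 s pre-window, so S1 sits at
epoch-local 1.0 s and the stimulus windows are 1-1.05 s and 1.5-1.55 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSet
from .spectral import PsdBins, band_power, bin_psd_1hz_log, morlet_tfr

__all__ = [
    "ErpWaveform",
    "ErpComponents",
    "GatingMetrics",
    "GammaGating",
    "average_erp",
    "score_erp_components",
    "gating_metrics",
    "evoked_power_gating",
    "stimulus_psd_profile",
    "P20_WINDOW",
    "N40_WINDOW",
]

P20_WINDOW = (0.015, 0.030)  # s post-tone, endpoints inclusive
N40_WINDOW = (0.025, 0.055)


@dataclass
class ErpWaveform:
    values: np.ndarray
    rate: float
    n_trials: int
    baseline_window: tuple[float, float]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


@dataclass
class ErpComponents:
    p20: float
    n40: float
    p20_latency: float
    n40_latency: float

    @property
    def p20_n40(self) -> float:
        return self.p20 - self.n40

    def amplitude(self, component: str) -> float:
        """Signed-magnitude amplitude used for gating ratios/differences.

        P20 and P20_N40 are positive quantities as scored; N40 is reported
        as its magnitude so that S2/S1 and S1-S2 carry the same sense
        (smaller S2 response -> ratio < 1, difference > 0) for all three.
        """
        if component == "P20":
            return self.p20
        if component == "N40":
            return -self.n40
        if component == "P20_N40":
            return self.p20_n40
        raise ValueError(f"unknown component {component!r}")


@dataclass
class GatingMetrics:
    component: str
    s2_over_s1: float
    s1_minus_s2: float


@dataclass
class GammaGating:
    evoked_power_s1: float
    evoked_power_s2: float
    band: tuple[float, float]

    @property
    def percent_reduction(self) -> float:
        return 100.0 * (1.0 - self.evoked_power_s2 / self.evoked_power_s1)


def average_erp(epochs: EpochSet, baseline: tuple[float, float] | None = None) -> ErpWaveform:
    """Trial-average ERP after per-trial baseline-mean subtraction.

    Default baseline: the 100 ms immediately before the event onset.
    """
    if baseline is None:
        baseline = (epochs.event_time - 0.1, epochs.event_time)
    b0, b1 = baseline
    t = epochs.time
    if not (t[0] <= b0 < b1 <= t[-1] + 1.0 / epochs.rate):
        raise ValueError(f"baseline window {baseline} outside epoch")
    mask = (t >= b0) & (t < b1)
    if not mask.any():
        raise ValueError("empty baseline window")
    corrected = epochs.data - epochs.data[:, mask].mean(axis=1, keepdims=True)
    return ErpWaveform(values=corrected.mean(axis=0), rate=epochs.rate,
                       n_trials=epochs.n_trials, baseline_window=baseline)


def score_erp_components(erp: ErpWaveform, tone_onset: float) -> ErpComponents:
    """Score P20 (max, 15-30 ms) and N40 (min, 25-55 ms) after ``tone_onset``.

    Peaks are extremal samples (no fitting); ties break to the earliest
    sample; window endpoints are inclusive at sample resolution.
    """
    t = erp.time
    eps = 0.25 / erp.rate
    out = {}
    for name, (lo, hi), func in (("p20", P20_WINDOW, np.argmax), ("n40", N40_WINDOW, np.argmin)):
        mask = (t >= tone_onset + lo - eps) & (t <= tone_onset + hi + eps)
        if not mask.any() or t[mask][-1] < tone_onset + hi - 1.0 / erp.rate:
            raise ValueError(f"{name} window extends past the epoch end")
        idx = np.flatnonzero(mask)
        k = idx[func(erp.values[idx])]
        out[name] = (float(erp.values[k]), float(t[k] - tone_onset))
    return ErpComponents(p20=out["p20"][0], n40=out["n40"][0],
                         p20_latency=out["p20"][1], n40_latency=out["n40"][1])


def gating_metrics(c1: ErpComponents, c2: ErpComponents, component: str = "P20_N40") -> GatingMetrics:
    """S2/S1 ratio and S1-S2 difference for one ERP component."""
    a1 = c1.amplitude(component)
    a2 = c2.amplitude(component)
    if a1 == 0.0:
        raise ZeroDivisionError(f"S1 {component} amplitude is zero; ratio undefined")
    return GatingMetrics(component=component, s2_over_s1=a2 / a1, s1_minus_s2=a1 - a2)


def evoked_power_gating(
    epochs: EpochSet,
    band: tuple[float, float] = (30.0, 80.0),
    s1_window: tuple[float, float] | None = None,
    s2_window: tuple[float, float] | None = None,
    isi: float = 0.5,
    stim_duration: float = 0.05,
    cycles: float = 7.0,
) -> GammaGating:
    """Evoked gamma gating: band power of the trial average per 50 ms window.

    "Evoked" means average-then-transform: the Morlet TFR is taken of the
    baseline-corrected trial-averaged waveform, so non-phase-locked activity
    cancels before the power estimate.
    """
    if s1_window is None:
        s1_window = (epochs.event_time, epochs.event_time + stim_duration)
    if s2_window is None:
        s2_window = (s1_window[0] + isi, s1_window[1] + isi)
    erp = average_erp(epochs)
    freqs = np.arange(band[0], band[1] + 1.0, 2.0)
    tfm = morlet_tfr(erp.values[None, :], rate=erp.rate, freqs=freqs,
                     cycles=cycles, keep_phase=False)
    p1 = band_power(tfm, band, s1_window).value
    p2 = band_power(tfm, band, s2_window).value
    if p1 <= 0:
        raise ZeroDivisionError("degenerate S1 evoked power")
    return GammaGating(evoked_power_s1=p1, evoked_power_s2=p2, band=band)


def stimulus_psd_profile(
    epochs: EpochSet,
    window: tuple[float, float] | None = None,
    baseline: tuple[float, float] | None = None,
    range_hz: tuple[float, float] = (0.5, 100.5),
) -> PsdBins:
    """1 Hz-binned log10 profile of evoked power: stimulus vs pre-stimulus.

    The trial average is Morlet-transformed on a 1 Hz grid (cycle count
    tapered at low frequencies so the wavelets fit the epoch); each bin is
    log10(mean power in the stimulus window / mean power in the baseline
    window).  Defaults: the 50 ms S1 window and the 500 ms immediately
    before the tone.
    """
    if window is None:
        window = (epochs.event_time, epochs.event_time + 0.05)
    if baseline is None:
        baseline = (epochs.event_time - 0.5, epochs.event_time)
    erp = average_erp(epochs)
    lo, hi = range_hz
    freqs = np.arange(lo + 0.5, hi, 1.0)  # bin centres, 1 Hz apart
    epoch_len = erp.values.size / erp.rate
    # taper the cycle count at low frequencies so every wavelet (support
    # ~ 10 cycles / (2 pi f)) fits inside the epoch
    cycles = np.minimum(7.0, np.maximum(1.0, 0.5 * freqs * epoch_len))
    tfm = morlet_tfr(erp.values[None, :], rate=erp.rate, freqs=freqs,
                     cycles=cycles, keep_phase=False, decim=4)
    t = tfm.times
    wmask = (t >= window[0]) & (t < window[1])
    bmask = (t >= baseline[0]) & (t < baseline[1])
    if not wmask.any() or not bmask.any():
        raise ValueError("stimulus or baseline window outside epoch")
    pw = tfm.power[0][:, wmask].mean(axis=1)
    pb = tfm.power[0][:, bmask].mean(axis=1)
    return bin_psd_1hz_log(freqs, pw, pb, range_hz=range_hz)
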