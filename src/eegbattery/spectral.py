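"""Spectral estimators shared by every biomarker.

Two estimators cover the battery: a multitaper PSD (DPSS eigenspectra,
averaged) for stationary windows such as pre-investigation baselines and
vigilance-state spectra, and a complex Morlet wavelet transform for
time-resolved power and phase around events.  On top of these sit the
normalisations the biomarkers are defined in terms of: percent-of-baseline,
percent-of-total-power, and the 1 Hz-binned log10-normalised spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import dpss as _dpss

logger = logging.getLogger(__name__)

__all__ = [
    "PsdEstimate",
    "TimeFrequencyMap",
    "BandPower",
    "PsdBins",
    "multitaper_psd",
    "morlet_tfr",
    "band_power",
    "normalize_percent_baseline",
    "percent_of_total_power",
    "bin_psd_1hz_log",
]


@dataclass
class PsdEstimate:
    """One-sided power spectral density: power in uV^2/Hz on ``freqs`` (Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power shapes differ")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("PSD power must be non-negative")


@dataclass
class TimeFrequencyMap:
    """Power (trials x freqs x times or freqs x times) with optional phase.

    ``normalization`` is a state token ({'raw', 'percent_baseline',
    'percent_total', 'log_norm'}); normalising an already-normalised map is
    an error, which keeps grand averages from silently mixing scales.
    ``edge_mask`` flags (freq, time) cells within half the wavelet's
    temporal support of either epoch edge.
    """

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    phase: np.ndarray | None = None
    normalization: str = "raw"
    edge_mask: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        self.power = np.asarray(self.power, float)
        if self.power.shape[-2:] != (self.freqs.size, self.times.size):
            raise ValueError("power trailing dims must be (n_freqs, n_times)")
        if self.normalization == "raw" and np.any(self.power < 0):
            raise ValueError("raw power must be non-negative")

    @property
    def per_trial(self) -> bool:
        return self.power.ndim == 3

    def average(self) -> "TimeFrequencyMap":
        """Mean over trials (no-op for an already averaged map)."""
        if not self.per_trial:
            return self
        return replace(self, power=self.power.mean(axis=0), phase=None)


@dataclass
class BandPower:
    band: tuple[float, float]
    value: float
    window: tuple[float, float] | None = None
    units: str = "uV^2"

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError("band low must be < high")


@dataclass
class PsdBins:
    """1 Hz-binned log10 normalised spectrum (default 0.5-100.5 Hz, 100 bins)."""

    centers: np.ndarray
    values: np.ndarray
    range: tuple[float, float] = (0.5, 100.5)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        self.values = np.asarray(self.values, float)
        if self.centers.shape != self.values.shape:
            raise ValueError("centers/values shape mismatch")


# ---------------------------------------------------------------------------
# Multitaper PSD
# ---------------------------------------------------------------------------

def multitaper_psd(
    signal,
    rate: float,
    nw: float = 3.0,
    k: int = 5,
    segment_s: float | None = None,
) -> PsdEstimate:
    """Multitaper PSD: average of K DPSS eigenspectra, one-sided, uV^2/Hz.

    ``nw`` is the time-bandwidth product; the half-bandwidth resolution is
    nw/T Hz for a segment of T seconds.  ``k`` tapers must satisfy
    k <= 2*nw - 1.  With ``segment_s`` the signal is cut into
    non-overlapping segments whose eigenspectra are pooled (Welch-style
    variance reduction for long stationary stretches).
    """
    x = np.asarray(signal, float).ravel()
    if rate <= 0:
        raise ValueError("rate must be positive")
    if k > 2 * nw - 1:
        raise ValueError(f"taper count k={k} exceeds 2*nw-1={2 * nw - 1}")
    if segment_s is None:
        segs = [x]
    else:
        seg_len = int(round(segment_s * rate))
        if seg_len < 2 * k:
            raise ValueError("segment too short for taper count")
        n_segs = x.size // seg_len
        if n_segs == 0:
            raise ValueError("signal shorter than one segment")
        segs = [x[i * seg_len : (i + 1) * seg_len] for i in range(n_segs)]
    n = segs[0].size
    if n < 2 * k:
        raise ValueError("signal too short for taper count")
    tapers = _dpss(n, nw, Kmax=k)  # rows unit-energy
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    acc = np.zeros(freqs.size)
    for seg in segs:
        spec = np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2
        acc += spec.mean(axis=0)
    psd = acc / len(segs) / rate
    # one-sided: double everything except DC (and Nyquist when present)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    return PsdEstimate(
        freqs, psd, params={"nw": nw, "k": k, "segment_s": segment_s, "n": n, "rate": rate}
    )


# ---------------------------------------------------------------------------
# Morlet TFR
# ---------------------------------------------------------------------------

def morlet_tfr(
    epochs,
    rate: float | None = None,
    freqs=None,
    cycles=7.0,
    decim: int = 1,
    keep_phase: bool = True,
    times=None,
) -> TimeFrequencyMap:
    """Complex Morlet time-frequency transform of an epoch set.

    Accepts an EpochSet (from eegbattery.core) or a raw (n_trials, n_samples)
    array plus ``rate``/``times``.  Power is the squared magnitude per trial;
    phase is retained for phase-locking measures.  ``cycles`` may be a scalar
    or per-frequency array; the temporal support half-width cycles/(2 f) is
    used to flag edge-contaminated cells in ``edge_mask``.
    """
    from mne.time_frequency import tfr_array_morlet

    data, t = _coerce_epochs(epochs, rate, times)
    if rate is None:
        rate = epochs.rate
    freqs = np.asarray(freqs, float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("freqs must be a non-empty 1-D sequence")
    if np.any(freqs >= rate / 2):
        raise ValueError("frequency at or above Nyquist")
    n_cycles = np.broadcast_to(np.asarray(cycles, float), freqs.shape).copy()
    epoch_len = data.shape[1] / rate
    if np.any(freqs < n_cycles / epoch_len):
        raise ValueError("wavelet longer than epoch at the lowest frequency")
    out = tfr_array_morlet(
        data[:, None, :], sfreq=rate, freqs=freqs, n_cycles=n_cycles,
        output="complex", decim=decim, zero_mean=True,
    )[:, 0]  # (n_trials, n_freqs, n_times)
    t_out = t[::decim][: out.shape[-1]]
    power = np.abs(out) ** 2
    phase = np.angle(out) if keep_phase else None
    half_support = n_cycles / (2.0 * freqs)
    edge = (t_out[None, :] - t[0] < half_support[:, None]) | (
        t[-1] - t_out[None, :] < half_support[:, None]
    )
    return TimeFrequencyMap(
        freqs, t_out, power, phase=phase, edge_mask=edge,
        params={"cycles": n_cycles, "rate": rate, "decim": decim},
    )


def _coerce_epochs(epochs, rate, times):
    if hasattr(epochs, "data") and hasattr(epochs, "time"):
        return np.atleast_2d(np.asarray(epochs.data, float)), np.asarray(epochs.time)
    data = np.atleast_2d(np.asarray(epochs, float))
    if rate is None:
        raise ValueError("rate required when passing a bare array")
    t = np.asarray(times) if times is not None else np.arange(data.shape[1]) / rate
    return data, t


# ---------------------------------------------------------------------------
# Band power and normalisations
# ---------------------------------------------------------------------------

def _freq_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if lo >= hi:
        raise ValueError("band low must be < high")
    return (freqs >= lo) & (freqs <= hi)


def band_power(obj, band: tuple[float, float], window: tuple[float, float] | None = None) -> BandPower:
    """Mean power over a frequency band (and time window, for a TFR).

    For a TimeFrequencyMap the value is the mean over the band x window
    region of the trial-averaged map (the window is half-open [start, end)).
    For a PsdEstimate it is the trapezoidal band integral divided by the
    band width, i.e. mean density.
    """
    if isinstance(obj, PsdEstimate):
        num = _trapz_band(obj.freqs, obj.power, band)
        return BandPower(band, num / (band[1] - band[0]), units="uV^2/Hz")
    tfm = obj.average()
    fmask = _freq_mask(tfm.freqs, band)
    if not fmask.any():
        raise ValueError(f"no frequencies inside band {band}")
    if window is None:
        tmask = np.ones(tfm.times.size, bool)
    else:
        tmask = (tfm.times >= window[0]) & (tfm.times < window[1])
    if not tmask.any():
        raise ValueError(f"no samples inside window {window}")
    val = float(tfm.power[np.ix_(fmask, tmask)].mean())
    units = "%" if tfm.normalization in ("percent_baseline", "percent_total") else "uV^2"
    return BandPower(band, val, window=window, units=units)


def _trapz_band(freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]) -> float:
    """Trapezoidal integral of a PSD over [lo, hi], interpolating the edges."""
    lo, hi = band
    if lo >= hi:
        raise ValueError("band low must be < high")
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(f"band {band} outside estimate range")
    inner = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inner], [hi]))
    p = np.concatenate(
        ([np.interp(lo, freqs, power)], power[inner], [np.interp(hi, freqs, power)])
    )
    return float(np.trapezoid(p, f))


def normalize_percent_baseline(tfm: TimeFrequencyMap, baseline: tuple[float, float]) -> TimeFrequencyMap:
    """Express each frequency row as percent of its baseline-window mean.

    Per-trial maps are normalised trial by trial.  The baseline window is
    half-open [start, end) in epoch-local seconds and must lie inside the
    map; a zero baseline mean at any frequency is degenerate and raises.
    """
    if tfm.normalization != "raw":
        raise ValueError(f"map already normalised ({tfm.normalization})")
    b0, b1 = baseline
    tmask = (tfm.times >= b0) & (tfm.times < b1)
    if not tmask.any():
        raise ValueError("baseline window outside map times")
    base = tfm.power[..., tmask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("zero baseline power at some frequency: cannot normalise")
    return replace(
        tfm, power=100.0 * tfm.power / base, normalization="percent_baseline"
    )


def percent_of_total_power(
    psd: PsdEstimate,
    band: tuple[float, float],
    total_range: tuple[float, float] = (1.0, 100.0),
) -> BandPower:
    """Band power as percent of the power integrated over ``total_range``."""
    if not (total_range[0] <= band[0] and band[1] <= total_range[1]):
        raise ValueError("band must lie inside total_range")
    num = _trapz_band(psd.freqs, psd.power, band)
    den = _trapz_band(psd.freqs, psd.power, total_range)
    if den <= 0:
        raise ValueError("zero total power")
    return BandPower(band, 100.0 * num / den, units="%")


def bin_psd_1hz_log(
    freqs,
    power,
    reference,
    range_hz: tuple[float, float] = (0.5, 100.5),
) -> PsdBins:
    """1 Hz-binned log10 ratio of power to a per-bin reference.

    Bin i covers [lo + i, lo + i + 1) Hz with centre lo + i + 0.5; each bin's
    value is log10(mean power in bin / mean reference in bin).  The default
    range 0.5-100.5 Hz yields exactly 100 bins.  Requires the frequency grid
    to resolve 1 Hz bins (spacing <= 1 Hz) and strictly positive binned
    means on both sides of the ratio.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    reference = np.asarray(reference, float)
    if power.shape != freqs.shape or reference.shape != freqs.shape:
        raise ValueError("freqs, power and reference must share a grid")
    if freqs.size > 1 and np.max(np.diff(freqs)) > 1.0 + 1e-9:
        raise ValueError("frequency resolution coarser than 1 Hz bins")
    lo, hi = range_hz
    n_bins = int(round(hi - lo))
    edges = lo + np.arange(n_bins + 1)
    centers = edges[:-1] + 0.5
    vals = np.empty(n_bins)
    for i in range(n_bins):
        m = (freqs >= edges[i]) & (freqs < edges[i + 1])
        if not m.any():
            raise ValueError(f"no frequencies in bin [{edges[i]}, {edges[i+1]})")
        num, den = power[m].mean(), reference[m].mean()
        if num <= 0 or den <= 0:
            raise ValueError("non-positive power before log transform")
        vals[i] = np.log10(num / den)
    return PsdBins(centers, vals, range=range_hz)
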