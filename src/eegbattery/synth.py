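"""Synthetic EEG sessions with known ground truth.

Each generator emits a (Recording, EventTrack/Hypnogram, GroundTruth) triple
whose manifest fully determines the session given the seed, so every
downstream biomarker has a recoverable target:

* ``simulate_background`` — 1/f^alpha noise plus tonic oscillations;
* ``simulate_gating_session`` — paired tones with Gabor-like P20/N40 kernels
  and a multiplicative S2 gating factor;
* ``simulate_social_session`` — investigation-locked narrowband gamma bursts
  calibrated to a programmed percent-of-baseline ratio, with an optional
  negative coupling between per-event background gamma and burst amplitude;
* ``simulate_assr_session`` — 40 Hz click trains with per-trial phase jitter;
* ``simulate_sleep_session`` — semi-Markov wake/NREM/REM bouts, NREM delta,
  and NREM-only spindle bursts at a programmed density.

Amplitudes are in microvolts but only ratios matter downstream; the defaults
are plausible for epidural screw electrodes in mouse (tens of microvolts RMS).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .core import EventTrack, Hypnogram, Recording

__all__ = [
    "BackgroundParams",
    "ErpKernelParams",
    "GammaBurstParams",
    "AssrParams",
    "SpindleParams",
    "GroundTruth",
    "simulate_background",
    "simulate_gating_session",
    "simulate_social_session",
    "simulate_assr_session",
    "simulate_sleep_session",
    "erp_kernel",
]


@dataclass
class BackgroundParams:
    """1/f^alpha background: spectral exponent, target RMS (uV), tonic tones."""

    alpha: float = 1.0
    rms: float = 50.0
    band_tones: tuple = ()  # (freq_hz, amplitude_uv) pairs

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 2.0:
            raise ValueError("alpha must lie in [0, 2]")
        if self.rms < 0:
            raise ValueError("rms must be >= 0")


@dataclass
class ErpKernelParams:
    """P20/N40 kernel: (latency s, width s, amplitude uV) per component.

    The kernel is the sum of two Gaussian-windowed cosines; the N40 component
    is applied with negative sign.  ``gating_factor`` multiplies the whole S2
    kernel, so the programmed S2/S1 amplitude ratio equals it exactly.
    """

    p20: tuple[float, float, float] = (0.021, 0.005, 40.0)
    n40: tuple[float, float, float] = (0.044, 0.009, 60.0)
    gating_factor: float = 0.25

    def __post_init__(self) -> None:
        if not (0.015 <= self.p20[0] <= 0.030 and 0.025 <= self.n40[0] <= 0.055):
            raise ValueError("component latencies must sit inside their scoring windows")
        if self.p20[1] <= 0 or self.n40[1] <= 0:
            raise ValueError("widths must be positive")
        if self.gating_factor < 0:
            raise ValueError("gating factor must be >= 0")


@dataclass
class GammaBurstParams:
    """Investigation-locked gamma bursts.

    ``elicited_ratio`` is the programmed percent-of-baseline band power during
    the burst (100 = no burst).  ``coupling`` links per-event background gamma
    level (uV) to burst amplitude (uV per uV); negative values build the
    inverse elicited-vs-background relation.  The default coupling was
    calibrated once so the recovered repeated-measures correlation sits near
    -0.25 at the default noise level.
    """

    band: tuple[float, float] = (25.0, 58.0)
    elicited_ratio: float = 150.0
    burst_duration: float = 1.0
    background_gamma_level: float = 8.0
    background_gamma_spread: float = 0.35  # lognormal sigma of per-event level
    coupling: float = -0.50
    ramp: float = 0.1

    def __post_init__(self) -> None:
        if self.elicited_ratio <= 0:
            raise ValueError("elicited_ratio must be > 0")
        if self.band[0] >= self.band[1]:
            raise ValueError("band low must be < high")


@dataclass
class AssrParams:
    train_rate: float = 40.0
    train_duration: float = 1.0
    click_decay: float = 0.010  # s, per-click damped-oscillation time constant
    amplitude: float = 30.0
    phase_jitter_sd: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.phase_jitter_sd < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class SpindleParams:
    center_freq: float = 12.0
    density: float = 6.0  # events per NREM minute
    duration_range: tuple[float, float] = (0.6, 1.2)
    amplitude: float = 150.0
    taper_fraction: float = 0.08  # Tukey ramp fraction of each event

    def __post_init__(self) -> None:
        if not 10.0 <= self.center_freq <= 15.0:
            raise ValueError("spindle centre frequency must lie in [10, 15] Hz")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not 0 < self.duration_range[0] < self.duration_range[1]:
            raise ValueError("duration_range must be positive and increasing")


@dataclass
class GroundTruth:
    """Per-session manifest: everything needed to predict the analysis output."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonify)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(Path(path)) as fh:
            d = json.load(fh)
        return cls(**d)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _one_over_f(n: int, rate: float, alpha: float, rng: np.random.Generator,
                highpass: float = 0.5, lowpass: float = 200.0) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise by spectral shaping of white noise.

    Below ``highpass`` the shaping gain is frozen at its value at
    ``highpass`` (and DC is zeroed), bounding low-frequency power.  A
    4th-order Butterworth response at ``lowpass`` mimics the acquisition
    chain's anti-alias filter.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    gain = np.ones_like(f)
    if alpha > 0:
        ff = np.maximum(f, highpass)
        gain = ff ** (-alpha / 2.0)
    if lowpass and lowpass < rate / 2:
        gain = gain / np.sqrt(1.0 + (f / lowpass) ** 8)
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=n)
    rms = shaped.std()
    return shaped / rms if rms > 0 else shaped


def _narrowband(n: int, rate: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (4th-order Butterworth)."""
    sos = _sig.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _burst_carrier(n: int, rate: float, band: tuple[float, float], alpha: float,
                   rng: np.random.Generator, skirt: float = 8.0) -> np.ndarray:
    """Burst carrier: noise with the background's 1/f^alpha shape inside
    ``band`` and raised-cosine skirts of ``skirt`` Hz beyond each edge.

    Matching the in-band spectral shape of the background (rather than a
    flat brick-wall band) makes the percent-of-baseline ratio uniform across
    analysis frequencies, and the soft skirts keep wavelet rows at the band
    edges from under-reading the burst.  Normalised so the power strictly
    inside ``band`` is 1.
    """
    lo, hi = band
    white = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.maximum(f, 0.5) ** (-alpha / 2.0)
    w = np.zeros_like(f)
    core = (f >= lo) & (f <= hi)
    w[core] = 1.0
    low_sk = (f >= lo - skirt) & (f < lo)
    w[low_sk] = 0.5 * (1 - np.cos(np.pi * (f[low_sk] - (lo - skirt)) / skirt))
    hi_sk = (f > hi) & (f <= hi + skirt)
    w[hi_sk] = 0.5 * (1 + np.cos(np.pi * (f[hi_sk] - hi) / skirt))
    spec = white * shape * w
    x = np.fft.irfft(spec, n=n)
    in_band = np.fft.irfft(np.where(core, spec, 0.0), n=n)
    return x / in_band.std()


def _strict_band_power(x: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    """Periodogram power integrated strictly inside ``band`` (uV^2)."""
    f, p = _sig.periodogram(x, fs=rate)
    m = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[m], f[m]))


def _plateau_envelope(n_plateau: int, n_ramp: int) -> np.ndarray:
    """Envelope: cosine on-ramp, flat plateau, cosine off-ramp."""
    up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / max(n_ramp, 1)))
    return np.concatenate([up, np.ones(n_plateau), up[::-1]])


def erp_kernel(params: ErpKernelParams, rate: float, length_s: float = 0.2) -> np.ndarray:
    """Noiseless ERP kernel sampled from tone onset (t = 0) for ``length_s``."""
    t = np.arange(int(round(length_s * rate))) / rate
    lat_p, w_p, a_p = params.p20
    lat_n, w_n, a_n = params.n40
    # Gaussian-windowed cosines centred on each latency; the cosine period is
    # wide relative to the window so each component is a clean deflection.
    p = a_p * np.exp(-0.5 * ((t - lat_p) / w_p) ** 2) * np.cos(np.pi * (t - lat_p) / (6 * w_p))
    n = a_n * np.exp(-0.5 * ((t - lat_n) / w_n) ** 2) * np.cos(np.pi * (t - lat_n) / (6 * w_n))
    return p - n


def _kernel_truth(params: ErpKernelParams, rate: float) -> dict:
    """Extrema of the noiseless kernel inside the P20/N40 scoring windows."""
    k = erp_kernel(params, rate)
    t = np.arange(k.size) / rate
    w_p = (t >= 0.015) & (t <= 0.030)
    w_n = (t >= 0.025) & (t <= 0.055)
    p20 = float(k[w_p].max())
    n40 = float(k[w_n].min())
    return {"p20": p20, "n40": n40, "p20_n40": p20 - n40}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_background(
    duration: float,
    rate: float,
    params: BackgroundParams | None = None,
    seed: int = 0,
    channel_names: tuple[str, ...] = ("frontal",),
) -> Recording:
    """Continuous 1/f^alpha background with optional tonic oscillations."""
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    params = params or BackgroundParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    chans = []
    for _ in channel_names:
        x = params.rms * _one_over_f(n, rate, params.alpha, rng)
        for f0, amp in params.band_tones:
            x = x + amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        chans.append(x)
    return Recording(np.vstack(chans), rate, list(channel_names))


def simulate_gating_session(
    n_trials: int = 100,
    kernel: ErpKernelParams | None = None,
    noise: BackgroundParams | None = None,
    seed: int = 0,
    rate: float = 2000.0,
    iti: float = 6.0,
    isi: float = 0.5,
    lead_in: float = 10.0,
) -> tuple[Recording, EventTrack, GroundTruth]:
    """Paired-tone session: S1 evokes the kernel, S2 evokes g x kernel."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    kernel = kernel or ErpKernelParams()
    noise = noise or BackgroundParams()
    duration = float(np.ceil(lead_in + n_trials * iti + 5.0))
    rec = simulate_background(duration, rate, noise, seed=seed)
    sig = rec.samples[0]
    kern = erp_kernel(kernel, rate)
    onsets, durations, labels, blocks = [], [], [], []
    for k in range(n_trials):
        s1 = lead_in + k * iti
        for label, t0, g in (("tone_S1", s1, 1.0), ("tone_S2", s1 + isi, kernel.gating_factor)):
            i0 = int(round(t0 * rate))
            sig[i0 : i0 + kern.size] += g * kern
            onsets.append(t0)
            durations.append(0.05)
            labels.append(label)
            blocks.append(k)
    events = EventTrack.from_lists(onsets, durations, labels, blocks)
    truth = GroundTruth(
        scenario="gating",
        seed=seed,
        params={
            "gating_factor": kernel.gating_factor,
            "kernel": dataclasses.asdict(kernel),
            "noise": dataclasses.asdict(noise),
            "true_components": _kernel_truth(kernel, rate),
            "isi": isi,
            "iti": iti,
            "rate": rate,
        },
        events=[{"onset_s": o, "label": l, "block": b}
                for o, l, b in zip(onsets, labels, blocks)],
    )
    return rec, events, truth


def simulate_social_session(
    n_investigations: int = 40,
    bursts: GammaBurstParams | None = None,
    noise: BackgroundParams | None = None,
    seed: int = 0,
    rate: float = 2000.0,
    label: str = "investigation_novel",
    min_spacing: float = 10.0,
) -> tuple[Recording, EventTrack, GroundTruth]:
    """Investigation session with calibrated post-onset gamma bursts.

    Per event i the background gamma level b_i (a narrowband tonic component
    spanning the event's baseline and burst windows) is drawn lognormally
    around ``background_gamma_level``; the burst's band power is calibrated
    so the first second after onset carries ``elicited_ratio`` percent of
    that event's measured [-4, 0) s baseline band power, then perturbed by
    ``coupling x (b_i - mean level)``.  The burst plateau covers exactly
    [onset, onset + burst_duration); the cosine ramps sit outside it so the
    analysed bins see full burst power.
    """
    if n_investigations < 1:
        raise ValueError("n_investigations must be >= 1")
    bursts = bursts or GammaBurstParams()
    noise = noise or BackgroundParams()
    rng = np.random.default_rng(seed)
    gaps = min_spacing + rng.exponential(2.0, size=n_investigations)
    onsets = 8.0 + np.cumsum(gaps)
    inv_durations = rng.uniform(1.5, 3.0, size=n_investigations)
    duration = float(np.ceil(onsets[-1] + 8.0))
    rec = simulate_background(duration, rate, noise, seed=seed + 1)
    sig = rec.samples[0]
    n = sig.size

    # per-event tonic background gamma spanning [-5, +2] s around onset
    levels = bursts.background_gamma_level * np.exp(
        rng.normal(0.0, bursts.background_gamma_spread, size=n_investigations)
    )
    tonic_carrier = _narrowband(n, rate, bursts.band, rng)
    tonic_gain = np.zeros(n)
    for t0, lv in zip(onsets, levels):
        a = max(0, int(round((t0 - 5.0) * rate)))
        b = min(n, int(round((t0 + 2.0) * rate)))
        tonic_gain[a:b] = np.maximum(tonic_gain[a:b], lv)
    sig += tonic_gain * tonic_carrier

    # measure each event's baseline band power (strict-band periodogram)
    burst_amps = []
    n_ramp = int(round(bursts.ramp * rate))
    n_plateau = int(round(bursts.burst_duration * rate))
    env = _plateau_envelope(n_plateau, n_ramp)
    extra = (bursts.elicited_ratio / 100.0) - 1.0
    for t0, lv in zip(onsets, levels):
        a = int(round((t0 - 4.0) * rate))
        i_on = int(round(t0 * rate))
        base_power = _strict_band_power(sig[a:i_on], rate, bursts.band)
        post_power = _strict_band_power(sig[i_on : i_on + n_plateau], rate, bursts.band)
        # total post-onset band power should be elicited_ratio % of baseline:
        # the burst tops the realized post-onset background up to the target
        if extra <= 0:
            amp = amp_cal = 0.0  # null session: no burst, coupling moot
        else:
            target = max((bursts.elicited_ratio / 100.0) * base_power - post_power, 0.0)
            amp_cal = float(np.sqrt(target))
            amp = max(amp_cal + bursts.coupling * (lv - bursts.background_gamma_level), 0.0)
        burst_amps.append(amp)
        if amp > 0:
            # burst spectrum mirrors the baseline's in-band composition
            # (1/f part + tonic narrowband part) so the percent-of-baseline
            # ratio is uniform across analysis frequencies; the carrier's
            # realized in-band power is pinned exactly to amp^2
            p_tonic = min(lv**2, base_power)
            p_1f = base_power - p_tonic
            c_1f = _burst_carrier(env.size, rate, bursts.band, noise.alpha, rng)
            c_tn = _narrowband(env.size, rate, bursts.band, rng)
            carrier = np.sqrt(p_1f) * c_1f + np.sqrt(p_tonic) * c_tn
            carrier *= amp / np.sqrt(_strict_band_power(carrier, rate, bursts.band))
            i0 = int(round(t0 * rate)) - n_ramp
            seg = env * carrier
            lo, hi = max(i0, 0), min(i0 + seg.size, n)
            sig[lo:hi] += seg[lo - i0 : hi - i0]

    events = EventTrack.from_lists(onsets, inv_durations,
                                   [label] * n_investigations,
                                   np.arange(n_investigations))
    truth = GroundTruth(
        scenario="social",
        seed=seed,
        params={
            "elicited_ratio": bursts.elicited_ratio,
            "coupling": bursts.coupling,
            "band": list(bursts.band),
            "burst_duration": bursts.burst_duration,
            "noise": dataclasses.asdict(noise),
            "rate": rate,
        },
        events=[{"onset_s": float(o), "duration_s": float(d), "label": label,
                 "background_level": float(lv), "burst_amplitude": float(a)}
                for o, d, lv, a in zip(onsets, inv_durations, levels, burst_amps)],
    )
    return rec, events, truth


def simulate_assr_session(
    n_trains: int = 100,
    params: AssrParams | None = None,
    noise: BackgroundParams | None = None,
    seed: int = 0,
    rate: float = 2000.0,
    iti: float = 5.0,
    lead_in: float = 5.0,
) -> tuple[Recording, EventTrack, GroundTruth]:
    """40 Hz click-train session with per-trial phase offsets ~ N(0, jitter^2).

    Each click evokes a damped 40 Hz oscillation; superposed at the train
    rate these sum to a steady-state response whose carrier phase is the
    trial's offset, so the programmed jitter maps directly onto the
    phase-locking factor (e^(-sigma^2/2) in the wrapped-normal limit).

    The default background is quiet (RMS 5 uV) because any 40 Hz background
    power contaminates the single-trial phase estimate and caps the PLF below
    its programmed value; the closed-form jitter-PLF mapping only holds when
    the entrained response dominates the band.
    """
    if n_trains < 1:
        raise ValueError("n_trains must be >= 1")
    params = params or AssrParams()
    noise = noise or BackgroundParams(rms=5.0)
    rng = np.random.default_rng(seed)
    duration = float(np.ceil(lead_in + n_trains * iti + 3.0))
    rec = simulate_background(duration, rate, noise, seed=seed + 1)
    sig = rec.samples[0]
    phases = rng.normal(0.0, params.phase_jitter_sd, size=n_trains)
    f0 = params.train_rate
    # per-click kernel: damped oscillation, 3 decay constants long
    kt = np.arange(int(round(3 * params.click_decay * rate))) / rate
    onsets = lead_in + np.arange(n_trains) * iti
    n_clicks = int(round(params.train_duration * f0))
    for t0, phi in zip(onsets, phases):
        kern = params.amplitude * np.exp(-kt / params.click_decay) * np.sin(
            2 * np.pi * f0 * kt + phi
        )
        for c in range(n_clicks):
            i0 = int(round((t0 + c / f0) * rate))
            sig[i0 : i0 + kern.size] += kern
    events = EventTrack.from_lists(onsets, [params.train_duration] * n_trains,
                                   ["assr_train"] * n_trains, np.arange(n_trains))
    truth = GroundTruth(
        scenario="assr",
        seed=seed,
        params={
            "phase_jitter_sd": params.phase_jitter_sd,
            "train_rate": f0,
            "train_duration": params.train_duration,
            "amplitude": params.amplitude,
            "noise": dataclasses.asdict(noise),
            "rate": rate,
        },
        events=[{"onset_s": float(o), "phase": float(p)}
                for o, p in zip(onsets, phases)],
    )
    return rec, events, truth


def simulate_sleep_session(
    duration: float = 1800.0,
    hyp_bouts: dict | None = None,
    spindles: SpindleParams | None = None,
    noise: BackgroundParams | None = None,
    seed: int = 0,
    rate: float = 500.0,
    epoch_length: float = 10.0,
    nrem_delta_amp: float = 40.0,
    period: str = "light",
) -> tuple[Recording, Hypnogram, GroundTruth]:
    """Sleep session: semi-Markov bouts, NREM delta, NREM-only spindles.

    ``hyp_bouts`` gives mean bout lengths in seconds per state (defaults
    wake 120, NREM 240, REM 60; exponential durations rounded up to whole
    scoring epochs; REM entered from NREM with probability 0.3).  Spindle
    counts per NREM bout are Poisson at ``spindles.density`` per minute;
    events are placed uniformly, non-overlapping, fully inside their bout.
    The default 500 Hz rate keeps half-hour sessions cheap while resolving
    everything below the 9-16 Hz spindle band with a wide margin.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    spindles = spindles or SpindleParams()
    noise = noise or BackgroundParams()
    hyp_bouts = hyp_bouts or {"wake": 120.0, "NREM": 240.0, "REM": 60.0}
    rng = np.random.default_rng(seed)

    n_epochs = int(np.ceil(duration / epoch_length))
    states: list[str] = []
    state = "wake"
    while len(states) < n_epochs:
        mean = hyp_bouts.get(state, 120.0)
        n_ep = max(1, int(np.ceil(rng.exponential(mean) / epoch_length)))
        states.extend([state] * n_ep)
        if state == "wake":
            state = "NREM"
        elif state == "NREM":
            state = "REM" if rng.random() < 0.3 else "wake"
        else:
            state = "wake"
    states_arr = np.asarray(states[:n_epochs], dtype=object)
    hyp = Hypnogram(states=states_arr, epoch_length=epoch_length,
                    periods=np.asarray([period] * n_epochs, dtype=object))

    rec = simulate_background(n_epochs * epoch_length, rate, noise, seed=seed + 1)
    sig = rec.samples[0]
    n = sig.size

    nrem_mask = hyp.state_mask(rate, n, "NREM")
    if nrem_mask.any():
        delta = nrem_delta_amp * _narrowband(n, rate, (1.0, 4.0), rng)
        sig += nrem_mask * delta

    spindle_events = []
    for t0, t1 in hyp.intervals("NREM"):
        bout_min = (t1 - t0) / 60.0
        count = rng.poisson(spindles.density * bout_min)
        placed: list[tuple[float, float]] = []
        for _ in range(count):
            dur = rng.uniform(*spindles.duration_range)
            for _attempt in range(20):
                start = rng.uniform(t0, t1 - dur) if t1 - t0 > dur else None
                if start is None:
                    break
                if all(start + dur <= a or start >= b for a, b in placed):
                    placed.append((start, start + dur))
                    break
        for start, end in placed:
            dur = end - start
            m = int(round(dur * rate))
            tt = np.arange(m) / rate
            env = _sig.windows.tukey(m, alpha=2 * spindles.taper_fraction)
            wave = spindles.amplitude * env * np.sin(
                2 * np.pi * spindles.center_freq * tt + rng.uniform(0, 2 * np.pi)
            )
            i0 = int(round(start * rate))
            sig[i0 : i0 + m] += wave[: max(0, min(m, n - i0))]
            spindle_events.append({"start_s": float(start), "end_s": float(end),
                                   "freq_hz": spindles.center_freq,
                                   "amplitude_uV": spindles.amplitude})

    truth = GroundTruth(
        scenario="sleep",
        seed=seed,
        params={
            "density_per_min": spindles.density,
            "duration_range": list(spindles.duration_range),
            "center_freq": spindles.center_freq,
            "nrem_delta_amp": nrem_delta_amp,
            "noise": dataclasses.asdict(noise),
            "rate": rate,
            "epoch_length": epoch_length,
        },
        events=spindle_events,
    )
    return rec, hyp, truth
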