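"""Per-event power metrics, arrival times, and propagation delays.

Power is summarized as band power over 0–50 Hz from a short-time
periodogram: Hann-tapered 1-s windows with 50% overlap, power spectral
density summed over the band (units µV²).  From the band-power series
each event gets

* its duration,
* the maximum band power over the event,
* the time-integrated band power over the event (the area under the
  curve, AUC, in µV²·s),
* the same metrics at the distal electrodes normalized to the focus,
* per-channel arrival times — the first window whose band power
  exceeds that channel's session threshold (session mean band power
  plus one SD) — and distal-minus-focus propagation delays.

Events flagged as saturation-excluded never reach these computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .detection import EpileptiformEvent
from .io import EcogRecording, RunConfig


class ExcludedEventError(ValueError):
    """Metrics requested for a saturation-excluded event."""


def band_power_series(
    trace: np.ndarray,
    sampling_rate: float,
    window_s: float = 1.0,
    hop_s: float = 0.5,
    band: tuple[float, float] = (0.0, 50.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Band power per window; returns (window-center times s, power µV²).

    Each window is a Hann-tapered periodogram whose PSD is integrated
    over ``band``; for a pure tone of amplitude A inside the band the
    value approaches A²/2.  A trace shorter than one window is treated
    as a single untapered window (interictal spikes are shorter than
    the default 1-s window).
    """
    x = np.asarray(trace, dtype=float)
    fs = sampling_rate
    if not fs > 2 * band[1]:
        raise ValueError(f"sampling rate {fs} cannot resolve {band[1]} Hz")
    nperseg = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if hop <= 0 or nperseg <= 0:
        raise ValueError("window and hop must be positive")

    if len(x) == 0:
        raise ValueError("empty trace")
    if len(x) < nperseg:
        f, p = signal.periodogram(x, fs, window="boxcar", detrend=False)
        m = (f >= band[0]) & (f <= band[1])
        df = f[1] - f[0] if len(f) > 1 else 1.0
        return np.array([len(x) / fs / 2.0]), np.array([p[m].sum() * df])

    f, t, Sxx = signal.spectrogram(
        x,
        fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    m = (f >= band[0]) & (f <= band[1])
    df = f[1] - f[0]
    return t, Sxx[m].sum(axis=0) * df


@dataclass
class SessionPowerStats:
    """Session-wide band-power statistics per channel.

    The arrival threshold is the session mean band power plus one SD,
    computed per channel over the entire recording.
    """

    mean: dict[str, float]
    sd: dict[str, float]

    @property
    def threshold(self) -> dict[str, float]:
        return {ch: self.mean[ch] + self.sd[ch] for ch in self.mean}


def session_power_stats(
    recording: EcogRecording, config: RunConfig | None = None
) -> SessionPowerStats:
    config = config or RunConfig()
    mean, sd = {}, {}
    for ch, x in recording.channels.items():
        _, p = band_power_series(
            x,
            recording.sampling_rate,
            config.bp_window_s,
            config.bp_hop_s,
            (config.band_low_hz, config.band_high_hz),
        )
        mean[ch] = float(p.mean())
        sd[ch] = float(p.std())
    return SessionPowerStats(mean=mean, sd=sd)


@dataclass
class EventMetrics:
    duration_s: float
    max_band_power: float  # µV²
    auc: float  # µV²·s
    norm_duration: dict[str, float | None]
    norm_max_power: dict[str, float | None]
    norm_auc: dict[str, float | None]
    arrival: dict[str, float | None]  # s from event start, per channel
    delay_d1: float | None
    delay_d2: float | None


def _auc(t: np.ndarray, p: np.ndarray, duration_s: float) -> float:
    """Integral of the band-power series over the whole event.

    The series is extended flat from the first/last window center to the
    event edges, so constant power P over T seconds integrates to P·T.
    """
    if len(p) == 1:
        return float(p[0] * duration_s)
    tt = np.r_[0.0, t, duration_s]
    pp = np.r_[p[0], p, p[-1]]
    return float(np.trapezoid(pp, tt))


def _threshold_duration(t: np.ndarray, p: np.ndarray, thr: float, hop_s: float) -> float:
    """Time spanned by windows exceeding the arrival threshold."""
    idx = np.flatnonzero(p > thr)
    if len(idx) == 0:
        return 0.0
    return float(t[idx[-1]] - t[idx[0]] + hop_s)


def arrival_delay(
    event: EpileptiformEvent,
    session_stats: SessionPowerStats,
    config: RunConfig | None = None,
) -> tuple[dict[str, float | None], float | None, float | None]:
    """Arrival time per channel and distal propagation delays.

    Arrival = time (s, relative to event start) of the first band-power
    window exceeding the channel's session threshold; ``None`` when the
    event never crosses it on that channel.  Delays are distal arrival
    minus focus arrival, defined only when both exist.
    """
    config = config or RunConfig()
    thr = session_stats.threshold
    arrival: dict[str, float | None] = {}
    for ch in ("focus", "d1mm", "d2mm"):
        t, p = band_power_series(
            getattr(event, {"focus": "focus", "d1mm": "d1mm", "d2mm": "d2mm"}[ch]),
            event.sampling_rate,
            config.bp_window_s,
            config.bp_hop_s,
            (config.band_low_hz, config.band_high_hz),
        )
        idx = np.flatnonzero(p > thr[ch])
        arrival[ch] = float(t[idx[0]]) if len(idx) else None

    def _delay(ch: str) -> float | None:
        if arrival[ch] is None or arrival["focus"] is None:
            return None
        return arrival[ch] - arrival["focus"]

    return arrival, _delay("d1mm"), _delay("d2mm")


def compute_event_metrics(
    event: EpileptiformEvent,
    session_stats: SessionPowerStats,
    config: RunConfig | None = None,
    metrics_excluded: bool = False,
) -> EventMetrics:
    """All power metrics for one retained event."""
    if metrics_excluded:
        raise ExcludedEventError(
            "event exceeds the saturation exclusion fraction; metrics undefined"
        )
    config = config or RunConfig()
    fs = event.sampling_rate
    band = (config.band_low_hz, config.band_high_hz)
    dur = event.duration_s

    series = {
        ch: band_power_series(x, fs, config.bp_window_s, config.bp_hop_s, band)
        for ch, x in (("focus", event.focus), ("d1mm", event.d1mm), ("d2mm", event.d2mm))
    }
    t_f, p_f = series["focus"]
    max_f = float(p_f.max())
    auc_f = _auc(t_f, p_f, dur)
    thr = session_stats.threshold
    dur_f = _threshold_duration(t_f, p_f, thr["focus"], config.bp_hop_s)

    norm_dur: dict[str, float | None] = {}
    norm_max: dict[str, float | None] = {}
    norm_auc: dict[str, float | None] = {}
    for ch in ("d1mm", "d2mm"):
        t_d, p_d = series[ch]
        max_d = float(p_d.max())
        auc_d = _auc(t_d, p_d, dur)
        dur_d = _threshold_duration(t_d, p_d, thr[ch], config.bp_hop_s)
        norm_max[ch] = max_d / max_f if max_f > 0 else None
        norm_auc[ch] = auc_d / auc_f if auc_f > 0 else None
        norm_dur[ch] = dur_d / dur_f if dur_f > 0 else None

    arrival, d1, d2 = arrival_delay(event, session_stats, config)
    return EventMetrics(
        duration_s=dur,
        max_band_power=max_f,
        auc=auc_f,
        norm_duration=norm_dur,
        norm_max_power=norm_max,
        norm_auc=norm_auc,
        arrival=arrival,
        delay_d1=d1,
        delay_d2=d2,
    )
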