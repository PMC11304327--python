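"""Synthetic three-channel ECoG cohort generator.

Stands in for chronically recorded sessions from the iron-chloride
focal-epilepsy model: a focus electrode over the injection site and two
electrodes 1 mm and 2 mm away.  Every generated session carries its
ground truth, so detection, propagation scoring, clustering, metrics and
cohort statistics are all testable against known answers.

The generator emulates

* three event morphologies — seizures (rhythmic spike-wave trains),
  polyspikes (short runs of >= 3 sharp transients) and interictal
  spikes (single biphasic transients);
* three propagation regimes — ``propagated``, ``attenuated`` and
  ``nonpropagated`` — realized as per-event gain/noise presets for the
  distal channels, chosen to reproduce the characteristic geometry of
  the (r_1mm, r_2mm) correlation plane: a tight high-correlation cloud,
  a decaying intermediate cloud, and a near-zero cloud;
* homogeneous Poisson event incidence at per-day rates (defaults follow
  the chronic-model incidence: ~52 seizures/day in epilepsy controls,
  hundreds of spikes/day);
* 1/f background noise and amplifier saturation (hard clipping at the
  rail), including events whose amplitude is scaled to saturate a
  requested fraction of samples.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EVENT_TYPES, GROUPS, REGIMES, EcogRecording


class SessionOverflowError(RuntimeError):
    """Requested event rates leave no room for non-overlapping events."""


# ---------------------------------------------------------------------------
# event specification


@dataclass
class EventSpec:
    """Ground truth for one synthetic event on the focus channel."""

    type: str  # seizure | polyspike | interictal_spike
    onset: float  # s from session start
    duration: float  # s
    amplitude: float  # µV, peak of the focus waveform
    rhythm_rate: float  # Hz; spike repetition rate (seizure / polyspike)
    regime: str  # propagated | attenuated | nonpropagated
    d1_gain: float
    d2_gain: float
    d1_delay: float = 0.0  # s
    d2_delay: float = 0.0  # s
    noise_sd: float = 0.0  # µV, distal additive noise
    noise_ratio: float = 0.0  # distal noise as a fraction of focus SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if min(self.d1_gain, self.d2_gain, self.d1_delay, self.d2_delay) < 0:
            raise ValueError("gains and delays must be >= 0")
        if self.noise_sd < 0 or self.noise_ratio < 0:
            raise ValueError("noise_sd and noise_ratio must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


#: per-regime distal presets: uniform sampling ranges for the 1-mm and
#: 2-mm gains and for the distal noise expressed relative to the focus
#: waveform SD.  Gains follow the documented preset centers 0.9/0.8,
#: 0.6/0.25 and 0.05/0.02; the noise ratios place the three regimes at
#: (r1, r2) ~ (0.95, 0.93), (0.66, 0.36) and (0.08, 0.04).
REGIME_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "propagated": {
        "d1_gain": (0.85, 0.95),
        "d2_gain": (0.75, 0.85),
        "noise_ratio": (0.15, 0.30),
    },
    "attenuated": {
        "d1_gain": (0.50, 0.70),
        "d2_gain": (0.20, 0.30),
        "noise_ratio": (0.50, 0.80),
    },
    "nonpropagated": {
        "d1_gain": (0.02, 0.08),
        "d2_gain": (0.01, 0.04),
        "noise_ratio": (0.50, 0.80),
    },
}

#: morphology sampling ranges per event type:
#: (duration s, amplitude µV, rhythm Hz)
MORPHOLOGY_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "seizure": {
        "duration": (12.0, 30.0),
        "amplitude": (400.0, 1200.0),
        "rhythm_rate": (3.0, 8.0),
    },
    "polyspike": {
        "duration": (0.3, 0.9),
        "amplitude": (250.0, 700.0),
        "rhythm_rate": (8.0, 15.0),
    },
    "interictal_spike": {
        "duration": (0.05, 0.10),
        "amplitude": (250.0, 700.0),
        "rhythm_rate": (0.0, 0.0),
    },
}


def sample_regime_params(
    regime: str, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Draw (d1_gain, d2_gain, noise_ratio) from the regime's preset."""
    p = REGIME_PRESETS[regime]
    return (
        rng.uniform(*p["d1_gain"]),
        rng.uniform(*p["d2_gain"]),
        rng.uniform(*p["noise_ratio"]),
    )


# ---------------------------------------------------------------------------
# waveform synthesis


def _spike_kernel(width_s: float, fs: float) -> np.ndarray:
    """Biphasic sharp transient: derivative-of-Gaussian, peak 1."""
    n = max(int(round(width_s * fs)), 3)
    t = np.linspace(-3.0, 3.0, n)
    k = -t * np.exp(-0.5 * t**2)
    return k / np.max(np.abs(k))


def synth_event(spec: EventSpec, sampling_rate: float, seed: int | None = None) -> np.ndarray:
    """Generate the focus-channel waveform of one event.

    Seizures are amplitude-modulated rhythmic spike-wave trains at
    ``rhythm_rate``; polyspikes are short runs of >= 3 sharp transients;
    interictal spikes are single ~50–100 ms biphasic transients.
    Deterministic given (spec, seed); ``seed`` defaults to ``spec.seed``.
    """
    if not sampling_rate > 0:
        raise ValueError("sampling rate must be positive")
    fs = sampling_rate
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(spec.duration * fs))
    if n <= 0:
        raise ValueError("duration too short for the sampling rate")
    x = np.zeros(n)

    if spec.type == "interictal_spike":
        k = _spike_kernel(spec.duration, fs)[:n]
        x[: len(k)] = k
    elif spec.type == "polyspike":
        rate = max(spec.rhythm_rate, 3.0 / spec.duration)
        period = int(round(fs / rate))
        kernel = _spike_kernel(0.05, fs)
        starts = np.arange(0, n - len(kernel), max(period, 1))
        if len(starts) < 3:  # a polyspike is >= 3 transients by definition
            starts = np.linspace(0, max(n - len(kernel), 1), 3).astype(int)
        for s in starts:
            x[s : s + len(kernel)] += kernel * rng.uniform(0.7, 1.0)
    else:  # seizure: spike-and-wave train under a smooth envelope
        rate = max(spec.rhythm_rate, 0.5)
        period = max(int(round(fs / rate)), 2)
        kernel = _spike_kernel(min(0.07, 0.5 / rate), fs)
        t = np.arange(n) / fs
        # slow "wave" component at the rhythm rate carries the fundamental;
        # the sharp transients ride on top of it
        x = 0.9 * np.sin(2 * np.pi * rate * t - np.pi / 2)
        for s in range(0, n - len(kernel), period):
            x[s : s + len(kernel)] += 0.7 * kernel * rng.uniform(0.8, 1.0)
        # ramp on/off plus slow amplitude modulation
        ramp = min(int(0.1 * n), int(2 * fs))
        env = np.ones(n)
        if ramp > 0:
            env[:ramp] = np.linspace(0.2, 1.0, ramp)
            env[-ramp:] = np.linspace(1.0, 0.3, ramp)
        env *= 1.0 + 0.2 * np.sin(2 * np.pi * rng.uniform(0.05, 0.15) * t + rng.uniform(0, 2 * np.pi))
        x *= env

    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return spec.amplitude * x


def synth_distal(
    focus_trace: np.ndarray,
    gain: float,
    delay: float,
    noise_sd: float,
    sampling_rate: float,
    seed: int,
    rail: float | None = None,
) -> np.ndarray:
    """Distal channel = gain × delayed focus + white Gaussian noise.

    Optionally hard-clipped at ``rail``.
    """
    if gain < 0 or noise_sd < 0 or delay < 0:
        raise ValueError("gain, delay and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    shift = int(round(delay * sampling_rate))
    y = np.zeros_like(focus_trace, dtype=float)
    if shift < len(focus_trace):
        y[shift:] = focus_trace[: len(focus_trace) - shift]
    y = gain * y + rng.normal(0.0, noise_sd, len(y))
    if rail is not None:
        np.clip(y, -rail, rail, out=y)
    return y


def scale_for_saturation(trace: np.ndarray, rail: float, frac: float) -> float:
    """Scale factor making a fraction ``frac`` of |samples| reach the rail."""
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    q = np.quantile(np.abs(trace), 1.0 - frac)
    if q <= 0:
        raise ValueError("trace has no amplitude to scale")
    return rail / q


# ---------------------------------------------------------------------------
# cohort configuration


def _default_rates() -> dict[str, dict[str, float]]:
    # per-day incidence by group: (seizures, interictal spikes, polyspikes)
    table = {
        "epilepsy_control": (52.0, 363.0, 274.0),
        "epilepsy_laser_cut_single": (46.0, 600.0, 363.0),
        "epilepsy_laser_cut_close_double": (5.0, 600.0, 363.0),
        "epilepsy_laser_cut_wide_double": (3.0, 600.0, 363.0),
        "laser_cut_control": (0.3, 95.0, 24.0),
        "surgical_control": (0.0, 155.0, 46.0),
    }
    return {
        g: {"seizure": s, "interictal_spike": i, "polyspike": p}
        for g, (s, i, p) in table.items()
    }


def _default_mixtures() -> dict[str, dict[str, float]]:
    control = {"propagated": 0.80, "attenuated": 0.07, "nonpropagated": 0.13}
    cut = {"propagated": 0.05, "attenuated": 0.60, "nonpropagated": 0.35}
    return {
        "epilepsy_control": dict(control),
        "epilepsy_laser_cut_single": dict(cut),
        "epilepsy_laser_cut_close_double": dict(cut),
        "epilepsy_laser_cut_wide_double": dict(cut),
        "laser_cut_control": dict(cut),
        "surgical_control": dict(control),
    }


@dataclass
class CohortConfig:
    """Study-level generator settings (defaults are the study conditions)."""

    sampling_rate: float = 500.0
    session_s: float = 86400.0  # 24-h weekly sessions
    rail_uv: float = 5000.0
    background_sd_uv: float = 20.0
    min_event_gap_s: float = 2.5
    rates: dict[str, dict[str, float]] = field(default_factory=_default_rates)
    regime_mixture: dict[str, dict[str, float]] = field(default_factory=_default_mixtures)
    morphology: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in MORPHOLOGY_RANGES.items()}
    )
    #: fraction of seizures whose amplitude is scaled to partially
    #: saturate the amplifier (clipping 12–30% of in-event samples)
    saturating_seizure_fraction: float = 0.0
    weeks: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        for g, mix in self.regime_mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"regime mixture for {g!r} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"negative mixture weight in {g!r}")
        for g, r in self.rates.items():
            if any(v < 0 for v in r.values()):
                raise ValueError(f"negative rate in {g!r}")
        if not 0.0 <= self.saturating_seizure_fraction <= 1.0:
            raise ValueError("saturating_seizure_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# session synthesis


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian background with the requested SD."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = 1.0 / np.sqrt(np.maximum(f, f[1] if len(f) > 1 else 1.0))
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def draw_event_specs(
    config: CohortConfig, group: str, seed: int, session_s: float | None = None
) -> list[EventSpec]:
    """Draw ground-truth event specs for one session (no waveforms).

    Onsets follow a homogeneous Poisson process per event type at the
    group's daily rate; overlapping draws are rejection-resampled so
    events are pairwise disjoint with at least ``min_event_gap_s``
    separation.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    T = config.session_s if session_s is None else session_s
    specs: list[EventSpec] = []
    intervals: list[tuple[float, float]] = []

    for etype in EVENT_TYPES:
        rate = config.rates[group][etype]
        n_ev = rng.poisson(rate * T / 86400.0)
        morph = config.morphology[etype]
        for _ in range(n_ev):
            dur = rng.uniform(*morph["duration"])
            placed = False
            for _try in range(200):
                onset = rng.uniform(0.0, max(T - dur, 1e-6))
                a, b = onset - config.min_event_gap_s, onset + dur + config.min_event_gap_s
                if all(b <= s or a >= e for s, e in intervals):
                    placed = True
                    break
            if not placed:
                raise SessionOverflowError(
                    f"cannot place {n_ev} non-overlapping {etype} events in {T} s"
                )
            regime = rng.choice(REGIMES, p=[config.regime_mixture[group][r] for r in REGIMES])
            g1, g2, rho = sample_regime_params(regime, rng)
            specs.append(
                EventSpec(
                    type=etype,
                    onset=onset,
                    duration=dur,
                    amplitude=rng.uniform(*morph["amplitude"]),
                    rhythm_rate=rng.uniform(*morph["rhythm_rate"]),
                    regime=regime,
                    d1_gain=g1,
                    d2_gain=g2,
                    noise_ratio=rho,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            intervals.append((onset, onset + dur))
    specs.sort(key=lambda s: s.onset)
    return specs


def synth_session(
    config: CohortConfig,
    group: str,
    week: int,
    seed: int,
    animal_id: str = "synthetic",
    session_s: float | None = None,
    events_only: bool = False,
) -> tuple[EcogRecording | None, list[EventSpec]]:
    """Generate one session: recording plus its ground-truth event list.

    ``session_s`` overrides the configured 24-h duration for desk-scale
    work; daily rates are scaled accordingly.  With ``events_only`` the
    (possibly very long) waveforms are skipped and only the ground truth
    is drawn — useful for incidence statistics.
    """
    specs = draw_event_specs(config, group, seed, session_s)
    if events_only:
        return None, specs

    fs = config.sampling_rate
    T = config.session_s if session_s is None else session_s
    n = int(round(T * fs))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEC06]))
    chans = {role: _pink_noise(n, config.background_sd_uv, rng) for role in ("focus", "d1mm", "d2mm")}

    # which seizures saturate the amplifier
    seiz_idx = [i for i, s in enumerate(specs) if s.type == "seizure"]
    n_sat = int(round(config.saturating_seizure_fraction * len(seiz_idx)))
    sat_set = set(rng.permutation(seiz_idx)[:n_sat]) if n_sat else set()

    for i, spec in enumerate(specs):
        trace = synth_event(spec, fs)
        if i in sat_set:
            target = rng.uniform(0.12, 0.30)
            trace = trace * scale_for_saturation(trace, config.rail_uv, target)
        i0 = int(round(spec.onset * fs))
        i1 = min(i0 + len(trace), n)
        seg = trace[: i1 - i0]
        chans["focus"][i0:i1] += seg
        sd = spec.noise_sd + spec.noise_ratio * seg.std()
        for role, gain, delay, off in (
            ("d1mm", spec.d1_gain, spec.d1_delay, 1),
            ("d2mm", spec.d2_gain, spec.d2_delay, 2),
        ):
            chans[role][i0:i1] += synth_distal(seg, gain, delay, sd, fs, spec.seed + off)

    for role in chans:
        np.clip(chans[role], -config.rail_uv, config.rail_uv, out=chans[role])

    rec = EcogRecording(
        animal_id=animal_id,
        group=group,
        week=week,
        sampling_rate=fs,
        channels=chans,
        rail=config.rail_uv,
    ).validate()
    return rec, specs


# ---------------------------------------------------------------------------
# profile-level cohorts (event traces without a full session)


def synth_propagation_profiles(
    n_events: int,
    mixture: dict[str, float],
    seed: int,
    sampling_rate: float = 500.0,
    duration_range: tuple[float, float] = (8.0, 16.0),
) -> pd.DataFrame:
    """Simulate ``n_events`` seizures and score their propagation.

    Each event is a full seizure waveform with distal channels built
    from a regime drawn from ``mixture``; the returned frame has columns
    ``r_1mm``, ``r_2mm`` (zero-lag Pearson against the focus trace) and
    ``regime`` (ground truth).  This is the event-level path used to
    study cluster-mixture recovery without composing 24-h sessions.
    """
    from .propagation import pearson_r  # local import to avoid a cycle

    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture sums to {total}, not 1")
    rng = np.random.default_rng(seed)
    rows = []
    probs = [mixture.get(r, 0.0) for r in REGIMES]
    for i in range(n_events):
        regime = rng.choice(REGIMES, p=probs)
        g1, g2, rho = sample_regime_params(regime, rng)
        spec = EventSpec(
            type="seizure",
            onset=0.0,
            duration=rng.uniform(*duration_range),
            amplitude=rng.uniform(*MORPHOLOGY_RANGES["seizure"]["amplitude"]),
            rhythm_rate=rng.uniform(*MORPHOLOGY_RANGES["seizure"]["rhythm_rate"]),
            regime=regime,
            d1_gain=g1,
            d2_gain=g2,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        focus = synth_event(spec, sampling_rate)
        sd = rho * focus.std()
        d1 = synth_distal(focus, g1, spec.d1_delay, sd, sampling_rate, spec.seed + 1)
        d2 = synth_distal(focus, g2, spec.d2_delay, sd, sampling_rate, spec.seed + 2)
        rows.append(
            {
                "event_id": i,
                "r_1mm": pearson_r(focus, d1),
                "r_2mm": pearson_r(focus, d2),
                "regime": regime,
            }
        )
    return pd.DataFrame(rows)
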