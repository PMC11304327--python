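"""Synthetic cohort generator: determinism, morphology, regimes, rates."""

import numpy as np
import pytest

from ecogprop import (
    CohortConfig,
    EventSpec,
    pearson_r,
    synth_distal,
    synth_event,
    synth_propagation_profiles,
    synth_session,
)
from ecogprop.synthetic import draw_event_specs, scale_for_saturation


def _seizure_spec(rate=5.0, duration=20.0, seed=3) -> EventSpec:
    return EventSpec(
        type="seizure",
        onset=0.0,
        duration=duration,
        amplitude=500.0,
        rhythm_rate=rate,
        regime="propagated",
        d1_gain=0.9,
        d2_gain=0.8,
        seed=seed,
    )


def test_synth_event_deterministic():
    spec = _seizure_spec()
    np.testing.assert_array_equal(synth_event(spec, 500.0), synth_event(spec, 500.0))


def test_zero_amplitude_gives_zero_trace():
    spec = _seizure_spec()
    spec.amplitude = 0.0
    assert not synth_event(spec, 500.0).any()


@pytest.mark.parametrize("rate", [3.0, 5.0, 8.0])
def test_seizure_spectrum_peaks_at_rhythm_rate(rate):
    """DFT oracle: the spike-wave train's fundamental dominates."""
    spec = _seizure_spec(rate=rate)
    x = synth_event(spec, 500.0)
    freqs = np.fft.rfftfreq(len(x), 1 / 500.0)
    peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
    assert peak == pytest.approx(rate, abs=freqs[1])


def test_distal_identity_and_independence():
    x = synth_event(_seizure_spec(), 500.0)
    same = synth_distal(x, gain=1.0, delay=0.0, noise_sd=0.0, sampling_rate=500.0, seed=1)
    assert pearson_r(x, same) == pytest.approx(1.0)
    noise = synth_distal(x, gain=0.0, delay=0.0, noise_sd=30.0, sampling_rate=500.0, seed=1)
    assert abs(pearson_r(x, noise)) < 3 / np.sqrt(len(x))


def test_distal_correlation_matches_closed_form():
    """E[r] = g·σ_s / sqrt(g²σ_s² + σ_n²), Monte-Carlo over 100 seeds."""
    x = synth_event(_seizure_spec(), 500.0)
    sigma_s = x.std()
    for g, rho in [(0.9, 0.2), (0.6, 0.65), (0.25, 0.65)]:
        rs = [
            pearson_r(x, synth_distal(x, g, 0.0, rho * sigma_s, 500.0, seed))
            for seed in range(100)
        ]
        expected = g * sigma_s / np.hypot(g * sigma_s, rho * sigma_s)
        mc_err = 3 * np.std(rs) / 10 + 1e-3
        assert np.mean(rs) == pytest.approx(expected, abs=max(mc_err, 5e-3))


def test_session_zero_rates_is_pure_background():
    cfg = CohortConfig()
    cfg.rates = {g: {t: 0.0 for t in r} for g, r in cfg.rates.items()}
    rec, specs = synth_session(cfg, "epilepsy_control", 0, seed=1, session_s=30.0)
    assert specs == []
    assert np.max(np.abs(rec.channels["focus"])) < 8 * cfg.background_sd_uv


def test_session_deterministic():
    cfg = CohortConfig()
    a, sa = synth_session(cfg, "epilepsy_control", 0, seed=5, session_s=60.0)
    b, sb = synth_session(cfg, "epilepsy_control", 0, seed=5, session_s=60.0)
    assert sa == sb
    for ch in a.channels:
        np.testing.assert_array_equal(a.channels[ch], b.channels[ch])


def test_daily_seizure_incidence_matches_control_rate():
    """Mean seizure count over 20 independent 24-h sessions stays within
    sampling error (±5) of the 52/day control incidence."""
    cfg = CohortConfig()
    counts = []
    for seed in range(20):
        specs = draw_event_specs(cfg, "epilepsy_control", seed=seed)
        counts.append(sum(1 for s in specs if s.type == "seizure"))
    assert np.mean(counts) == pytest.approx(52.0, abs=5.0)


def test_ground_truth_intervals_disjoint_and_inside():
    cfg = CohortConfig()
    _, specs = synth_session(
        cfg, "epilepsy_control", 0, seed=9, session_s=86400.0, events_only=True
    )
    assert len(specs) > 100
    ivs = sorted((s.onset, s.offset) for s in specs)
    assert all(0.0 <= a < b <= 86400.0 for a, b in ivs)
    assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))


def test_regime_medians_dominate_componentwise():
    """Over 500 events per regime, median (r1, r2) of propagated >
    attenuated > nonpropagated, component-wise."""
    meds = {}
    for i, regime in enumerate(("propagated", "attenuated", "nonpropagated")):
        mix = {r: (1.0 if r == regime else 0.0) for r in ("propagated", "attenuated", "nonpropagated")}
        df = synth_propagation_profiles(500, mix, seed=100 + i)
        meds[regime] = (df["r_1mm"].median(), df["r_2mm"].median())
    for j in range(2):
        assert meds["propagated"][j] > meds["attenuated"][j] > meds["nonpropagated"][j]


def test_saturation_fraction_control():
    """Scaling an event to saturate fraction f clips f ± 0.02 of samples."""
    x = synth_event(_seizure_spec(), 500.0)
    rail = 5000.0
    for f in (0.1, 0.2, 0.3):
        y = np.clip(x * scale_for_saturation(x, rail, f), -rail, rail)
        clipped = np.mean(np.abs(y) >= 0.999 * rail)
        assert clipped == pytest.approx(f, abs=0.02)


def test_session_saturating_seizures_are_clipped():
    cfg = CohortConfig(saturating_seizure_fraction=1.0)
    cfg.rates["epilepsy_control"] = {"seizure": 2000.0, "interictal_spike": 0.0, "polyspike": 0.0}
    rec, specs = synth_session(cfg, "epilepsy_control", 0, seed=2, session_s=600.0)
    assert any(s.type == "seizure" for s in specs)
    fs = cfg.sampling_rate
    for s in specs:
        i0, i1 = int(s.onset * fs), int(s.offset * fs)
        frac = np.mean(np.abs(rec.channels["focus"][i0:i1]) >= 0.999 * cfg.rail_uv)
        assert 0.05 < frac < 0.40  # requested range 0.12–0.30, quantized edges


def test_overcrowded_session_raises():
    from ecogprop.synthetic import SessionOverflowError

    cfg = CohortConfig()
    cfg.rates["epilepsy_control"]["seizure"] = 5e5  # no room at 24-h scale
    with pytest.raises(SessionOverflowError):
        draw_event_specs(cfg, "epilepsy_control", seed=0, session_s=120.0)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        EventSpec(
            type="seizure", onset=0, duration=-1, amplitude=1, rhythm_rate=5,
            regime="propagated", d1_gain=0.9, d2_gain=0.8,
        )
    cfg = CohortConfig()
    cfg.regime_mixture["epilepsy_control"]["propagated"] = 0.5
    with pytest.raises(ValueError):
        CohortConfig(regime_mixture=cfg.regime_mixture)
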