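"""Focus-to-distal propagation scoring.

Each event gets a correlation profile: zero-lag Pearson coefficients
between the focus slice and each distal slice over the full event
interval, together with per-channel saturation bookkeeping.  Events
whose focus channel is saturated for more than the exclusion fraction
(default 10% of samples) keep their profile — propagation clustering
still uses them — but are flagged out of the power-metric analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import EpileptiformEvent


class DegenerateFocusError(ValueError):
    """Constant focus slice: correlation undefined."""


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation; 0 (by convention) if y is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0:
        raise DegenerateFocusError("constant reference slice")
    if np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class PropagationProfile:
    """Per-event correlation and saturation summary."""

    r_1mm: float
    r_2mm: float
    sat_frac_focus: float
    sat_frac_d1: float
    sat_frac_d2: float
    metrics_excluded: bool = False
    degenerate_d1: bool = False
    degenerate_d2: bool = False


def saturated_fraction(x: np.ndarray, rail: float, tolerance: float = 0.999) -> float:
    """Fraction of samples at the amplifier rail.

    A sample counts as saturated when |sample| >= tolerance × rail; the
    tolerance absorbs quantization after unit conversion.
    """
    if not rail > 0:
        raise ValueError("rail must be positive")
    return float(np.mean(np.abs(x) >= tolerance * rail))


def correlation_profile(
    event: EpileptiformEvent, rail: float, rail_tolerance: float = 0.999
) -> PropagationProfile:
    """Score one event's propagation to the 1-mm and 2-mm electrodes."""
    if not (len(event.focus) == len(event.d1mm) == len(event.d2mm)):
        raise ValueError("channel slices of unequal length")
    if len(event.focus) < 2:
        raise ValueError("event too short to correlate")
    d1_const = np.ptp(event.d1mm) == 0
    d2_const = np.ptp(event.d2mm) == 0
    return PropagationProfile(
        r_1mm=pearson_r(event.focus, event.d1mm),
        r_2mm=pearson_r(event.focus, event.d2mm),
        sat_frac_focus=saturated_fraction(event.focus, rail, rail_tolerance),
        sat_frac_d1=saturated_fraction(event.d1mm, rail, rail_tolerance),
        sat_frac_d2=saturated_fraction(event.d2mm, rail, rail_tolerance),
        degenerate_d1=d1_const,
        degenerate_d2=d2_const,
    )


def saturation_filter(
    events: list[tuple[EpileptiformEvent, PropagationProfile]],
    rail: float,
    exclusion_fraction: float = 0.10,
) -> tuple[list, list]:
    """Partition events for the power-metric analysis.

    An event is excluded when its focus-channel saturated fraction is
    *strictly greater* than ``exclusion_fraction`` (an event with
    exactly the boundary fraction is retained).  Flags are set on the
    profiles in place; both partitions are returned and the excluded
    events remain available to propagation clustering.
    """
    if not rail > 0:
        raise ValueError("rail must be positive")
    retained, excluded = [], []
    for ev, prof in events:
        prof.metrics_excluded = prof.sat_frac_focus > exclusion_fraction
        (excluded if prof.metrics_excluded else retained).append((ev, prof))
    return retained, excluded
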