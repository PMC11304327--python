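"""Epileptiform event detection and rule-based classification.

Events are found on the focus channel by robust amplitude thresholding:
the rectified signal is compared against median + k × (1.4826 × MAD),
which is insensitive to the events themselves inflating the noise
estimate.  Candidate intervals separated by sub-threshold gaps up to
``merge_gap_s`` are merged (so a spike-and-wave train stays one event)
and intervals shorter than ``min_duration_s`` are discarded.

Each interval is then classified from its duration and constituent
sharp transients:

* 1–2 spikes, shorter than ``polyspike_max_s``  → interictal spike
* >= 3 spikes, shorter than ``seizure_min_s``   → polyspike
* >= ``seizure_min_s`` with sustained rhythmic spiking
  (>= ``seizure_min_rate`` spikes/s)            → seizure

The rules are explicit so the pipeline is reproducible end to end;
they are a deterministic automation of criteria that are applied by
eye in chronic-recording studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import EcogRecording, RunConfig


@dataclass
class EpileptiformEvent:
    """A detected event with per-channel trace slices.

    ``start``/``end`` are a half-open sample interval on the session;
    slices cover exactly that interval on all three channels.
    ``spike_times`` are absolute sample indices of the constituent
    sharp transients.
    """

    type: str
    start: int
    end: int
    focus: np.ndarray
    d1mm: np.ndarray
    d2mm: np.ndarray
    spike_times: np.ndarray
    sampling_rate: float

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def robust_threshold(x: np.ndarray, k: float) -> float:
    """median + k × 1.4826 MAD of the rectified signal."""
    r = np.abs(x)
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    return med + k * 1.4826 * mad


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    recording: EcogRecording, params: RunConfig | None = None
) -> list[tuple[int, int]]:
    """Return sorted, disjoint candidate intervals on the focus channel."""
    params = params or RunConfig()
    x = recording.channels["focus"]
    if len(x) == 0:
        raise ValueError("empty recording")
    fs = recording.sampling_rate
    thr = robust_threshold(x, params.threshold_k)
    mask = np.abs(x) > thr
    runs = _runs(mask)
    if not runs:
        return []

    gap = int(round(params.merge_gap_s * fs))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = int(round(params.min_duration_s * fs))
    return [(s, e) for s, e in merged if e - s >= min_len]


def extract_spike_times(
    focus_slice: np.ndarray, threshold: float, fs: float, refractory_s: float
) -> np.ndarray:
    """Suprathreshold sharp-transient peaks, >= refractory gap apart."""
    distance = max(int(round(refractory_s * fs)), 1)
    peaks, _ = find_peaks(np.abs(focus_slice), height=threshold, distance=distance)
    return peaks


def classify_event(
    recording: EcogRecording,
    interval: tuple[int, int],
    params: RunConfig | None = None,
    threshold: float | None = None,
) -> EpileptiformEvent:
    """Classify one detected interval; total over valid intervals."""
    params = params or RunConfig()
    start, end = interval
    n = recording.n_samples
    if not (0 <= start < end <= n):
        raise ValueError(f"interval {interval} outside recording of {n} samples")
    fs = recording.sampling_rate
    focus = recording.channels["focus"][start:end]
    if threshold is None:
        threshold = robust_threshold(recording.channels["focus"], params.threshold_k)
    spikes = extract_spike_times(focus, threshold, fs, params.spike_refractory_s)
    dur = (end - start) / fs
    rate = len(spikes) / dur if dur > 0 else 0.0

    if dur >= params.seizure_min_s and rate >= params.seizure_min_rate:
        etype = "seizure"
    elif len(spikes) >= 3:
        etype = "polyspike"
    else:
        etype = "interictal_spike"
    # guard the definitional bounds: a 1–2 spike event longer than the
    # polyspike ceiling is still closest to a polyspike-class discharge
    if etype == "interictal_spike" and dur >= params.polyspike_max_s:
        etype = "polyspike"

    return EpileptiformEvent(
        type=etype,
        start=int(start),
        end=int(end),
        focus=focus,
        d1mm=recording.channels["d1mm"][start:end],
        d2mm=recording.channels["d2mm"][start:end],
        spike_times=spikes + start,
        sampling_rate=fs,
    )


def detect_and_classify(
    recording: EcogRecording, params: RunConfig | None = None
) -> list[EpileptiformEvent]:
    """Detection followed by classification, sharing one threshold."""
    params = params or RunConfig()
    thr = robust_threshold(recording.channels["focus"], params.threshold_k)
    return [
        classify_event(recording, iv, params, threshold=thr)
        for iv in detect_events(recording, params)
    ]


def match_events(
    detected: list[tuple[int, int]],
    truth: list[tuple[int, int]],
    min_overlap: float = 0.5,
) -> tuple[float, float]:
    """(recall, precision) of detected vs ground-truth intervals.

    A pair matches when their overlap covers at least ``min_overlap``
    of the shorter interval; each truth interval matches at most one
    detection.
    """
    if not truth:
        return (float("nan"), 0.0 if detected else float("nan"))
    used: set[int] = set()
    hits = 0
    for ts, te in truth:
        for j, (ds, de) in enumerate(detected):
            if j in used:
                continue
            ov = min(te, de) - max(ts, ds)
            if ov > 0 and ov >= min_overlap * min(te - ts, de - ds):
                used.add(j)
                hits += 1
                break
    recall = hits / len(truth)
    precision = len(used) / len(detected) if detected else float("nan")
    return recall, precision
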