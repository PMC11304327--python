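# Methods

`ecogprop` analyses chronic three-electrode electrocorticography (ECoG)
from a focal-epilepsy model: one electrode over the seizure focus and
two more at 1 mm and 2 mm.  The question it quantifies is whether each
epileptiform event *propagates* from the focus to the distal
electrodes, and how an intervention (a circumscribing sub-surface
laser cut) changes the propagated fraction over weeks.  This note
documents the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Pipeline overview

1. **Detection** (`detection`).  Events are intervals where the
   rectified focus signal exceeds a robust threshold
   `median + k · 1.4826 · MAD` (default `k = 6`), computed per session.
   The MAD-based scale is used because the events themselves would
   inflate a naive SD.  Sub-threshold gaps up to `merge_gap_s = 1 s`
   are merged so a spike-and-wave train stays one event; intervals
   shorter than `min_duration_s = 30 ms` are dropped.  Saturated
   (clipped) samples are retained at this stage — saturation is
   handled later, at the metrics stage only — so powerful seizures
   stay detectable.

2. **Classification** (`detection`).  Deterministic rules replace the
   by-eye criteria used in chronic-recording practice: 1–2 sharp
   transients and < 1 s → interictal spike; ≥ 3 transients and < 10 s
   → polyspike; ≥ 10 s with sustained spiking (≥ 1 spike/s) →
   seizure.  Sharp transients are suprathreshold peaks of the
   rectified slice separated by a 60 ms refractory gap.  The rules are
   a documented stand-in, not a reconstruction of any particular
   curation protocol; category counts on real data are approximate by
   construction.

3. **Propagation scoring** (`propagation`).  Each event's profile is
   the pair of zero-lag Pearson correlations `(r_1mm, r_2mm)` between
   the focus slice and each distal slice over the full event interval,
   on raw (unfiltered) traces.  No lag search is performed: inter-
   electrode conduction delays are far shorter than event durations,
   and delays are measured separately from band-power envelopes.  A
   constant distal slice yields `r = 0` by convention and is flagged.
   A focus-channel sample is saturated when `|x| ≥ 0.999 · rail` (the
   0.999 absorbs quantization after unit conversion); events whose
   saturated focus fraction strictly exceeds 10% are excluded from
   power metrics but kept for clustering, since clipping corrupts
   power much more than it corrupts the correlation geometry.

4. **Clustering** (`clustering`).  Events are pooled across animals
   (per event type) and clustered in the `(r_1mm, r_2mm)` plane with
   `k = 3` under a per-cluster Mahalanobis metric.  The fit is a hard
   EM: assign each point to the cluster minimizing
   `d²_Σc(x, µc) + log det Σc` (the equal-weight Gaussian
   classification score), then refit means and covariances with
   `1e-6 · I` regularization, until assignments stabilize.  The
   log-determinant term matters: with bare minimum-distance assignment
   the within-cluster distance is *not* monotone across iterations,
   because the covariance refit renormalizes the metric (the mean
   squared Mahalanobis distance of a cluster returns to the dimension
   after every MLE refit).  With the log-det term the objective is a
   negative classification log-likelihood and decreases provably; for
   clusters of equal covariance volume the two assignments coincide,
   and for identity covariances both reduce to Euclidean.

   Initialization is deterministic: a farthest-first traversal (first
   anchor at the point farthest from the data mean, then greedy
   max-min), each anchor smoothed to the mean of its ≈ n/50 nearest
   neighbours, followed by a short Euclidean Lloyd warm start (≤ 10
   iterations) before the covariance-adaptive phase.  This choice came
   out of failure analysis: quantile-based anchors (90th/10th/50th
   percentile corners) land inside the dominant cloud when the
   propagated cluster holds only ~5% of events — exactly the
   laser-cut situation — and the small cluster is absorbed; and
   without the Lloyd warm start the covariance-adaptive phase can lock
   onto a poor vertical split of heavily overlapping clouds.  With
   both, the fit recovers 80/7/13 and 5/60/35 mixtures essentially
   perfectly at n = 2,000.  A percentile-anchor initialization remains
   available (`init="percentile"`).

   With `k = 3` clusters are named by mean `r_1mm + r_2mm`: highest →
   `propagated`, lowest → `nonpropagated`, middle → `attenuated`.
   Other `k` return index labels only.

5. **Power metrics** (`metrics`).  Band power is the 0–50 Hz integral
   of a Hann-tapered short-time periodogram: 1-s windows, 0.5-s hop
   (≥ 1 Hz resolution; a pure in-band tone of amplitude A gives
   ≈ A²/2).  Events shorter than one window use a single untapered
   window.  Per event: duration; maximum band power; AUC — the
   trapezoidal integral of the band-power series extended flat from
   the first/last window centers to the event edges, so constant power
   P over T seconds integrates to exactly `P·T` and splits at
   non-overlapping window boundaries are exactly additive; distal
   metrics normalized by the focus value (absent when the focus value
   is zero).  Arrival per channel is the first window whose band power
   exceeds that channel's session threshold — the session-wide mean
   band power plus one SD, per channel because channel noise floors
   differ — and the propagation delay is distal arrival minus focus
   arrival, absent when either never crosses.

6. **Cohort statistics** (`cohort`).  Daily summaries count events per
   type and per cluster and report percent propagated and propagated
   seizures per day (counts scale to per-day rates by the session
   length).  Per-animal propagation averages *session-level*
   percentages rather than pooling events, so high-incidence sessions
   do not dominate; zero-seizure sessions contribute no percentage
   (avoiding 0/0) but still contribute counts.  Group comparisons:
   two-sample Kolmogorov–Smirnov on correlation distributions
   (asymptotic p at the effective sample size) and the Pearson χ² test
   of group × cluster association.  `percent_reduction(a, b) =
   100·(a−b)/a`.  Weekly centroid tracks connect per-week geometric
   medians of `(r_1mm, r_2mm)` (Weiszfeld iteration with the
   Vardi–Zhang coincident-point correction, tolerance 1e-9); weeks
   with fewer than ten seizures are flagged excluded.  One 24-h
   recording per week makes the per-day and per-week exclusion
   coincide, and the package treats them as such.

   Density summaries use a Gaussian KDE with Silverman bandwidth per
   axis; contours are extracted at fractions of the peak density
   (defaults 0.80 and 0.33) on a regular grid over [−1, 1]².

## Synthetic cohort generator

The generator (`synthetic`) emulates the study's recording conditions
so every stage is testable without the deposited data.  Defaults are
the study conditions: 24-h weekly sessions (`--session-minutes`
overrides for desk-scale work, with daily rates scaled), 500 Hz
sampling, a 5,000 µV amplifier rail, and per-day Poisson event
incidence of 52 seizures / 363 interictal spikes / 274 polyspikes in
epilepsy controls and 46 / 600 / 363 with a single laser cut (double
cuts 5 and 3 seizures/day; non-epileptic controls near zero).  Event
intervals are rejection-resampled to be pairwise disjoint with ≥ 2.5 s
separation.

Morphologies: seizures are amplitude-modulated spike-wave trains whose
fundamental is at the rhythm rate (3–8 Hz, 12–30 s, 400–1200 µV);
polyspikes are runs of ≥ 3 sharp transients (0.3–0.9 s); interictal
spikes are single biphasic derivative-of-Gaussian transients
(50–100 ms).  Amplitude ranges sit 10–60× above the 20 µV 1/f
background so detection operates at realistic SNR.

Propagation regimes set the distal channels:
`distal = gain × delayed focus + white noise`, with per-event gains
and noise drawn from presets — propagated (gain 0.85–0.95 at 1 mm /
0.75–0.85 at 2 mm, noise 0.15–0.30 of the focus SD), attenuated
(0.50–0.70 / 0.20–0.30, noise 0.50–0.80), nonpropagated (0.02–0.08 /
0.01–0.04, noise 0.50–0.80).  These reproduce the characteristic
correlation-plane geometry — a tight high-correlation cloud near
(0.95, 0.93), a decaying intermediate cloud near (0.66, 0.36), and a
near-zero cloud — and follow the closed form
`E[r] = g·σs / sqrt(g²σs² + σn²)`.  They are presets chosen for that
geometry, not measured physiology.  Default inter-channel delay is
zero so the zero-lag correlation reflects the regime geometry;
non-zero delays are available and are used when testing arrival-delay
recovery.  Saturation is modelled by hard clipping at the rail, and a
configurable fraction of seizures is rescaled so that a target 12–30%
of in-event samples clip.

What the generator does *not* model: biophysical seizure dynamics,
spatial fields beyond three point electrodes, electrode drift,
artifacts (movement, chewing, line noise), state-dependent incidence,
or epileptogenesis beyond configurable weekly rates.  Passing tests
therefore demonstrate that the pipeline recovers known structure under
controlled conditions — they do not certify detector performance on
real recordings, where the classification rules in particular would
need validation against curated data.

## Numerical choices and degenerate inputs

* Intervals are half-open `[start, end)`, 0-based samples; amplitudes
  are µV everywhere; time is samples internally, seconds at
  interfaces.
* Channel identity travels by label (`focus`, `d1mm`, `d2mm`), never
  by order.
* The EDF writer emits 16-bit records (1-s blocks, physical range
  ± rail); round-trips are exact for the binary-array format and
  within one quantization step (`2·rail/65535`) for EDF.  Reading goes
  through MNE, which doubles as an independent check of the writer.
* Correlation of a constant distal slice is 0 (flagged); a constant
  focus slice raises a named error.
* Cluster covariances get `1e-6` on the diagonal; clusters falling
  below 3 points keep their center and fall back to the pooled
  covariance.
* The Weiszfeld iteration caps at 10,000 iterations, tolerance 1e-9.
* Saturation exclusion is strictly-greater: an event at exactly the
  10% boundary is retained.
* Seeds: every stochastic routine takes an explicit seed; session and
  event seeds derive from it, so identical (config, seed) reproduce
  sessions and tables byte-for-byte.

## Desk-scale problem sizes

The validation suite and the reproduction script run the same code as
a full cohort but at sizes a laptop handles comfortably: simulated
sessions of 5–20 minutes (with per-day rates scaled), mixture-recovery
cohorts of 2,000 events, and 1,000-instance oracle sweeps for the
statistical primitives.  The analysis drivers default to 60-minute
sessions, two animals per group and three weeks; all sizes are flags.

## Known limitations

* The classification rules are deterministic surrogates for manual
  curation; absolute category counts on real data will differ.
* Zero-lag correlation underestimates propagation when conduction
  delays approach the waveform autocorrelation width; the generator's
  default zero delay sidesteps this, real data may not.
* KDE contour radii inherit sampling noise of the peak-density
  estimate; near the flat density top (high contour levels) this
  noise is amplified roughly as `Δr/r ≈ Δf/(2f·(−ln L))`.
* Mixture-recovery accuracy depends on the regime presets' separation;
  heavily overlapping real-world clouds would lower agreement, as the
  SD-0.12 overlap example (~98%) indicates.
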