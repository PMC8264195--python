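# Methods

This note records the models behind `stimfire`, the defaults that matter,
the choices made where the underlying experimental conventions leave room,
and what the synthetic benchmarks do and do not demonstrate.

## Burst detection and the generative burst model

**Detector.** The two-threshold interspike-interval (ISI) rule: a burst
opens at the first of two spikes with ISI < 80 ms while no burst is open;
an open burst absorbs spikes until an ISI > 160 ms occurs (the second spike
of that interval is outside the burst). Both comparisons are strict, so an
ISI of exactly 80 ms does not open a burst and exactly 160 ms does not
terminate one; ISIs in (80, 160] ms continue an open burst but never open
one. A burst still open at the end of the recording closes at the last
spike — no termination interval exists there, and discarding the tail would
bias %SIB downward. Both thresholds are configurable
(`BurstDetectorConfig`).

**Generator.** Spike trains are drawn from an alternating renewal process:
each *event* is a burst with probability `q` (length `L = 1 + Geometric(p)`
with minimum 2 and mean `m`, so `p = 1/(m−1)`), otherwise a single spike.
Within-burst ISIs are uniform on [50, 70] ms — strictly below the onset
threshold — and events are separated by a 200 ms minimum gap plus an
exponential excess — strictly above the termination threshold. The
detector therefore recovers generated bursts exactly, and the generative
percent of spikes in bursts has the closed form

```
%SIB = 100 · q·m / (q·m + (1 − q)) ,
```

with expected spike rate `event_rate · (q·m + 1 − q)`. The exponential
excess is solved from the requested event rate
(`1/rate − min_gap − q·(m−1)·E[ISI]`), and parameters whose excess would be
non-positive are rejected — the process cannot reach arbitrarily high
rates while keeping gaps above 200 ms (the ceiling is ≈ 12–13 spikes/s for
strongly bursty settings). `BurstTrainParams.from_firing_targets` inverts
the closed forms so a train can be generated directly at a target
(%SIB, spikes/burst, rate) triple.

The uniform/shifted-exponential choices deliberately keep all generated
intervals away from the 80/160 ms boundaries so recovery tests measure the
statistics, not boundary tie-breaking. Real DA-neuron ISI distributions
put mass near those boundaries; the brute-force oracle-equivalence tests
(random trains with ISIs concentrated around 79–81 and 159–161 ms) cover
that regime instead.

## PSTH and epoch detection

PSTHs accumulate counts over all trials in 5 ms half-open bins, with 500 ms
pre-stimulus (100 baseline bins) and 500 ms post-stimulus windows (both
configurable). Baseline mean μ and SD σ are computed across the baseline
bins; the SD uses the sample (n−1) formula.

**Excitation.** Threshold μ + 2σ. The epoch onset is the first
post-stimulus bin that *leads* a sustained crossing: the 5-bin window
starting there has mean above threshold **and** its first two bins each
exceed threshold individually. The window-mean condition rejects isolated
noise bins; the leading-edge anchor pins the onset to the front of the
elevated activity. A pure sliding-window-mean rule was rejected because a
window first exceeds threshold up to four bins *before* the response
starts (once enough elevated bins overlap it), a deterministic early-onset
bias of up to 20 ms that would corrupt the short-/long-latency split. The
offset (exclusive) is the first later bin whose 5-bin running mean is back
within 2σ; if activity never returns, the epoch runs to the end of the
analysis window. A zero-σ baseline is refused unless explicitly overridden
(the threshold then collapses to the mean).

**Inhibition.** Threshold 0.65 μ (i.e. at least 35% below baseline). The
epoch is the earliest, then longest, stretch of ≥ 15 consecutive bins whose
*mean* count is below threshold and whose first and last bins are
themselves below it. The per-epoch-mean reading keeps detection robust at
realistic counts (a per-bin rule would demand 15 consecutive sub-threshold
Poisson draws and miss most genuine epochs); the edge anchors stop the
epoch from swallowing leading or trailing baseline bins, which would
otherwise shift onsets and inflate epoch lengths.

**Onset-latency window.** Both detectors only open epochs within 150 ms of
the pulse (configurable). Evoked responses in this preparation are
stimulus-locked with onsets of tens of milliseconds; the window also
controls the multiple-comparisons problem of the 35%/15-bin rule, which on
a flat 100-bin PSTH with a few counts per bin would otherwise find a
spurious "suppressed" window at a few percent per neuron.

**Rmag.** `Rmag_raw = Σ counts(epoch) − μ·n_bins` (negative for
inhibition); the normalized form divides by μ ("normalized to baseline")
and is flagged undefined for silent baselines. The divisor is recorded in
the configuration, not hard-coded into downstream tables.

**Classification.** No epoch → no response; excitation splits at a 20 ms
onset boundary (boundary ≤ 20 ms counts as short-latency; the boundary is a
package choice, configurable, as the convention is not standardized); when
both epoch kinds are present the earliest onset wins (tie to excitation)
and all epochs are retained in the output.

## Evoked-response generator and the default baseline

Each simulated neuron is a baseline burst train plus per-pulse modulation:
excitation adds Poisson spikes at `(gain − 1) ·` baseline rate inside
`[onset, onset + duration)` after every pulse; inhibition deletes baseline
spikes there with probability equal to the suppression fraction; outside
the epochs the baseline process is untouched. Default archetypes: short
onsets at 5 ms, long onsets drawn from the 25–50 ms grid in 5 ms steps
(bin-aligned so detected onsets are unambiguous), 75 ms excitation epochs,
150 ms inhibition epochs, gain 5 and suppression 0.8 as the "strong effect"
defaults.

The default baseline for population simulations is a strongly bursty train
of ≈ 12.4 spikes/s — about 3.1 baseline counts per bin over 50 trials.
This is the upper end of what the renewal generator supports and was chosen
by a power analysis of the epoch rules: with 50 trials fixed by the
protocol, the 35%-below-baseline inhibition criterion needs roughly ≥ 3
counts/bin for its false-detection rate on flat PSTHs to be negligible, and
the 2σ excitation rule needs similar counts for near-certain single-bin
detection at gain 4–5. At these settings the classifier recovers a
55-neuron population's archetypes with ≈ 99.9% per-neuron accuracy
(measured over 30 seeds at the weaker gain-4/0.7 setting). Slow 2–3 spikes/s
baselines — typical of real DA neurons — leave these published rules
noise-limited at 50 trials; that is a property of the rules, not of the
implementation, and classification of weak-baseline units should be read
with that caveat.

## Behavior metrics

Zone occupancy attributes the interval between consecutive samples to the
zone of the interval's first sample, so zone times partition the session
exactly; path segments are attributed the same way. An entry is a maximal
in-zone run of at least `dwell_min` samples (default 1; a session starting
inside the zone counts one entry). Specific conventions:

* The open-field central zone is a concentric square of 50% linear extent
  (20 × 20 cm in the 40 cm field) — the apparatus marks the zone with lines
  but its size is not standardized, so it is configurable.
* "Zone crossings" are center/periphery boundary transitions between
  consecutive samples.
* The EPM "45 cm diameter" arms are modelled as 45 cm long, 15 cm wide,
  around a 15 cm central platform. An *arm entry* requires the tracked
  centroid to penetrate 5 cm (configurable) past the platform edge — a
  centroid proxy for the four-paw criterion, which cannot be evaluated
  from centroid tracking; re-entry requires leaving the arm entirely.
  Open-arm *time* counts any sample in the arm regardless of depth.

The trajectory generator is a discrete-time biased random walk: the step
direction is a unit vector of `bias · (unit vector toward the target zone)
plus 2-D standard normal noise`, scaled to `speed · dt`; steps leaving the
arena are resolved by axis-wise projection (a reflection-style wall rule
that keeps the walk inside the plus-maze's non-convex footprint). Occupancy
of the target zone is monotone in the bias and approaches 1 in the strong-
bias limit. Defaults: 900 s sessions, 10 Hz sampling, 3 cm/s mean speed
(≈ 27 m per session, a typical rat's travel). The walk has no thigmotaxis,
rearing, or pause/run structure; it validates the *metric computations*,
not rodent behavior.

## Group statistics

Textbook sums-of-squares forms: one-way ANOVA `F = MS_b/MS_w` with df
(k−1, N−k); Fisher's LSD `t = (m_i − m_j)/√(MS_w(1/n_i + 1/n_j))` on N−k
df using the pooled within-group mean square; Pearson chi-square without
continuity correction, df (r−1)(c−1); paired `t = mean(d)/(sd(d)/√n)`.
P-values are two-sided throughout and no multiplicity correction is applied
beyond LSD's own logic, matching the reporting conventions of this
literature. Zero within-group (or difference) variance is flagged
degenerate rather than silently producing an infinite statistic; summaries
are reported as mean ± SEM. The per-rat table generator draws from
per-group normal distributions — printed mean ± SEM (× √n) is treated as
that normal model without any claim of distributional fidelity, since only
those two moments are ever reported.

In the %SIB stimulation contrast, neurons are the paired units within each
group (baseline segment = everything before the first pulse, required
≥ 5 min; stimulation segment = the pulse-train span); whether such designs
should instead nest neurons within animals is a modelling question outside
this package's scope.

## Determinism and problem sizes

Every generator takes an explicit integer seed and derives per-neuron child
seeds through `numpy` seed sequences; no global random state is touched,
and identical configuration reproduces byte-identical output files. The
recovery benchmarks use 20 × 300 s trains per setting (≈ 14,000 spikes),
a 55-neuron population under the 50-pulse 0.5 Hz protocol, 500 random
trains / 200 random PSTHs for oracle equivalence, and 2,000 replicates for
the type-I-error check — sizes at which Monte-Carlo error is comfortably
inside the stated tolerances while the whole suite runs in seconds.

## Known limitations

* Waveform features are generated and assessed as scalars only; no voltage
  waveforms are synthesized, and spike sorting is out of scope.
* The published DA-neuron rate criterion is printed as "slow … > 10
  spikes/s"; the package defaults to the standard slow reading (< 10
  spikes/s) with threshold and direction configurable.
* Excitation-offset detection uses a single running-mean return; a
  sustained-return requirement (several consecutive sub-threshold windows)
  is not implemented.
* The renewal generator cannot produce spike rates above ≈ 13 spikes/s
  (the 200 ms gap floor), so fast-firing, GABA-like activity cannot be
  emulated — consistent with such units being excluded from the analyses.
* The chi-square and ANOVA implementations are fixed-effects only; no
  mixed models, repeated measures, or non-parametric alternatives.
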