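# stimfire

Analysis tool-kit for a classic systems-neuroscience experiment: *in vivo*
extracellular single-unit recordings of ventral tegmental area (VTA)
dopamine neurons while single electrical pulses are delivered to the
ventromedial prefrontal cortex (vmPFC), combined with open-field (OFT) and
elevated-plus-maze (EPM) anxiety assays and the group-level statistics that
tie them together. It is aimed at electrophysiologists and behavioral
neuroscientists who want the standard spike-train and trajectory metrics as
tested, scriptable building blocks — plus a synthetic-data generator that
gives every analysis stage a known ground truth, so the whole pipeline is
verifiable without any recordings.

## What it computes

**Burst analysis (Grace–Bunney criterion).** A burst opens at the first of
two spikes with an interspike interval < 80 ms and closes at the first
interval > 160 ms. The headline statistic is the percentage of spikes in
bursts,

```
%SIB = 100 · (spikes inside bursts) / (all spikes),
```

reported alongside firing rate (spikes/10 s) and mean spikes per burst.

**Evoked-response classification.** For each neuron a cumulative
peri-stimulus time histogram (PSTH; 5 ms bins, 500 ms baseline and analysis
windows, 50 trials) is built around the pulses. With baseline mean μ and
sample SD σ per bin, an excitation epoch starts at the first bin leading a
sustained crossing above μ + 2σ and ends when the 5-bin running mean
returns within 2σ; an inhibition epoch is ≥ 15 consecutive bins whose mean
count is ≥ 35% below μ. Response magnitude is

```
Rmag = Σ counts(epoch) − μ · n_bins ,    Rmag_norm = Rmag / μ ,
```

and each neuron is labelled short-latency excitation (onset ≤ 20 ms),
long-latency excitation, inhibition, or no response.

**Behavior.** OFT central-zone time/distance/entries, total distance and
zone crossings on a 40 cm field; EPM open-arm time, percent time and
entries (centroid ingress-depth proxy for the four-paw rule) — all from
plain `(t, x, y)` tracking CSVs.

**Group statistics.** Closed-form one-way ANOVA, Fisher's LSD post hoc,
Pearson chi-square on response-type proportions, and paired t-tests (e.g.
%SIB baseline vs stimulation), reported as mean ± SEM.

**Synthetic data.** Burst trains from an alternating renewal process with a
closed-form generative %SIB; stimulus-locked excitation/inhibition kernels
for the four response archetypes; biased-random-walk arena trajectories
with monotone occupancy control; per-group normal metric tables (4 groups ×
n = 8). All generators are seed-deterministic.

## Worked example

```python
import stimfire as sf

# one synthetic DA neuron at the PTSD-group firing profile
params = sf.BurstTrainParams.from_firing_targets(
    pct_sib=31.2, spikes_per_burst=3.0, rate_per_10s=29.8, duration_s=300.0, seed=42
)
train = sf.simulate_burst_train(params)
summary = sf.summarize_bursting(train, sf.detect_bursts(train))
print(f"firing rate : {summary.firing_rate_per_10s:.1f} spikes/10 s")
print(f"%SIB        : {summary.pct_sib:.1f} %")
print(f"spikes/burst: {summary.mean_spikes_per_burst:.2f}  ({summary.n_bursts} bursts)")

# one evoked neuron under the 50-pulse 0.5 Hz protocol
records = sf.simulate_population({"long_latency_excitation": 1}, seed=3)
response, psth, base = sf.classify_train(records[0]["train"], records[0]["stim"])
epoch = response.epochs[0]
print(f"label       : {response.label}")
print(f"onset       : {epoch.onset_latency_ms:.0f} ms, epoch {epoch.n_bins} bins")
print(f"Rmag (norm) : {epoch.rmag_norm:.2f}")
```

prints

```
firing rate : 30.4 spikes/10 s
%SIB        : 34.5 %
spikes/burst: 3.18  (99 bursts)
label       : long_latency_excitation
onset       : 50 ms, epoch 15 bins
Rmag (norm) : 63.64
```

A single 300 s train scatters around its generative targets (31.2%, 3.0,
29.8/10 s) with the expected Monte-Carlo spread; averaging 20 trains
recovers them to within a fraction of a point. The evoked neuron was
generated as a long-latency responder and is classified back as one, with
its detected onset on the 25–50 ms grid the generator draws from.

The same operations are available from a shell:

```bash
stimfire simulate population --composition 24,7,20,4 --seed 1 --out-dir pop
stimfire analyze evoked --spikes pop/spikes.csv --stim pop/stimulus.csv --out results
stimfire run --seed 1 --out-dir full_run     # simulate -> analyze -> stats -> report
```

## Layout

| module | contents |
| --- | --- |
| `stimfire.core` | `SpikeTrain`, `StimulusTrain` containers |
| `stimfire.bursting` | burst detection, %SIB, DA-neuron qualification |
| `stimfire.evoked` | PSTH, epoch detection, Rmag, 4-way classification, %SIB contrast |
| `stimfire.behavior` | arena geometry, OFT/EPM metrics |
| `stimfire.stats` | ANOVA, Fisher LSD, chi-square, paired t |
| `stimfire.synthetic` | all generators with ground-truth sidecars |
| `stimfire.pipeline` / `stimfire.cli` | end-to-end runs, YAML config, `stimfire` CLI |

See `docs/methods.md` for the models, the default parameters and why, and
known limitations.
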