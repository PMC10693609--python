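# Methods

This note documents the models, rules and numerical choices implemented in
`biomk`, and what the synthetic data can and cannot establish.

## Signal chain

Recordings are channels × samples matrices in microvolts. Clinical-style
acquisition is emulated end to end: signals referenced to a common contact are
re-referenced to a bipolar montage (anode − cathode, labelled "A-B"), and
4000 Hz acquisitions are decimated to 2000 Hz behind a zero-phase FIR low-pass
cutting at 0.8× the new Nyquist frequency (Kaiser design, 80 dB). Time is in
seconds from recording start; analysis intervals are half-open
[start, start+duration).

Interval selection keeps only five-minute intervals lying at least three hours
from every seizure, capped at six per night (earliest first); the function is
idempotent. For mesial-temporal depth electrodes only the three most mesial
bipolar channels enter the analysis; eloquent-cortex contacts are removed via
an exclusion list supplied by the caller (no evoked-response analysis is
performed).

EDF is the on-disk signal format (16-bit, physical units µV, one-second data
records). The writer is a minimal EDF implementation in this package; reading
goes through `mne`, so round-trip tests cross two independent code paths.
EDF export requires an integer sampling rate and a whole number of seconds.

## Band filtering and HFO detection

Ripple band: pass 80–240 Hz, stop 70/250 Hz. Fast-ripple band: pass
250–490 Hz, stop 240/500 Hz. Both are linear-phase FIR equiripple designs
(`scipy.signal.remez`) with ≥ 60 dB stopband attenuation. The design targets a
single-pass passband ripple of ≤ 0.4 dB and grows the filter order until the
measured frequency response complies (557 taps at fs = 2000 Hz), so that the
forward–backward (zero-phase) application used in detection stays within 1 dB
in the passband and leaves event latencies unbiased.

The band-event detector is this package's own documented rule — it is a
simplified stand-in, not a re-implementation of any clinically validated
detector, and is calibrated against planted synthetic events:

1. band-pass filter (zero phase) and take the analytic-signal envelope;
2. baseline = median envelope; robust SD = 1.4826 × MAD;
3. an event is an excursion above the *boundary* threshold
   (baseline + 2 robust SD) that reaches the *peak* threshold
   (baseline + k robust SD, k = 5 default) and lasts at least 4 oscillation
   cycles at the band's geometric-mean frequency √(pass_lo·pass_hi)
   (≈ 29 ms for ripples, ≈ 11 ms for fast ripples);
4. excursions separated by < 10 ms merge; the event peak is the envelope
   maximum.

The two-threshold (hysteresis) form is used because a single supra-threshold
duration criterion referenced to the lower passband edge demands longer
excursions than a Gaussian-windowed burst of realistic duration can sustain
above a 5-SD threshold; the boundary threshold measures the event extent while
the peak threshold controls false positives. At default settings the detector
recovers 100% of planted bursts with ≤ 1 false event/min on pure pink noise
(measured in the test suite and acceptance script).

An **HFO** is a ripple and a fast ripple on the same channel with overlapping
intervals, paired greedily by earliest onset (each constituent joins at most
one HFO); the HFO interval is the union of the pair. A **spike+HFO** is an
HFO whose interval intersects [peak − 50 ms, peak + 50 ms] around a spike
peak on the same channel; pairing is unique on both sides (nearest peak
first), so the count never exceeds either constituent count and shrinking the
window never adds events. Interval intersection rather than HFO-onset
containment was chosen for robustness to HFO duration; both the window and the
rule are configurable.

Spikes are ingested as cursor marks from two reviewers, snapped to the maximum
absolute broadband amplitude within ±50 ms (a flat window keeps the mark), and
fused: marks within 100 ms on the same channel merge at the mean latency;
unmatched marks survive only if flagged consensus-accepted. The peak-search
window is this module's default — the marking procedure it emulates does not
fix one — and is configurable.

## Rates and biomarker areas

Rates are events/min per (channel, biomarker, interval), with pooled rate =
total events / total minutes (equal to the duration-weighted mean of interval
rates; asserted as an invariant). The biomarker area is the set of channels
whose pooled rate **strictly exceeds** the 95th percentile of the pooled rates
over all montage channels. The percentile uses linear interpolation between
order statistics; this choice moves marginal channels and is therefore
explicit and configurable. Because the threshold is a percentile of the rate
values, the area is not "the top 5% of channels": its size depends on the
distribution tail, and with all rates equal it is empty. A biomarker with zero
events has an *undefined* area (`defined = False`), which excludes the patient
from that biomarker's confusion matrix downstream.

The temporal-consistency filter keeps a channel only if its rate exceeds its
interval's own 95th-percentile threshold in ≥ 50% of intervals; it guards the
HFO area against transient artefacts and is applied to the HFO area by default
(the min-fraction of 0.5 is this package's choice). With a single interval the
filter warns and passes everything.

Paired per-patient area sizes (Spike vs HFO) are compared with the two-sided
Wilcoxon signed-rank test, zero differences dropped, exact null for ≤ 25
informative pairs.

## Spike propagation

A spike on channel c at time t leads a spike on channel r ≠ c with peak in
(t, t + W]; W = 100 ms by default (wide enough to cover observed PSTH latency
ranges; configurable). Equal peak times never pair, so leader/follower order
is always defined. By default a receiver spike follows only the earliest
leader whose window covers it (first-leader claiming); an all-pairs variant is
available by flag and is the form checked against a brute-force oracle in the
tests.

Adjacency: A[r, c] = (# leader spikes on c followed by ≥ 1 spike on r within
W) / (# spikes on c), zero diagonal, zero columns for spike-free channels.
Out-strength = column sum, in-strength = row sum.

Communities maximise Newman modularity on w = (A + Aᵀ)/2 via deterministic
greedy agglomeration (`networkx`); when contact coordinates are available,
weights are multiplied by exp(−d/λ) with λ = median inter-contact distance, so
proximity reinforces within-cluster ties. Significance: each permutation
shuffles which channel each spike occurred on — preserving per-channel spike
counts and the full set of spike times, hence all marginal rate structure —
and recomputes the maximal modularity; p = (1 + #{Q_perm ≥ Q_obs})/(1 + n_perm)
(add-one, so p is never zero). n_perm = 1000 by default; < 100 warns.

PSTHs bin receiver-spike latencies after each leader spike into half-open
(lo, hi] bins (10 ms default, up to 200 ms). Graph rendering shows nodes with
spike rate ≥ half the mean rate and edges with weight ≥ a quarter of the
maximum adjacency entry; node diameter ∝ spike rate, node colour ∝
out-strength, arrow width ∝ weight.

## Outcome validation

Patients are classified per biomarker from the area-resected flag and the
ILAE outcome dichotomised at 1 vs 2–6 (see README table). Undefined areas
exclude the patient from that biomarker's matrix only. All five metrics carry
exact Clopper–Pearson 95% CIs (beta-quantile inversion; closed at 0 and 1
when x = 0 or x = n); this interval choice reproduces every printed CI
bracket of the reference cohort to the integer percent, which the tests
verify — the choice is evidence-based, not assumed. A metric with a zero
denominator is reported as undefined, never as zero. Display rounding is
half-up to integer percent.

Accuracy comparison defaults to the unpaired pooled two-proportion z-test
(two-sided normal p; zero pooled variance gives p = 1). Since the same
patients underlie both biomarkers, an exact McNemar test on per-patient
correctness is also provided (`compare_accuracy_paired`); the unpaired test is
the default reporting route.

The fixed 20-patient reference cohort ships as `table1_fixture()`: 13/20
seizure-free; HFO area resected in patients 1–16; confusion matrices
HFO (TP 4, FP 0, TN 13, FN 3), Spikes (5, 6, 7, 2), Spike+HFO (4, 2, 11, 2
with one exclusion).

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults define the simulated recording conditions: 2000 Hz,
five-minute intervals, pink-noise background (sd 5 µV), triangular biphasic
spikes (70 ms, 300 µV, apex at 40% of the waveform), Gaussian-windowed bursts
(ripple 120 Hz/60 ms/20 µV; fast ripple 300 Hz/30 ms/10 µV; σ = duration/6),
spike rate 2/min, ripple 2/min, FR 1/min per channel, P(FR | ripple) = 0.5,
P(HFO | spike) = 0.3. Event counts are Poisson; spikes are thinned to ≥ 0.3 s
spacing per channel so pairing structure stays well defined. Amplitudes and
rates are *configuration*, chosen once as plausible values — clinical
recordings do not pin them down — so passing recovery tests demonstrates
internal consistency of the pipeline at these SNRs, not performance on
clinical data. Follower echoes inherit leader polarity; latencies are normal
(25 ± 5 ms default) truncated at one sample so simultaneity is impossible.
When a leader is configured, independent spikes are planted only on the
leader and followers carry echoes only, making leader/follower ground truth
unambiguous. Not modelled: sleep-stage dynamics, muscle/electrode artefacts
(beyond an optional 50 Hz sinusoid), physiological-vs-pathological HFO
distinction, volume conduction, electrode geometry.

Ground-truth HFO and spike+HFO markers are derived from the planted ripples,
fast ripples and spikes with the same co-occurrence functions the analysis
uses, so truth and detection are directly comparable.

Synthetic cohorts plant a small HFO area (1–3 channels), a strictly larger
spike area, and a spike+HFO area that tracks the HFO area (undefined with
probability 0.05); the resection fully contains the HFO area with probability
0.65. Outcome: deterministically ILAE 1 iff the HFO area is fully resected
(recurrent patients draw ILAE uniformly from 2–6, since only the dichotomy
matters downstream), or with the outcome flipped with probability ε under the
noisy rule. Structure and noise use separate seed streams so cohorts are
identical across ε.

## Problem sizes and determinism

All stochastic tests and the acceptance script are seeded; simulations use
small but statistically adequate sizes chosen as this package's own test
conditions: detection sensitivity on 2 channels × 120 s, false positives on
5 min of noise, co-occurrence recovery on ~350 spikes, leader recovery on
~500 leader spikes (binomial 99% bands), permutation tests at n_perm = 1000
for significance claims (lower for null-uniformity checks). The acceptance
script runs in a few seconds; the test suite in well under a minute.

## Known limitations

* The band-event detector is a documented stand-in; event lists identical to
  any clinically validated detector are out of scope.
* The community-detection operationalisation (symmetrisation, exponential
  spatial kernel, greedy modularity) is one reasonable choice among several;
  the clustering itself, not its exact algorithmic lineage, is the tested
  contract.
* Whether conditional propagation probabilities should condition on leading
  spikes only is configurable (`claim_first`); the default claims each
  receiver spike for its earliest leader.
* The temporal-consistency criterion (fraction 0.5, applied to the HFO area
  only) is a package default, configurable per analysis.
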