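# Methods

`meapheno` implements the multiparametric analysis used to phenotype drug
effects on the spontaneous activity of cultured cortical networks recorded
on microelectrode arrays (MEAs), together with a stochastic generator of
MEA-like activity that provides ground truth for every stage. This note
records the models, the numerical choices, and what the synthetic tests do
and do not establish.

## Burst detection

Each sorted unit's spike train is scanned with a two-threshold interspike-
interval (ISI) rule: a burst *opens* when an ISI ≤ `burst_start_isi_max`
(default 100 ms, configurable 50–150 ms) follows the candidate first spike,
*extends* while ISIs stay ≤ `burst_end_isi_max` (default 200 ms, 100–300 ms),
and *closes* at the first longer ISI. Giving the looser threshold to
continuation only is the single automaton in which both thresholds matter
and end ≥ start is coherent. Bursts need ≥ `burst_min_spikes` (3) spikes —
the smallest count for which intra-burst interval statistics exist. Bursts
straddling an analysis-window edge are discarded rather than truncated, so
duration statistics are unbiased at the cost of at most two events per
window. Because end ≥ start, every burst is confined to one maximal run of
ISIs ≤ end-threshold; the implementation exploits this closed form and is
verified against a literal sequential re-implementation on random trains.

Burst shape is summarized from a spike-density envelope: each spike carries
a unit-mass Gaussian kernel (σ = `kernel_sigma`, 25 ms) evaluated on a 1-ms
grid spanning ±3σ around the burst. The envelope's peak is the burst
**amplitude** (Hz), its integral the **area** (≈ spike count, by kernel-mass
conservation — the integral runs over the full grid, since clipping at the
bare burst bounds would lose half a kernel per edge spike), the time at
≥ half-peak the **plateau** (ms), and amplitude per spike the **spike
density**. In the production path the kernel sum is evaluated by a compiled
routine with support truncated at 5σ (relative error < 4 × 10⁻⁶ against the
exact dense evaluation, which remains available as `burst_envelope`).

Population bursts are single-linkage clusters of unit-burst onsets with a
100-ms link window, kept when ≥ 50% of the window's active units
participate. On a line, single linkage reduces to splitting the sorted
onsets at gaps > link window; this is checked against an O(n²) all-pairs
merge oracle.

## The 40-parameter registry

Thirteen base parameters are computed per unit and 60-s bin: five General
Activity (spike rate, burst rate, % spikes in bursts, burst period,
inter-burst interval) and eight Burst Structure (duration, area, plateau,
amplitude, mean intra-burst ISI, in-burst spike rate, spikes per burst,
per-spike peak density). Three network statistics are derived per base:

* **mean** — grand mean over units of per-unit window means;
* **SD across bins** (Oscillatory Behavior) — sample SD (ddof = 1) of the
  network-mean per-bin value; 0 for perfectly regular activity;
* **CVnet** (Synchronicity) — SD across units of per-unit window means over
  their mean; 0 when all units behave identically, undefined (never
  infinite) at zero mean.

The per-spike density has no CVnet entry; two network-level synchrony
measures — **Syn All** (mean absolute distance of member-burst midpoints
from their population-burst center, ms) and **Spike Simplex** (1-ms bins in
which ≥ 2 distinct units spike, per minute) — complete the forty:
13 + 13 + 12 + 2. Ten of them (spike/burst rate, burst duration/amplitude,
their SDs and CVnets for the rates, Syn All, Spike Simplex) form the
concentration-response curve set. The exact published membership of the
40-parameter panel is not fully reproducible from available sources; this
registry reconstructs it from the four-category scheme and the documented
headline definitions, keeping the counts and taxonomy that downstream
analyses rely on.

Missing values (no bursts in a bin, a single unit, zero native reference)
propagate as missing through normalization and statistics; nothing is
imputed.

## Episodes, QC and normalization

A cumulative-dosing experiment applies rising concentrations to one network;
each episode's analysis window is its final `stable_phase` seconds (default
1800 s — the steady state of a step change; drift detection is deliberately
out of scope because stability was established operationally, not
algorithmically), truncated to whole 60-s bins. Networks enter the analysis
only if ≥ 6 units burst in the native window (inclusive threshold);
acceptance is decided on native activity alone, since later suppression of
bursting is the measured effect. Every parameter is normalized within its
own network to the native value (native ≡ 100%).

## Statistics

Because normalization makes the native member of every within-network pair
exactly 100, the paired comparison of a treated episode against native
reduces algebraically to a one-sample two-sided t-test of normalized values
against 100. Heat-map cells are colored only when p ≤ 0.05, with tiers at
0.05/0.01/0.001 and the color encoding the signed % change. A one-way
repeated-measures ANOVA across concentrations is reported per parameter as
an omnibus companion but does not gate the cells (the cell-level test
is the paired t alone). Between-compound contrasts use Welch's unpaired t.
No multiple-testing correction is applied — the fingerprint is descriptive,
and the output metadata says so. Degenerate inputs take conventions: zero
variance with zero effect gives p = 1; n < 2 is untestable.

## Concentration-response model

Responses (% of native) are fit with a four-parameter logistic on log₁₀
concentration, R(c) = R0 + (Rinf − R0)/(1 + (EC50/c)^h), h > 0, where R0 is
the zero-concentration and Rinf the high-concentration asymptote; direction
is reported as a signed Hill slope. The native point (c = 0) cannot sit on a
log axis and instead anchors R0 = 100 through an extra residual. Fits are
multi-started over a log-EC50 grid × slopes {0.5, 1, 2}; the best residual
sum of squares wins, and data whose fitted span is < 5 percentage points are
reported unconverged rather than given a meaningless EC50. EC50s outside the
tested range ×[1/10, 10] are flagged extrapolated. The default fit pools
per-concentration network means; per-network fits expose EC50 dispersion.

Fold shifts between two conditions are estimated with a *global* EC50-shift
fit: both curves share bottom, top and slope and differ only in log-EC50.
When the shifted curve is truncated by the tested ladder (the combination
experiment reaches only ~2× its shifted EC50), independent free-asymptote
fits ride a (top, EC50) likelihood ridge and overestimate the shift
severalfold; the shared-parameter fit stays identifiable because the
reference curve pins the asymptotes, and it is exactly correct when the
shift is surmountable (same maximal effect, altered potency) — which is how
the generator programs it. The plain EC50 ratio of two independent fits
remains available (`fold_shift`).

## Synthetic activity generator

The generator emulates a mature cortical culture in its population-burst
regime: network burst events follow a gamma renewal process (default 8
events/min, interval CV 0.3); each of 25 units joins an event with
probability 0.9, its burst onset jittered by N(0, 30 ms); spike counts per
burst are Poisson (mean 12, floored at 3) spread over a 300-ms gamma-shaped
packet (shape 2); independent 0.3-Hz Poisson background is superposed; times
are clipped, sorted and deduplicated at the 0.1-ms acquisition resolution.
These defaults reproduce the reported scale of such recordings (~25 active
units, coordinated bursting every few seconds) and give a closed-form
network-mean spike rate, bg + (events/s)·p·spikes_per_burst ≈ 1.74 Hz, used
as a moment check.

Drugs act multiplicatively on generator parameters through Hill multipliers
m(c) = 1 + (max_mult − 1)·c/(c + EC50). The presets encode the qualitative
pharmacology being fingerprinted: muscimol-like pan-GABA_A agonism (EC50
100 nM; event rate ×0.2, burst duration ×0.6, spikes/burst ×0.7, jitter
×0.8), baclofen-like GABA_B agonism (1 μM; rate down but bursts *longer* and
denser — the opposite burst-structure signature), a benzodiazepine-like PAM
(150 nM, a design choice as no published network EC50 exists), THIP (17 μM)
and the δ-selective ago-PAM DS1 (170 nM), plus a combination preset in
which the PAM's EC50 is shifted 30-fold by a trace of DS1 with a constant
0.9× event-rate suppression applied to its drug episodes. Because several
modulated parameters feed one response, a recovered response-EC50 sits
slightly left of the programmed value (analytically ~0.75× for spike rate
under the muscimol preset); the factor-2 recovery tolerance absorbs this
composite-response shift.

What the generator does *not* emulate: voltage traces, spike sorting and
its artifacts, doublets, bursts with internal sub-structure, slow drift,
desensitization, or between-culture heterogeneity beyond seed-to-seed
variation. Passing recovery tests therefore demonstrates that the analysis
chain is correct and well-calibrated on data that match its assumptions —
not that the assumptions hold for any particular biological recording.

## Problem sizes and runtimes

Synthetic experiments in the test suite and analysis drivers use 10-minute
episodes with a 5-minute stable phase — a proportional scaling of the
60/30-minute acquisition protocol that keeps every pipeline stage (binning,
SDs, QC, normalization, fits) fully exercised at interactive runtimes.
Recovery designs mirror the study's arm sizes (7 muscimol, 8 baclofen,
9 THIP, 10 DS1, 9 + 9 for the combination, 12 vehicle). The type-I-error
calibration runs 200 vehicle experiments of 8 networks each at the same
scale. Seeds are fixed everywhere; identical inputs give bit-identical
outputs.

## Known limitations

* Registry membership beyond the documented headline parameters is a
  reconstruction (counts and categories are exact, names may differ from
  the original panel).
* The ISI-threshold automaton is one reading of a two-threshold rule whose
  published description does not fix the exact state machine; the chosen
  rule is the only coherent one we found, and it is config-exposed.
* CVnet-of-ratio parameters are mildly skewed at small per-window burst
  counts, which can inflate paired-t type-I rates in very short windows;
  the calibration suite runs at window sizes where this is negligible.
* No multiple-testing correction, by design parity with the fingerprint
  methodology; a 40-parameter grid at α = 0.05 colors ~2 cells per
  concentration by chance.
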