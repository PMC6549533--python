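# Methods

## Scope and data model

`measync` analyses extracellular recordings from multi-electrode-array
(MEA) wells: a rectangular electrode grid (default 4 × 4, 350 µm pitch)
each yielding a train of spike timestamps over a shared interval.  All
internal times are seconds, distances micrometres.  Time windows are
half-open `[t0, t1)` so adjacent bins never double-count a spike; the only
closed intervals are detected burst events, so a spike exactly at an event
boundary counts as part of the burst.

## Spike detection

A spike is a crossing of ±`k·σ` (default `k = 5.3`) by the deviation of
the raw trace from its median, timestamped at the absolute-amplitude
extremum of the excursion; events closer than a 1 ms dead time are merged
into the earlier one so one multiphasic waveform is never counted twice.
`σ` is the baseline-noise SD estimated robustly, by default from the
median absolute deviation (`MAD / 0.6745`), which is parameter-free and
insensitive to sparse spikes; an alternative estimator takes the sample SD
over the calmer half of 100 ms segments ("quiescent periods").  Both
agree within a few percent on Gaussian noise contaminated by spikes.  The
threshold is applied to the absolute deviation (single σ for both
polarities); with a dominant-negative biphasic waveform the practical
difference from per-polarity thresholding is negligible at `k = 5.3`
(two-sided Gaussian exceedance ≈ 1.2 × 10⁻⁷ per sample, i.e. ≪ 1 false
positive per second even at 20 kHz).

## Synchronized burst firing (SBF) detection

An SBF is an array-wide event in which many electrodes fire densely for a
fraction of a second.  Detection is a four-step histogram procedure with
every threshold exposed in `SBFParams`:

1. bin all spikes across electrodes (100 ms bins);
2. mark candidate bins with total count ≥ `min_total_count_per_bin` *and*
   ≥ `min_electrodes_per_bin` (default 4 of 16) electrodes active;
3. merge candidate runs separated by silent gaps shorter than 300 ms;
4. discard events shorter than 200 ms or containing fewer than 40 spikes.

The adaptive count threshold defaults to **4 × the median per-bin count,
floored at 10**.  The median tracks the sporadic background; a mean-based
threshold is inflated by the bursts themselves and, when burst frequency
and per-burst spike content trade off across protocol epochs (see the dose
model below), can rise above the intensity of diluted bursts and suppress
the very effect under study.  Detected events are finally padded by one
bin (`edge_pad = 0.1 s`, clamped below half the merge gap so events can
never overlap): burst-onset jitter places burst stragglers in the
sub-threshold flanking bins, and without padding ≈ 7 % of burst spikes
leak into the sporadic class and contaminate sporadic-class synchrony.

Spikes inside a (closed) event interval are classified *burst*, all others
*sporadic*; the partition is exhaustive and exclusive.  An *active
channel* is an electrode with ≥ 1 Hz sporadic rate; across-electrode
sporadic-rate summaries average over active channels only.

## Surrogate-null synchrony Z-score

Two spikes on different electrodes synchronize when they fall strictly
within 100 ms of each other.  The count `N_real` for a pair is the number
of unordered cross pairs within the window — a symmetric, order-free
convention whose scale the surrogate normalization absorbs — computed by a
sorted sweep in `O(n log n)` and verified in tests against exhaustive
`O(n²)` enumeration.  The null is built by independently permuting each
train's interspike-interval (ISI) sequence (both trains of the pair, to
keep the null exchangeable), anchoring the first spike so count, first and
last spike time and the ISI multiset are preserved.  With 100 surrogate
draws,

    Z = (N_real − Ave_surrogate) / SD_surrogate ,

where the SD is the sample SD (ddof = 1) of the surrogate counts.  A pair
with zero surrogate spread (e.g. single-spike trains) has no defined Z and
is flagged and excluded from every downstream summary rather than given an
infinite score.  A connection is called significant at `Z > 2.58`, the
two-sided standard-normal critical value at α = 0.01.

Calibration on independent stationary Poisson trains (15 min, 5 Hz) gives
a pair-Z distribution with |mean| ≤ 0.15 and SD ≈ 1; the surrogate null is
approximate, not exactly standard normal, so these bands are asserted in
tests rather than assumed.

**Known bias.** ISI shuffling preserves each train's rate profile only on
average.  When burst intervals are removed from *both* trains of a pair,
the remaining spikes share correlated silent gaps that the shuffle
destroys, so sporadic-class Z acquires a positive floor that grows with
the fraction of time excised (≈ +4 SD at this generator's default burst
load, 0.06 Hz × ~1.2 s events).  This is a property of the published
procedure, not of this implementation — empirical distance profiles from
such analyses also sit above zero at all distances.  Where a clean
above/below-2.58 split matters (the reduction-rate accounting), use
recordings or simulations in which bursts are absent or rare.

Distance summaries group pairs by exact lattice distance (9 distinct
values for a 4 × 4 grid; the nearest 350 µm group holds 24 unordered
pairs).  The *reduction rate* over a band of pairs (defined `Z_before`
above or below the criterion) is `100 · n_decreased / n_band`, with
undefined-Z pairs on either side excluded.

## Synthetic wells

The generator emits recordings with known ground truth (master burst
intervals, per-spike labels, the coupling matrix used):

- **Sporadic firing** — independent Poisson per electrode, default 5 Hz
  (mature cultures fire ~1–10 Hz).
- **SBFs** — a master Poisson process, default 0.06 Hz; each electrode
  joins an event with probability 0.9, with Normal(0, 20 ms) onset offset,
  firing Poisson at 50 Hz for 1 s.  Sporadic ≈ 5 Hz and total ≈ 8 Hz per
  electrode at these defaults; real cultures often show larger
  burst-dominated totals, so tests of rate summaries treat the split, not
  the absolute total, as the invariant.
- **Pairwise coupling** — a common-parent process per pair at rate
  `c · sporadic_rate` injects one spike into both electrodes with
  independent Normal(0, 5 ms) jitter; the expected coincidence excess is
  analytic, making coupling-recovery tests sharp.  The helper
  `distance_coupling_matrix` (strength `c0 e^{−d/350 µm}`) emulates the
  distance decay of functional connectivity.
- **Modulation** — piecewise-constant per-epoch multipliers on the
  sporadic rate, SBF rate, within-burst rate and coupling, so every count
  stays conditionally Poisson with closed-form expectations.  Smooth
  recoveries are discretised into 300 s sub-epochs evaluated at midpoints.

**Dose model.** A dose `C` multiplies the SBF rate by the Hill factor
`1 + Emax·C/(EC50 + C)` (defaults Emax 1.5, EC50 30 nM, calibrated to the
reported magnitude of serotonin-class responses) while the within-burst
rate is scaled by the inverse.  The inverse scaling is deliberate: the
observed phenomenon is a large dose-dependent rise in SBF *counts* with no
change in total spike rates, which arithmetically requires per-burst spike
content to shrink as bursts become more frequent.  Concentration units are
explicit and default to nM.

**Stimulation model.** Low-frequency stimulation (1 Hz, 15 min per set,
4 sets at 90 min intervals) depresses rates by fractional depths
(defaults: 0.2 on sporadic and SBF rates, 0.4 on coupling) with
exponential recovery, `1 − depth·e^{−dt/τ}`.  Separate recovery constants
reflect the observed order of recovery: τ = 600 s for SBFs (recovered
within ~30 min) and τ = 4800 s for spikes and coupling (recovered within
~4 h); τ is set to a third of the recovery horizon so residual depression
at the horizon is < 5 %.  Depression is re-triggered by each set (most
recent stimulation dominates), matching the roughly constant per-set
depression observed.  The coupling depth exists because a uniform rate
depression alone cannot reduce Z — the surrogate null renormalizes with
the rates — whereas the phenomenon under study is a genuine loss of
connection strength.

What the generator does **not** emulate: oscillatory/quasi-periodic burst
timing (real SBFs are more regular than Poisson, so real SBF counts are
less dispersed than simulated ones), burst shape and propagation structure,
electrode-specific rate heterogeneity, non-stationary culture maturation,
and stimulation artifacts.  Passing tests therefore certify the analysis
chain and its statistics under a faithful-but-idealised point-process
model, not biological effect sizes.

## Protocol statistics

Metrics (array-total spike counts or SBF counts) are binned over time and
normalized to a reference window set to 100 % (the reference must align
with bin edges and be positive); bins overlapping stimulation are masked
(NaN) rather than deleted, keeping indices aligned with wall-clock time.
Wells are the experimental unit throughout.  Comparisons use one-way ANOVA
with Dunnett many-to-one post hoc tests (multivariate-t, equal-variance;
`scipy.stats.dunnett`), with a permutation max-|t| null (≥ 10 000
resamples, pooled-SD t statistics) available for very small samples; Holm
step-down adjustment for dose panels; and the two-tailed paired t-test for
before/after pairs.  Dunnett's familywise type-I error is verified at
0.05 ± 0.02 over 1000 null simulations.

Because per-bin SBF counts at 0.06 Hz are small (~54 per 15 min bin) and
Poisson-dispersed in the generator, a 10–15 % SBF depression over n = 8
wells is not reliably familywise-significant; the end-to-end stimulation
test therefore asserts Dunnett significance on the spike metric (counts
~10⁴ per bin) and checks the SBF depression and its earlier recovery on
aggregate means across replicates.

## Problem sizes and numerical choices

End-to-end tests use deliberately scaled problem sizes chosen as this
package's own test conditions: 3 Hz sporadic / 25 Hz intra-burst rates,
1 h baseline and 4 h final recovery for the stimulation pipeline (20
replicates × 8 wells), 6 h half-cycles for the dosing-rhythm pipeline, and
15 min windows with 100 surrogates everywhere synchrony is computed.
Random draws are reproducible: every public entry point takes a seed, and
well-level seeds are spawned from it below 2³¹.  Exact duplicate
timestamps within a train (probability zero in continuous time, possible
in floating point) are dropped on assembly; events are reported in time
order and never overlap.

## Limitations

- No spike sorting: an electrode's train mixes all units it records.
- The surrogate null is approximate (see the bias note above); Z values
  are comparable across conditions, not exact normal quantiles.
- The four-step SBF thresholds are calibrated on the synthetic suite, not
  on laboratory recordings; real data may need different values, which is
  why all of them are parameters.
- Dose–response and depression magnitudes produced by the generator are
  phenomenological; the pipeline reproduces procedures and qualitative
  dissociations, not published effect sizes.
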