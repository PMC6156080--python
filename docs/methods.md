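# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical decisions a maintainer would
want to know about. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and ΔF/F

A recording is a (frames × cells) matrix of ROI-averaged raw
fluorescence at a fixed sampling rate (validated 1–100 Hz; resonant
scanners typically deliver 15.2–30.4 Hz over a ~440 µm square field).
Each trace is normalised to

    dff[t] = (F[t] / mean(F[window]) − 1) · 100   [%]

The normalisation window stands in for the interactively chosen "silent
period" of classical workflows: it is automated as the 2-s window of
minimal variance within the first 30 s of the trace (both spans
configurable). On a trace with events in its opening seconds, minimal
variance reliably avoids transient flanks; the residual risk is a
baseline biased by a long plateau, which the local-baseline logic below
absorbs.

## Preprocessing

**Smoothing.** Iterated convolution with the binomial kernel
(1, 2, 1)/4, reflecting at the trace ends; the default 30 iterations
(customary band 20–40) approximates a Gaussian of SD √(n/2) ≈ 3.9 frames
(≈ 0.25 s at 15.2 Hz). The iteration-with-reflection form is the
contract, not a single equivalent convolution, so boundary behaviour is
exactly the iterated one.

**Drift removal ("high-pass").** Zero-phase running-median baseline
subtraction with a centred window of half the cutoff period (default
cutoff 0.02 Hz → 25 s window). A median tracks any drift that is
monotone across the window essentially exactly, and attenuates a 120-s
sinusoid by ~95 %, while sparse transients that occupy well under half
the window leave a median untouched — amplitude and foot-to-tail area
of a 1-s-decay transient are preserved to ~1 %. A linear (Butterworth)
high-pass cannot do this: it must redistribute each transient's area
into an undershoot spread over ~1/cutoff seconds; measured across
orders 1–6 and cutoffs 0.01–0.02 Hz, the best linear design still
removed ≥ 11 % of the foot-to-tail area while meeting the drift spec.
One consequence of the robust filter: a very long transient (longer
than about half the window, e.g. astrocyte-like events at the default
cutoff) is partially tracked by the median and attenuated mid-decay;
its peak region, flanked by baseline within the window, survives, which
is what detection needs. Amplitudes and areas are therefore *measured*
on the smoothed trace without the high-pass (see below).

## Peak detection

Candidates are samples where the first difference crosses zero from
positive to non-positive and the second difference is negative.
Acceptance requires the amplitude to exceed the local baseline mean by
`amplitude_sd_multiple` (default 3) noise SDs. Detection runs in two
passes on the smoothed, drift-removed trace:

1. a provisional pass using whole-trace statistics marks active spans
   (each provisional peak's 0.5-SD foot–tail span, walked against the
   global median);
2. the definitive pass re-tests every candidate against the mean of its
   local baseline window — the nearest activity-free span of
   `baseline_window_s` (default 10 s) preceding the peak — plus 3 local
   noise SDs.

When no full-width clean span precedes a peak, the longest available
clean span is used; spans shorter than 5 frames are not trusted (a
2-frame window has a degenerate variance estimate of exactly zero,
which would accept arbitrary noise), and the fallback is whole-trace
statistics.

**Noise SD.** The SD entering both the 3-SD amplitude gate and the
0.5-SD edge rule is estimated from the *unsmoothed* ΔF/F over the same
baseline window with the first-difference estimator
`std(diff(x))/√2`, which is exact for white noise and insensitive to
slow drift. Referencing the threshold to the raw-noise SD rather than
the smoothed trace's SD matters: 30 binomial iterations cut the noise
SD ~3.7-fold, and a 3-SD gate referenced to smoothed noise admits ~0.3
spurious maxima per minute (Rice-rate estimate, confirmed by
simulation), which would swamp low-frequency cells. Referenced to the
raw SD, the measured false-positive rate on pure-noise traces is
< 0.1 events/min and precision on synthetic populations is ≈ 1.

**Peak location and shoulder merging.** The accepted peak index is
snapped to the nearest local maximum of the smoothed ΔF/F by greedy
hill-climb (replacing interactive peak correction). Adjacent accepted
peaks are treated as one transient when the valley between them stays
above `peak_merge_fraction` (default 0.8) of the smaller peak's height
over baseline: genuine transient pairs ≥ 1 s apart dip well below that
(a 1-s-decay transient falls to ~0.4 of its peak in one second), while
noise shoulders riding a slow decay do not. Without this rule, slow
astrocyte-like events fragment into several short "events" and their
kinetic classification fails; with a lower fraction, genuine
closely-spaced events of hyperactive cells merge and their rates are
underestimated. 0.8 separates the two regimes with margin on both
sides.

## Event refinement, AUC, frequency, classes

Foot and tail are the first samples before/after the (corrected) peak
within 0.5 local SD of the local baseline (the median of the baseline
window on the smoothed trace); walks are bounded by the peaks of
adjacent events, so overlapping transients keep distinct spans, and are
clamped (and flagged) at trace ends. AUC is the trapezoidal integral of
ΔF/F − baseline over [foot, tail] in (ΔF/F %)·s; amplitude is peak
minus baseline. Measuring on the smoothed, non-high-passed trace keeps
AUC within 2 % of the analytic kernel area across realistic amplitudes
(≥ 20 % ΔF/F) and decay constants (0.4–3 s), verified against
quadrature.

Frequency is 60 · events / duration (transients/min). Classes: silent
(no events), low (f < 0.3), medium (0.3 ≤ f ≤ 3, boundaries inclusive),
hyperactive (f > 3). Cells with a median event duration above
`astrocyte_duration_s` (default 4 s) are flagged astrocyte-like — a
purely kinetic criterion — and excluded from all network metrics. With
1-s neuron decays, isolated event durations concentrate around 2–3 s,
and with 8-s astrocyte decays around 15–20 s, so the 4-s threshold has
a wide margin for multi-event cells; a single noisy borderline event
can still flip a one-event cell.

## Synchrony and surrogates

Event peak times are binned into binary occupancy rasters with 328-ms
half-open bins, the trailing partial bin dropped. Binary occupancy
(not counts) is the raster entry: with seconds-scale transients and a
1-s minimum separation, a 328-ms bin essentially never holds two
events. Synchrony of a pair is Pearson's r between bin vectors;
zero-variance (silent) cells are excluded with a log entry.

The surrogate is two composable steps, applied in order for the full
null: (1) `permute_identity` reassigns whole trains to randomly
selected ROIs (a bijection), destroying any relation between activity
and position; (2) `shuffle_times` redraws each train's times uniformly
subject to all gaps ≥ 1 s, conserving counts exactly. The constrained
uniform draw uses the order-statistics construction (sample n points
uniformly on an interval shortened by (n−1)·minsep, sort, and re-inflate
by i·minsep), which is exact and needs no rejection loop; infeasible
count/duration combinations raise, naming the cell.

The distance–synchrony relationship is an ordinary least-squares fit of
pairwise r on pairwise Euclidean distance, reporting slope, intercept
and the slope's two-sided p-value. A caution documented by the
calibration tests: pairs built from nearly-silent cells (≈ 1 event)
have heavy-tailed r values that make the OLS t-test anticonservative;
on active populations (≥ ~6 events/cell) the null rejection rate is at
its nominal level.

## Spatial clustering test

For every class pair, the observed mean pairwise distance is compared
with its distribution under random permutations of the labels (cell
positions fixed). P-values are two-sided with the add-one estimator:
`min(1, 2·min(P[perm ≤ obs], P[perm ≥ obs]))`, never exactly zero.
Within-class distances need ≥ 2 members (skipped with a log entry
otherwise); a single-class population yields an empty result. Under
random labels the p-values are uniform to within the discreteness of
the estimator (verified by KS over 200 replicates); a subgroup planted
in a 50-µm cluster is detected at p < 0.01 with 999 permutations (the
smallest two-sided p at N permutations is 2/(N+1), so N ≥ 399 is
required to resolve 0.01).

## Group comparison

Scalar per-recording metrics go through a Lilliefors normality screen
(location and scale are estimated, so the plain one-sample KS would be
conservative); both groups normal → unpaired t-test, otherwise
Mann-Whitney. Groups with < 4 recordings or zero variance go directly
to the non-parametric branch. Subgroup composition uses chi-square on
pooled active-cell counts; cumulative frequency distributions use a
two-way ANOVA (group × frequency bin) on per-recording values. With
fewer than two recordings in a group the report is flagged not
testable.

## Synthetic generator

The generator emulates: uniform cell positions on a square field
(default 440 µm); a silent fraction (default 0.30); active-class
mixture (default 0.25/0.65/0.10 low/medium/hyper) with per-class rates
defaulting to 0.15, 1.0 and 4.0 transients/min — mid-band
representatives of the three class intervals; Poisson event trains
thinned to a 1-s minimum separation, with the candidate intensity
inflated to λ/(1 − λ·s) so the *retained* rate equals the nominal rate
(greedy thinning of a Poisson process is a renewal process of rate
λ′/(1 + λ′s)); difference-of-exponentials kernels, peak-normalised,
with rise 0.1 s / decay 1 s / amplitude 40 % ΔF/F for neurons (matching
the tens-of-percent scale of somatic bulk-dye transients) and rise
0.5 s / decay 8 s for astrocyte-like cells (default fraction 0);
i.i.d. Gaussian noise in ΔF/F units, default SD 8 % (SNR 5 against the
default amplitude); and co-active ensembles: random centres, membership
probability p·exp(−d²/2σ²) (defaults p = 0.5, σ = 50 µm), and a shared
event train injected into all members before re-thinning. Traces are
rendered as F = F₀·(1 + (signal% + noise%)/100), clipped at zero, and a
movie renderer places traces into disjoint ROI masks over a constant
background for end-to-end I/O tests.

What the generator does **not** emulate — and hence what passing tests
cannot certify about real recordings: neuropil contamination, photon
shot noise and its intensity dependence, bleaching, motion artifacts,
bursting (multi-spike transients of graded amplitude), inhomogeneous
staining, or overlapping ROIs. Detection performance numbers on
synthetic data are best-case relative to these effects.

Ground-truth class labels follow the *nominal* rate (silent if the
realised train is empty); ensemble participation adds events beyond the
nominal rate, so recovery comparisons group cells by nominal rate but
compare detected frequency to the realised ground-truth event rate —
at a few hundred cells per class, Poisson sampling noise in the nominal
rate (~7–10 % for the low class) would otherwise dominate the
comparison.

## Determinism and orchestration

All randomness flows from `numpy.random.Generator`. The pipeline fans a
master seed into per-stage child seeds via `SeedSequence.spawn`, logs
them in the manifest, and writes CSV at full repr precision and JSON
with sorted keys, so identical config + seed reproduces every output
byte-for-byte (verified by test). Writer/reader pairs round-trip
exactly; event times are therefore not rounded on output.

## Problem sizes used in validation

The validation suite simulates 3 × 200-cell populations (6 min at
15.2 Hz, SNR 5) for recovery, 100–150-cell populations for synchrony
and distance analyses (≥ 10⁴ pairs), 200 replicates × 199 permutations
for clustering calibration, and 50 replicate experiments of 8 + 6
recordings × 100 cells for the power check — sizes at which every
stochastic margin in the checks is several standard errors wide, while
the whole suite runs in a few minutes on one CPU.

## Known limitations

- The 3-SD gate references an estimated local SD; in recordings whose
  noise is strongly non-white (e.g. heavy neuropil contamination), the
  first-difference estimator under- or over-states the effective noise
  and the threshold shifts accordingly.
- Overlapping transients closer than ~0.7 s merge after smoothing;
  rates of cells firing near the 1-s separation limit are slightly
  underestimated (measured ≈ −5 % at 4/min).
- Astrocyte identification is kinetic only; it cannot separate a
  neuron with genuinely slow calcium dynamics from an astrocyte.
- The OLS distance fit treats pairs as independent; its p-value is
  calibrated on active populations but anticonservative when
  nearly-silent cells contribute pairs.
- Transients whose peak falls within ~0.3 s of the recording end are
  undetectable in principle (no zero-crossing exists yet).
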