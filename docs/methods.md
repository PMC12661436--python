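# Methods

`optoentrain` analyzes electrophysiological and behavioral recordings from
experiments that probe a neural pathway with pulsatile optogenetic
stimulation — pulse trains at 5, 10, 20, 30 or 40 Hz with a 50% duty cycle —
and that relate LFP gamma-band power (40–60 Hz) to operant behavioral state.
Because such analyses are usually validated against animal recordings that
cannot be regenerated, the package pairs every analysis stage with a
synthetic-session generator whose ground truth is known exactly. This note
documents the models, the estimators, the numerical conventions, and what the
synthetic data can and cannot establish.

## Session model

All data streams live on one session clock in seconds (origin t0 = 0):
continuous signals (uniformly sampled, with rate and region label), sorted
spike-time lists per unit, pulse trains (onset/offset pairs with nominal
frequency f and duty cycle), behavioral trial blocks and lever-press/reward
events. On disk a session is a *bundle*: `manifest.json` plus delimited event
tables and raw little-endian float64 signal files with the dtype and
endianness declared in the manifest. Validation enforces every container
invariant (sorted, strictly increasing spike times; positive rates;
non-overlapping blocks; on-widths consistent with duty/f) and names the
offending field. Spike times closer than 1 µs are treated as sorter artifacts
and collapsed to one event with a logged warning rather than rejected.

## Spike-phase locking

Spike phases relative to an f Hz pulse train are computed on the stimulus
clock as

    phi = 2*pi*f*(spt - t0)  mod 2*pi,

with t0 at pulse onset, so a 50% duty cycle maps the light-on half-period to
[0, pi). Phases are computed only for spikes inside full stimulation cycles
([onset, onset + 1/f) per pulse); spikes outside stimulation epochs are
excluded with a logged count. Each spike is referenced to its own cycle
onset, which equals the global formula for exactly periodic trains and stays
correct for trains delivered with pauses.

Non-uniformity is tested with the Rayleigh statistic: R = |Σ e^{i phi}|/n,
Z = nR², and the small-sample-corrected p-value
p = exp(sqrt(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)) — the same approximation
used by the MATLAB circular-statistics `circ_rtest`. Tests verify this
analytic p against an empirical null from 10⁵ uniform-phase draws and confirm
that p is Uniform(0,1) under uniform phases. Preferred phase is summarized by
the circular mean (flagged undefined when R = 0, e.g. antipodal input) and by
the center of the maximal bin of an 18-bin (20°) histogram; the bin count is
configurable and was chosen to match the granularity of standard rose plots.
A unit is "locked" per frequency condition (no pooling across frequencies),
and the preferred side is light_on when the circular mean is below
2·pi·duty (boundary assigned to light_off).

## Stimulation-response classification

The pairing unit for rate comparisons is the stimulation *train*: a
contiguous run of pulses (nominally 1 s), detected by splitting the pulse
sequence wherever consecutive onsets are more than 1.5 periods apart. The
baseline window is the equal-duration window immediately preceding each
train, which removes rate-estimator bias between the paired windows.
Per-train stimulation rates are compared with baseline rates by a
normality-gated paired test: Lilliefors and Anderson–Darling tests are
applied to the rate differences at a fixed 5% gate level; if both fail to
reject normality a paired t-test is used, otherwise the Wilcoxon signed-rank
test. All-zero differences short-circuit to p = 1 (no modulation). A unit is
excited/inhibited when p < alpha (default 0.05) with the sign of the mean
difference, ns otherwise. The same machinery applied to the first 100 ms of
each train detects transient responses (e.g. inhibition preceding a net
excitation). Category counts (e.g. transiently inhibited vs excited units)
are compared with a Pearson goodness-of-fit chi-square without continuity
correction; expected proportions are an explicit argument, defaulting to
equal.

PSTHs use half-open bins [left, right): a spike on a shared edge counts in
the right-hand bin, a spike at the final edge falls outside the window, and
the rate array integrates exactly to counted spikes per trial. Depth
profiles bin stimulation sites into half-open 0.5 mm bins anchored at the
shallowest depth rounded down to a 0.5 mm multiple, and test the
response-by-depth effect with a one-way ANOVA across non-empty bins; with
zero variance anywhere F = 0 and p = 1, and with a single non-empty bin the
ANOVA is marked not applicable.

## Spike-triggered average and spike-field coherence

The STA is the pointwise mean of ±100 ms LFP epochs centered on spike times
(spikes without full coverage are dropped and counted). The spike-field
coherence is

    SFC(f) = P_STA(f) / Pbar(f),

where P_STA is the power spectrum of the STA and Pbar the mean of the
epochs' power spectra on the same grid. Spectra are taken over exactly
200 ms (the symmetric extra center sample is kept only for STA display), so
the grid has 5 Hz resolution and the 35 Hz control frequency is a grid point.
The power-ratio reading of the estimator was chosen over an amplitude ratio
because normalizing "to the existing power" is only dimensionless as a power
ratio and yields the invariants the tests rely on: SFC ∈ [0, 1] exactly
(Cauchy–Schwarz per frequency bin), SFC = 1 for deterministic perfect
locking, expectation ≈ 1/n for spikes independent of the field, and
invariance to global amplitude scaling. Epochs are rectangular (no taper),
matching the bare estimator; bins where Pbar vanishes are flagged NaN. No
spike-artifact removal or interpolation is applied to the LFP, so
same-electrode spike bleed-through is a known caveat of the estimator as
implemented.

The within-site stimulation-vs-control contrast (default 40 vs 35 Hz) splits
the spikes into contiguous equal-spike-count segments (default 10; equal
counts equalize estimator variance across segments), computes the SFC per
segment, and applies the normality-gated paired test to the per-segment
values; the population-level test is a Wilcoxon signed-rank across per-site
mean differences.

## LFP band-power pipeline

Signals are down-sampled to 200 Hz through a polyphase anti-alias filter,
segmented into non-overlapping 1 s epochs, and screened for artifacts with a
robust amplitude rule — any sample deviating from the signal median by more
than 6 robust SD (1.4826·MAD) rejects the epoch — plus a saturation rule
(three consecutive identical extreme values). Robust statistics are used so
the artifacts themselves cannot mask the threshold. Per-epoch periodograms
(demeaned, one-sided) are normalized so the spectrum sums to the epoch
variance (Parseval), which pins the sine-wave fixtures exactly: a unit
50 Hz sine carries spectral mass 0.5 in its bin. Band power is the mean
spectral value over grid points in the band, edges inclusive ([40, 60] Hz by
default).

Epochs are labeled by behavioral state from lever presses in a 10 s window
centered on the epoch: high pressing with ≥ 2 presses, low with 0, otherwise
excluded — an explicit, conservative criterion with the parameters exposed
in configuration. Comparisons use the design-appropriate rank test:
epoch-level high-vs-low by Wilcoxon rank-sum, per-session pairs by Wilcoxon
signed-rank, and region-by-schedule families by sign tests with Bonferroni
correction (adjusted alpha = alpha/m reported alongside). For block designs
(rewarded S+ vs unrewarded S− trial blocks), artifact-free epochs are
assigned to the block containing their center (straddling epochs follow
their center, logged) and aggregated per condition.

## Behavior

The schedule engine implements continuous reinforcement (every press
rewarded), fixed ratio FR(k) (every k-th press), and variable interval
VI(mean, jitter): an interval drawn Uniform(mean − jitter, mean + jitter)
arms the schedule, the first subsequent press is rewarded, and the next
interval is drawn at the reward (first interval drawn at t = 0). The uniform
reading of "mean ± jitter" is the simplest bounded interpretation.
Cumulative records reset to zero after every 50 presses, so the local slope
is the press rate. Press-rate contrasts pair opto and control trials in
temporal order and use the gated paired test (unbalanced designs fall back
to an unpaired rank-sum with a warning). Discrimination performance is
percent correct = 100·S+/(S+ + S−) presses within one condition set, using
raw counts because block durations are equalized by design (a rate-based
variant would divide by block time first). Training is split into first /
middle / last seven-day stages, the middle stage centered on the median
training day; at least 21 days are required so stages cannot overlap.

The stage-restricted ANOVA takes the replication unit as an explicit
parameter. The default, unit="day", averages over subjects and treats days
as the paired unit, giving the condition effect F(1, n_days − 1) — the
design implied by an F(1,6) on seven-day stages; day and interaction effects
are not estimable there and are returned NaN. unit="subject" runs the full
two-way within-subject ANOVA from balanced sums of squares, testing each
effect against its effect-by-subject interaction; it is verified in tests
against both a from-scratch SS decomposition and pingouin. No sphericity
correction is applied by default. A Lilliefors test on the conditional
residuals (the highest-order within-cell residuals) is reported with every
fit.

## Synthetic data: what it emulates

Spiking units are inhomogeneous Poisson processes sampled by exact thinning
(no discretization bias; exact for the piecewise-constant archetype rates).
Archetypes: excited_on (baseline + gain during light-on), inhibited
(baseline·(1 − suppression) during light-on), rebound (suppressed during
light-on, plus rebound_rate for a rebound window after each offset),
md_biphasic (suppressed for the first 100 ms of each 1 s train, then
baseline + gain), and unmodulated. excited_on takes an optional onset time
constant: the on-rate increment becomes gain·c·exp(−t/tau) with c chosen to
preserve the mean on-rate, modelling short-latency channelrhodopsin-driven
onset firing. This matters for the spike-field harmonic: a perfectly flat
50%-duty boxcar rate has exactly zero modulation at 2f (the sinc null at
1/on-width), so the empirically observed first-harmonic SFC peak at 80 Hz is
only reproducible when the firing concentrates early in the on-phase, as
real units do.

LFPs are sums of independently returned components: 1/f-power background
noise (FFT-shaped white noise, normalized to a target SD), a
stimulation-locked oscillation with phase 0 at each train onset and a
decaying harmonic series at k·f (relative amplitudes 1, 1/2, 1/4 for
k = 1..3) emulating the edge-response comb of a square light drive,
narrowband gamma noise (4th-order Butterworth bandpass around 50 Hz, ±5 Hz)
whose amplitude is multiplied per behavioral state, and sparse exponential
artifact transients. Ground-truth components are returned alongside the
composite so recovery tests never re-derive truth from the mixture.

Operant sessions draw Poisson presses (optionally state-dependent via
thinning) and route them through the schedule engine. Trial sequences have
equal counts per type, no type repeating more than 3 times in a row
(constructive sampling with restart), durations Uniform(57, 63) s using the
same duration multiset for every type so total time per type is exactly
equalized, and inter-trial intervals Uniform(1, 4) s — a printed "1 ± 3 s"
ITI would allow negative durations, so the bounded uniform on (1, 4) s keeps
the printed center while staying positive. Discrimination-learning courses
follow chance + (asymptote − chance)·logistic(slope·(day − midpoint)) with
i.i.d. Gaussian session noise (SD 3%), an additive stage-specific opto
effect (default +15% in the first stage only), 7 subjects and 21 days,
clipped to [0, 100].

Defaults: 50% duty; protocol frequencies 5–40 Hz; stimulation sessions of
120 s (continuous, spike-field fixtures) or twenty 1 s trains with 3 s
pauses (classification fixtures); VI mean 30 s, jitter 5 s; gamma gate 2:1
engaged:paused amplitude on the gated channel. Every generator is a pure
function of (parameters, seed).

What passing tests do **not** show about real data: the generators have no
refractoriness, bursting statistics, or rate nonstationarity beyond the
modelled gates; LFP noise is Gaussian with an exact 1/f spectrum and no
line noise; spikes and LFP are generated independently given the stimulus,
so spike bleed-through into the LFP is absent; and behavioral policies are
Poisson, without the sequential dependencies of real lever pressing.
Calibration results (type-I error ≈ alpha) therefore certify the estimators
and test wiring under the stated models, not robustness to every real-world
violation.

## Numerical choices and problem sizes

Degenerate inputs are handled explicitly: all-zero paired differences → p=1;
zero resultant → undefined circular mean; Pbar = 0 → NaN SFC bin; single
depth bin → ANOVA not applicable; empty spike train → ns with a logged
warning. Histogram ties resolve to the lowest bin; all interval conventions
are half-open [a, b). Tie-free rank tests come from scipy; the Wilcoxon
signed-rank drops zero differences ("wilcox" rule).

Simulation sizes used in the test and acceptance runs — 50 seeds for the
spike-field recovery (120 s sessions, ~1800 spikes each), 200 seeds for the
phase-side bounds and end-to-end recoveries, 2000 replicates for the type-I
calibrations — were chosen so Monte-Carlo error is small against the margins
being checked (e.g. SE ≈ 0.005 for a 0.05 rejection rate at 2000 reps)
while a full run of the suite stays around a minute.
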