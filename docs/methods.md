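# Methods

`wnphase` studies a measurement problem in phase–perception research: when a
binary perceptual outcome depends on the phase of an ongoing oscillation at a
known moment, at what latency does a phase-opposition analysis *measure* that
dependence?  The package implements the statistical machinery (ITPC, POS,
permutation surrogates, corrections, cluster latencies), a simulation that
shows how a target-evoked potential displaces the measured latency, and a
white-noise reconstruction paradigm in which the evoked response is absent by
construction.

## Phase-opposition statistics

For phases φ_k over n trials, the intertrial phase clustering is
ITPC = |n⁻¹ Σ exp(iφ_k)|, and for two outcome groups A/B

    POS = ITPC_A + ITPC_B − 2·ITPC_all,

which is ≈0 for uniform or commonly-locked phases and 2 for perfect
equal-split opposition.  Because the null depends on the phase sampling of
the data at hand, observed values are referenced to label-shuffle surrogates
(group sizes preserved; default 1000 shuffles, shared across the cells of a
time–frequency map).  The z-score against the surrogate mean/SD is the
reported effect size.

**p-values.** The permutation null of POS is right-skewed, so converting z
through a plain normal CDF is anticonservative: simulated type-I error is
7.6–8.4% at a nominal 5%, and worse at the depths where Bonferroni/FDR
cutoffs operate.  The default (`tail="calibrated"`) therefore evaluates the
upper tail of a shifted gamma matched to the surrogates' mean, SD and
skewness (shape 4/γ²); simulated type-I error is then 5.2–5.6% at 0.05 and
calibrated at 0.01 and 0.001 as well.  `tail="normal"` keeps the literal
normal-CDF convention of the phase-opposition literature; the latency study
uses it by default (see below) because the published operating
characteristics it reproduces were obtained under that convention.

**Aggregation.** Grand averages sum POS across channels and subjects; the
surrogate distribution of the sum is rebuilt by repeatedly drawing one stored
surrogate per subject and re-summing (default 100 000 resamples; 10 000 for
the channel topography of a cluster).  Multiple comparisons: Bonferroni
(α/m) or Benjamini–Hochberg step-up.  The latency of a significance time
course is the mean time of its longest contiguous run (ties → earliest).
Median latencies across datasets carry the quartile-based 95% CI
q2 ± 1.7·1.25·(q3−q1)/(1.35·√N) with type-7 quartiles.

## Artificial datasets and the latency-distortion study

Each dataset holds 500 single-channel trials of 3 s (−1.5..1.5 s) at 500 Hz,
drawn i.i.d. from N(0, 10²) (a pink-noise option shapes the spectrum by
1/√f).  The outcome is injected at +40 ms: the phase of the `f₀ ± 1` Hz band
is extracted by a zero-phase Hamming-window FIR (length four periods of f₀,
capped at a third of the trial; a brick-wall FFT variant exists) followed by
a Hilbert transform, and outcome A is drawn with probability

    P(A|θ) = p̄·(1 + m·cosθ),  p̄ = 0.5, m = 0.4  (70% at θ = 0).

The additive reading `p̄ + m·cosθ` (90% at the peak) sits behind
`convention="additive"`.  After labelling, every trial receives an
outcome-independent ERP: raised-cosine (Hann) bumps, P1 positive
(amp 20±5, latency 65±10 ms, duration 50±10 ms) and N1 negative (30±10,
155±25 ms, 130±25 ms), parameters drawn per trial (non-positive draws are
redrawn, preserving the stated means).

The study analyses each dataset with a Morlet wavelet at the injection
frequency itself.  The wavelet is a complex exponential under a Gaussian
with σ_t = cycles/(2πf), truncated at ±4σ_t, envelope-normalised; cycle
counts interpolate geometrically from 3 cycles at 3 Hz to 8 at 100 Hz, so
window durations (cycles/f) run from 1 s at 3 Hz to 80 ms at 100 Hz.  Over
an 800 ms window (−360..+440 ms, decimated to 170 points; native grid
optional) each time point gets a surrogate POS test, Bonferroni-corrected;
the dataset's latency is its largest-cluster mean.  Per-frequency rows
aggregate 100 datasets (median, CI, Wilcoxon sign-rank against +40 ms at
α = 0.01); the sweep covers 24 log-spaced frequencies 3.99–100 Hz, and the
latency error (40 − measured) is Pearson-correlated with the window duration
across per-dataset pairs.

What the simulation shows, and reproduces here: without the ERP the measured
latency brackets +40 ms at every frequency (smearing only); with the ERP the
latency is displaced earlier by an amount that grows as frequency falls, the
displacement disappearing above ~40 Hz.  Operating points: at 7.08 Hz the
median latency lands near −80 ms with roughly half the datasets significant
at −120 ms; at 39.44 Hz near +37.5 ms.  At 3.99 Hz this implementation
yields a substantially larger displacement (≈ −270 ms) than the −143 ms
reference value for this protocol: the ERP's 4-Hz wavelet response here
peaks at ~8× the wavelet-domain noise SD and masks opposition from −150 ms
onward, and no reading of the stated ERP parameters that we explored
produces the weaker low-frequency interference the reference value implies.
The ERP waveform family is the one genuinely unconstrained ingredient; the
package treats the Hann-bump reading as its definition and reports what it
measures.  The same power deficit at 4–6 Hz dilutes the per-dataset
error–window correlation (≈0.5 here; ≈0.97 across per-frequency medians).

## The synthetic observer and the white-noise paradigm

The observer watches 6.25 s white-noise luminance sequences at 160 Hz
(1000 frames, i.i.d. uniform [0,1], mean gray 0.5) containing 2–4 targets
per sequence; target frames and a suppression window (14 frames before,
11 after) are set bit-exactly to the mean gray, so the stimulus-driven
signal is invariant to target presence.  The "recorded" signal is the causal
convolution of a known IRF with the mean-centred stimulus plus Gaussian
sensor noise (default SD 2, i.e. a stimulus-driven variance fraction of
~0.2 on the strongest channel — far cleaner than real scalp recordings, by
design, so that recovery properties are testable at desk scale).  The
default IRF is an early biphasic deflection plus damped 10 Hz ringing,
scaled across four channels.  Detection: a target is a hit with probability
0.5·(1 + 0.4·cos φ), where φ is the phase of the noiseless stimulus-driven
signal on channel 0 at 6 Hz and target time +75 ms, measured by a wavelet
whose cycle count matches the analysis schedule (a deliberate alignment:
with a longer detection wavelet, the mean-gray suppression gap shifts the
true coupling peak tens of ms earlier, and +75 ms would no longer be the
ground truth).

Pipeline operations mirror the experimental workflow: IRF estimation by
stimulus–signal cross-correlation (mean-centred stimulus, kernel normalised
by stimulus energy — exact least squares for white stimuli; lags 0–750 ms);
reconstruction by causal convolution; epoching (−800..+794 ms → 256 samples
at 160 Hz) with −200..0 ms baseline removal; grand-average POS over a
2→8-cycle, 50-step 3–100 Hz wavelet grid capped below 80 Hz, FDR at 0.05,
largest 2-D cluster (4-connectivity), z-weighted centroid and peak cell,
and a cluster topography via per-channel resampled sums.  Cross-validated
reconstruction quality uses k-fold (default 10) splits by sequence: IRF (or
target-locked ERP, as the comparison model) fit on training folds, Pearson r
on held-out folds per channel, Fisher-z averaged, cohort t-test against zero
with FDR across channels; band-limited variants filter both signals with
zero-phase brick-wall bands (δ 2–4, θ 4–8, α 7–14, β 14–28, γ 30–60 Hz).
Classification images t-test per-frame luminance between hits and misses,
excluding zero-variance frames (the suppression window), FDR across time and
subjects.  Phase-binned performance uses 11 fixed bins (no realignment
across subjects), hit rates normalised by mean performance, and a linear
cosine fit (cos/sin regressors); the amplitude is reported in percent.

**A structural limitation, by construction.** Every channel of the observer
is a fixed linear filter of one stimulus, so channel phases differ only by
fixed rotations — to which POS is blind.  The phase-opposition scalp
topography of this observer is therefore exactly flat: the machinery is
exercised and tested for shape, but no channel can "win".  Channel-selective
phase topographies require channel-specific non-stimulus sources (as in real
recordings), which this deterministic observer intentionally does not model.
Equally intentionally, the observer has no top-down states, no artifacts,
no 1/f background mixed into the recording, and its detection rule is purely
phase-driven — so passing tests demonstrate the pipeline's correctness and
sensitivity, not realism of scalp EEG.

## Numerical choices and reproducibility

Every stochastic operation takes a seed; sub-streams derive deterministically
(SeedSequence), and per-dataset seeds hash (study seed, frequency index,
dataset index) so runs parallelise reproducibly.  Fixed seeds give
bit-identical outputs.  Wavelet edge samples (support not fully inside the
signal) are flagged invalid, never silently zeroed; analyses restrict to
jointly valid times.  Degenerate inputs raise typed errors
(single-class labels, zero-spread surrogates, out-of-Nyquist bands).
Problem sizes used by the test-suite and the acceptance script — 100
datasets per study row, 30 per sweep frequency, 8-subject observer cohorts
of 60 sequences — are the package's chosen desk-scale operating points; the
row and count statistics quoted above were measured at exactly these sizes.
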