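# Methods notes

## The measurement model

The pipeline treats the visual N1 as a spatio-temporal component: a fixed
zero-mean scalp topography (bilateral occipito-temporal negativity with a
compensating anterior positivity, so the map is consistent with an average
reference) modulated by a temporal response kernel and a condition-specific
amplitude. The dependent measure throughout is the **cluster mean
amplitude**: the mean voltage over the nine LOT (or ROT) channels and over
the ±30 ms N1 window, in μV.

The N1 window is selected from the data, not fixed a priori: the global
field power of the grand-average ERP (unweighted mean over subjects and
conditions at each wave) shows a P1 peak followed by an N1 peak; the second
post-stimulus local maximum inside an 80–350 ms search range defines the
window centre. A local maximum is a sample strictly greater than both
neighbours after optional moving-average smoothing (off by default; the
pooled GFP is smooth at realistic SNR); plateaus resolve to their centre
sample, and window endpoints snap to the 500 Hz sampling grid with both
endpoints included in subsequent averages. An optional topography-check
hook can veto a candidate peak (e.g. require posterior negativity) and
advance to the next; it is disabled by default because the synthetic GFP
has an unambiguous two-peak structure. If fewer than two maxima exist the
selection fails loudly and asks for a manual window.

## Epoching conventions

Epochs span [−100, 613) ms relative to stimulus onset — half-open on the
post-downsampling grid, with the onset sample defined as the first sample at
or after the event time (357 samples at 500 Hz). Baseline correction
subtracts the mean of the −100…0 ms interval per channel; it can be
disabled, and the GFP/TANOVA measures are insensitive to it under the
average reference up to a per-epoch offset. The ±200 μV rejection criterion
is applied to the absolute amplitude of any sample on any channel
(not peak-to-peak), which is the stricter and simpler reading; the
inclusion rule (≥ 20 epochs in *every* condition) is inclusive at exactly
20.

## Filters

The band-pass is a 4th-order zero-phase Butterworth (two second-order
sections, applied forward–backward), the notch a 2nd-order band-stop over
48–52 Hz. Resampling is polyphase. The cutoffs (0.1–30 Hz, 50 Hz, 500 Hz)
are the conventional developmental-ERP settings; since no ICA stage exists
in this pipeline, a single band-pass covers what would otherwise be split
around artifact correction. Bad-channel repair uses inverse-distance
weighting of the k = 4 nearest good channels on the unit sphere, capped at
5 repaired channels per recording.

## TANOVA

The topographic test uses the generalized dissimilarity
s = √((1/K) Σ_c GFP(M_c − M̄)²) over the K condition grand-average maps,
computed on per-subject, per-condition maps that are GFP-normalized per
sample (zero-GFP maps pass through unchanged). For K = 2 this reduces
algebraically to GFP(M₁ − M₂)/2. The null permutes condition labels
independently within each subject (the paired design's exchangeable unit);
p = (1 + #{s_perm ≥ s_obs}) / (1 + B) so p is never zero. 5000 permutations
is the default (stable at the 1% level); per-sample p-values are reported
without correction across samples — the read-out is "periods of p < 0.05"
within the N1 window — and a max-statistic correction is a one-line
post-processing step on the returned per-permutation maxima if desired.
An alternative statistic (mean pairwise dissimilarity) was considered and
rejected: for balanced designs it is monotonically related to the
generalized dissimilarity, so it would change nothing but the scale.

## Mixed model

Amplitudes are modelled as hemisphere × condition × timepoint (all
within-subject factors, sum-coded) with a random intercept per subject,
estimated by REML through statsmodels' MixedLM. REML is the default because
its term-wise Wald F statistics coincide exactly with the classical
balanced repeated-measures ANOVA (verified against a cell-means oracle in
the tests); maximum likelihood is available via `LmmSpec(reml=False)`.
Denominator degrees of freedom use the within-group convention
N − n_subjects − (p − 1), matching the single-error-stratum ANOVA on
balanced data. Residual screening follows a single pass: normalized
(conditional Pearson) residuals — observation minus fixed effects minus the
predicted random intercept, divided by the estimated residual SD — beyond
±3 are dropped and the model refit once. One pass suffices by design; the
tests confirm no cascade on cleaned data. Contrasts are differences of
model cell means (averaged over uninvolved factors), signed
digits-minus-control so digit sensitivity appears as negative t values;
their p-values are reported unadjusted per wave.

Brain–behavior associations use Spearman correlations (midrank ties; exact
permutation null for n ≤ 9, t approximation otherwise) over a configurable
grid defaulting to 36 tests: 2 hemispheres × 2 contrasts × 9
behavior@wave cells (number knowledge at T1; arithmetic percentile and
word / pseudoword / average reading fluency percentiles at T4 and T5).
Benjamini–Hochberg FDR is applied across the whole grid. Each cell is also
re-estimated after screening the neural measure with a |v − median| >
3·MAD rule (raw MAD, no consistency scaling), mirroring the practice of
reporting correlations before and after neural-outlier exclusion.

## Synthetic cohort: what it emulates and what it does not

Defaults encode the emulated study's conditions: five waves with group
sizes 23/22/27/27/42 drawn from 62 children with 1–5 visits each; a
target-detection task of 4 blocks × 15 items per condition with 6 targets
(54 ERP trials per condition), 613 ms stimuli, 331/695 ms ISIs and 6/12 s
fixation gaps; N1 peak latencies 228/218/220/210/208 ms for T1–T5
(equivalently, ±30 ms windows of 198–258 … 178–238 ms); a P1 at 120 ms.
Condition peak amplitudes are DIG −8, LET −7, FF −6 μV with LET raised to
−8 μV at T2 — i.e. a persistent −2 μV coarse effect, and a −1 μV fine
effect that vanishes at the wave following intensive letter training.

Noise terms: 1/f background (exponent 1, 6 μV per channel), white sensor
noise (2 μV), boxcar artifacts > 200 μV on random channel subsets and
frontal blink transients, each hitting ~5% of epochs by default — both are
detectable only by the amplitude criterion, which is the point, since no
ICA stage exists here. Subject-level structure: a random intercept
(SD 1.5 μV) shared across visits and conditions, and a subject-specific
coarse-effect deviation (SD 1 μV) rank-coupled to a latent skill through a
Gaussian copula (r = 2·sin(πρ/6) yields Spearman ρ; default target 0.6).
Behavioral scores are deterministic monotone transforms of the latent
skill (counts for number knowledge, percentiles elsewhere).

The amplitude-level generator (`simulate_amplitude_table`) draws cluster
mean amplitudes directly from the mixed-effects data-generating model with
residual SD 2 μV — the scale of single-visit cluster means averaged over
~45 epochs and 9 channels. It interprets condition amplitudes on the
measured scale (no kernel attenuation), so injected differences are
recovered without a scale factor; the EEG-level forward model, by
contrast, attenuates window means by the kernel's average over the 60 ms
window (~0.93 for the default 90 ms FWHM Gaussian).

Not emulated: realistic head-model lead fields (the topography is a
Gaussian-on-sphere sketch), MR-environment artifacts, eye tracking,
latency jitter across trials, and spatially correlated noise. Passing
recovery tests therefore demonstrate that the *analysis* is correct and
calibrated under the stated generative assumptions, not that those
assumptions exhaust real developmental EEG.

## Problem sizes in the shipped checks

The validation suite uses sizes chosen to pin each property with adequate
Monte-Carlo precision: TANOVA type-I calibration over 500 exchangeable-null
cohorts (12 subjects × 3 conditions × 19 channels × 3 samples, 500
permutations each); coarse-effect power and bias over 100 amplitude-level
cohorts at the full study group sizes; Spearman coverage over 200
replicates at n = 27; BH-FDR over 2000 null grids of 36 tests. EEG-level
end-to-end checks run a reduced montage (≥ 24 channels always containing
both clusters) or a 6-subject full-montage wave, which is ample to localize
the GFP peak on the 2 ms grid.

## Numerical conventions

Ties in permutation statistics count as "greater or equal" (with a 1e-15
guard) so enumeration and Monte-Carlo agree; GFP uses the population SD;
zero-GFP maps are left unnormalized and flagged rather than divided by
zero; degenerate inputs (monotone GFP, empty clusters, missing factor
levels, zero rank variance) raise or flag explicitly rather than returning
silent defaults. All cohort-level randomness derives from one master seed
through a CRC-32 counter scheme (`child_seed`), keeping derived seeds below
2³¹ and every table byte-reproducible.
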