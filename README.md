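# n1dev

Analysis pipeline for the development of the **visual N1** response to single
characters — digits (DIG), letters (LET) and false fonts (FF) — in
longitudinal child EEG, together with a synthetic cohort generator that makes
every stage testable without any recorded data.

The visual N1 is a negative deflection over occipito-temporal cortex between
roughly 130 and 260 ms after stimulus onset whose amplitude indexes
category-sensitive visual processing. The pipeline quantifies two effects per
developmental wave (T1–T5, kindergarten to fifth grade):

* **coarse digit sensitivity** — N1(DIG) − N1(FF), familiar vs. unfamiliar
  characters;
* **fine digit sensitivity** — N1(DIG) − N1(LET), between familiar
  categories.

Negative values mean a stronger (more negative) N1 to digits.

## What the pipeline does

1. **Preprocessing** (`n1dev.preprocess`): zero-phase 0.1–30 Hz Butterworth
   band-pass with a 50 Hz notch, polyphase downsampling to 500 Hz, spherical
   inverse-distance interpolation of bad channels, common average reference,
   epoching −100…613 ms around non-target stimuli, rejection of epochs
   exceeding ±200 μV, and inclusion of a subject visit only when every
   condition retains ≥ 20 epochs.
2. **ERP features** (`n1dev.erp`): condition averages; global field power
   GFP(t) = √( (1/N) Σᵢ (uᵢ(t) − ū(t))² ); the N1 analysis window as the
   ±30 ms interval around the *second* post-stimulus local maximum of the
   grand-average GFP (the first is the P1); mean amplitudes over the left and
   right occipito-temporal nine-channel clusters (LOT: E57, E58, E65, E70,
   E63, E64, E69, E68, E73; ROT: E83, E90, E96, E100, E89, E95, E99, E88,
   E94).
3. **Topographic statistics** (`n1dev.tanova`): TANOVA — per-sample
   permutation test of GFP-normalized map differences between conditions
   using the generalized dissimilarity
   s = √( (1/K) Σ_c GFP(M_c − M̄)² )
   with within-subject label permutations (default 5000) and add-one
   p-values — plus electrode-wise one-sample t-maps of condition differences.
4. **Inference** (`n1dev.stats`): linear mixed model with a per-subject
   random intercept on N1 mean amplitudes and fixed factors
   hemisphere × condition × timepoint; observations with normalized residuals
   beyond ±3 are excluded once and the model refit; per-wave condition
   contrasts signed digits-minus-control; Spearman rank correlations between
   N1 sensitivity and behavioral scores (number knowledge, arithmetic,
   reading) with Benjamini–Hochberg FDR over the default 36-test grid.
5. **Synthetic cohort** (`n1dev.simulate`): 124-channel average-reference-
   consistent EEG with a P1/N1 forward model, 1/f background noise,
   high-amplitude artifact and blink epochs, per-wave group sizes 23/22/27/
   27/42 with 1–5 visits per child, and behavioral scores rank-coupled to the
   neural coarse effect through a Gaussian copula.

## Worked example

```python
from n1dev.pipeline import RunConfig, run_simulate, run_analysis

cfg = RunConfig(
    seed=5, n_channels=20, native_rate_hz=500.0,
    timepoints=("T1", "T2"), group_size={"T1": 5, "T2": 5}, n_subjects=6,
    design={"blocks_per_condition": 2, "items_per_block": 15, "targets_per_condition": 2},
    n_permutations=200,
)
bundle = run_simulate(cfg, "run/bundle")
res = run_analysis(cfg, bundle, "run/results")
for tp, w in res["windows"].items():
    print(tp, w.start_ms, w.end_ms)
print(res["contrasts"].query("contrast == 'DIG-FF'")[["timepoint", "estimate", "t", "p"]])
```

prints

```
T1 198.0 258.0
T2 188.0 248.0
  timepoint  estimate         t             p
0        T1 -2.101939 -7.950377  5.574118e-10
1        T2 -1.688203 -6.385461  1.004825e-07
```

The data-driven windows sit ±30 ms around the injected N1 peaks (228 ms at
T1, 218 ms at T2), and the coarse contrasts recover the injected −2 μV
digit–false-font effect (attenuated slightly by averaging the Gaussian
response kernel over the 60 ms window) with strongly negative t values —
the signature of coarse digit sensitivity.

The same run from a shell:

```bash
n1dev all --seed 5 --config small.yaml --outdir run
n1dev recover --seed 1 --outdir recovery   # calibration & recovery suite
```

## Layout

```
src/n1dev/        montage, design, simulate, recording, preprocess,
                  erp, tanova, stats, pipeline, plots, cli
tests/            unit, property and acceptance tests (pytest + hypothesis)
docs/methods.md   model, parameter and design notes
scripts/          acceptance.py
```
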