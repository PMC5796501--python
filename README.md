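# sdbsound

Acoustic screening of sleep disordered breathing (SDB) severity from
overnight breathing-sound recordings.

The pipeline turns a single-channel overnight recording (WAV, nominally
8 kHz) into a per-subject acoustic feature vector and classifies subjects
into apnea–hypopnea index (AHI) severity groups (normal / mild / moderate /
severe, cut-offs 5/15/30 events per hour):

1. **Preprocessing** — spectral-subtraction denoising, then retention of
   N2/N3 sleep epochs from a hypnogram (TSV).
2. **Feature extraction** — ~100 descriptors per 5 s window (spectral shape,
   MFCC / constant-Q MFCC, LPC, beat-histogram and area-moment statistics,
   spectral-envelope peak amplitudes F1–F3, gammatone sub-band energies over
   eight 500 Hz bands, A/C/unweighted sound pressure levels), aggregated per
   subject as mean/SD of the raw and first-difference series (max/min/mean/SD
   for formants, sub-bands and SPLs).
3. **qTM** — the magnitude envelope is quantized into silence/low/high
   levels, silence runs of 20–60 s are relabeled apnea candidates, and the
   4×4 transition-probability matrix is appended as 16 features.
4. **Biomarker selection** — one-way ANOVA screening plus Tukey HSD pairwise
   tests; a feature that separates one severity group from all three others
   (p < 0.05) is a group discriminator, and the deduplicated union of the
   four groups' discriminators is the acoustic biomarker. An optional
   linear-SVM recursive-elimination ranking selects top-k subsets.
5. **Classification** — logistic regression, linear SVM (C = 1.0), or a
   small 50/25 ReLU network with 20% dropout, under stratified 10-fold
   cross-validation with fold-internal standardization.

Because no clinical recordings ship with the package, `sdbsound.synthetic_data`
generates seeded cohorts with AHI-controlled structure (breathing-cycle
modulation, severity-scaled snore bursts, 10–60 s silence gaps at the target
hourly rate) so every stage is testable end to end.

## CLI

```sh
# write a synthetic cohort (WAVs + hypnograms + roster + ground truth)
sdbsound simulate --n-per-group 5 --duration-s 600 --seed 1 --out runs/data

# full pipeline: extract -> select -> classify, with a manifest
sdbsound run-all --data runs/data --out runs/demo

# individual stages
sdbsound preprocess --wav runs/data/severe_00.wav \
    --hypnogram runs/data/severe_00.hyp.tsv --out clean.wav
sdbsound extract  --data runs/data --out runs/demo
sdbsound select   --features runs/demo/features.csv --roster runs/data/roster.csv --out runs/demo
sdbsound classify --features runs/demo/features.csv --roster runs/data/roster.csv \
    --biomarker runs/demo/biomarker.json --classifier logistic \
    --feature-set biomarker+qtm --task four_group --out runs/demo
```

Configuration uses flat dotted YAML keys (see `sdbsound/config.py` for the
full key set), e.g. `features.window_s: 2.5`; CLI flags override file values.

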