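# eegcsp

Common spatial patterns (CSP) and surface-Laplacian-mask feature extraction
for separating two groups of EEG records (healthy controls vs. Parkinson's
disease patients) recorded under auditory oddball tasks, together with a
classical per-band baseline feature set and a classifier evaluation harness.
A synthetic cohort generator with planted ground truth makes the whole
pipeline testable end to end without any data download.

## Pipeline

1. **synthetic** — generate a labelled two-group cohort: 60-channel records
   at 500 Hz with 1/f background noise (optionally mixed through per-group
   channel mixing matrices), plus group/task-dependent event-locked
   responses for the *Standard*/*Novelty*/*Target* tasks.
2. **preprocess** — native record I/O (raw float32 matrix + JSON sidecar,
   EDF/EDF+ import), zero-phase least-squares FIR band-pass (0.1 Hz low
   edge; 4/13/20/30 Hz upper edges), 4-s onset-centered epochs
   (2000 samples at 500 Hz, onset at index 1000), and interval extraction
   (250/500/1000 ms after onset).
3. **groupavg** — pooled group/task average interval: every interval of
   every record weighted equally (the alternative average-of-averages is
   selectable).
4. **csp** — the two-step CSP: trace-normalized class covariances, whiten
   the composite, diagonalize the whitened pd-class covariance. Provides
   projection, log-variance component features, spatial patterns (inverse
   of W) and a channel-informativeness ranking on the montage grid.
5. **laplacian** — small (d=1) and large (d=2) masks on the electrode grid:
   center minus a quarter of its four neighbors, averaged over the analysis
   interval of the record's average interval.
6. **baseline** — sample entropy, RMS, median and peak frequency per band
   (delta/theta/alpha/beta/gamma) x task x channel (3600 columns for a
   60-channel record).
7. **evaluate** — fixed stratified 60/40 split, six classifiers (SVM
   poly/RBF, Gaussian naive Bayes, LDA, QDA, decision tree), PD-positive
   accuracy/sensitivity/specificity, and a parameter-grid runner (band x
   interval length x feature set x classifier). CSP is always fitted on the
   learning set only.

## CLI

```sh
eegcsp simulate --n-per-group 25 --duration 60 --seed 1 --out cohort/
eegcsp split --seed 1 --out split.json cohort/manifest.json
eegcsp filter --low 0.1 --high 20 cohort/control_00 filtered
eegcsp csp-fit --split split.json --interval 0:500 --high 20 \
    --out model/ cohort/manifest.json
eegcsp csp-features --model model/ --components MxPMnC2,MxPMnC3 \
    --out csp.csv cohort/manifest.json
eegcsp laplacian-features --masks Fz:1,F3:2,F4:2 --out lap.csv \
    cohort/manifest.json
eegcsp grid --split split.json --high 4,20 --lengths 250,500 \
    --out grid.csv cohort/manifest.json
```

Mask syntax is `center:d` (`Fz:1` small, `F3:2` large). Component names:
`MxPMnC1..3` maximize pd-group variance, `MnPMxC1..3` minimize it
(`MnPMxC1` is the most extreme minimizer). A custom electrode layout can be
supplied with `--layout` as a `label<TAB>row<TAB>col` table; the packaged
default is a 60-channel 10-10 grid.

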