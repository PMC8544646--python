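# mvpac

Multivariate phase–amplitude coupling (PAC) analysis for multi-channel,
multi-trial EEG-like recordings.

The pipeline computes a complex reduced-interference (Choi-Williams-smoothed
Rihaczek) time–frequency distribution per trial and channel, extracts
band-limited amplitude envelopes and band-analytic phases, forms the
amplitude-normalised trial-ensemble modulation index for every ordered
channel pair and frequency pair, gates it by block-swap surrogate
significance thresholds, band-averages the survivors into directed
`N x N` coupling networks, and stacks networks over `M` frequency-band pairs
and `S` subjects into a nonnegative 4-way tensor.  Higher-order robust PCA
(Singleton model, solved by an alternating-direction augmented Lagrangian
method) splits that tensor into a low-rank background part and a sparse
task-evoked part; coupled channel pairs are read off the sparse part.  A
nonnegative CP (PARAFAC) decomposition with DIFFIT rank selection and a
network-averaging baseline are included as comparators, together with a
synthetic multi-channel EEG generator with planted, ground-truth couplings
and the detection/identification experiments that validate the whole chain.

## Layout

| module | contents |
| --- | --- |
| `mvpac.tfd` | ambiguity function, RID-Rihaczek distribution, amplitude/phase extraction |
| `mvpac.pac` | modulation index, time averaging, block-swap surrogate thresholds |
| `mvpac.networks` | significance gating, band-averaged networks, 4-way PAC tensor |
| `mvpac.horpca` | unfold/fold, SVT, soft thresholding, HoRPCA (ADAL) |
| `mvpac.cp` | nonnegative CP via HALS, DIFFIT rank selection, factor-peak detection |
| `mvpac.simulate` | power-law noise, cross-correlation, coupling injection, lead field, noise |
| `mvpac.experiments` | subject networks, tensor assembly, detection experiments 1 and 2 |
| `mvpac.classify` | sparse-representation nearest-neighbour classification, cross-validation |
| `mvpac.io` | EDF/BDF ingestion, HDF5 persistence, run configuration, manifests |

## CLI

A `mvpac` console script exposes the stages:

```sh
mvpac simulate --out data.h5                 # synthetic dataset + truth manifest
mvpac build-tensor --data data.h5 --out tensor.h5
mvpac decompose --input tensor.h5 --lam auto --out dec.h5
mvpac parafac --input tensor.h5 --rank auto --out cp_out/
mvpac experiment1 --reps 5 --out exp1.tsv
mvpac experiment2 --sweep snr --reps 5 --out exp2.tsv
mvpac classify --train err.h5 --train crr.h5 --folds 5 --out cls.tsv
```

Every stage accepts `--config run.yaml` (schema-checked; unknown keys are
rejected) and writes a manifest with the per-stage seed so outputs are
reproducible bit for bit.

## Desk-scale conventions

The experiment drivers run a scaled-down version of the validation studies:
16 channels/dipoles on a synthetic spherical lead field, 1 s trials at
128 Hz, and a few sampled frequencies per band pair instead of every integer
frequency.  Two scaling choices matter when comparing against full-scale
numbers:

* the nominal SNR axis refers to broadband white noise at a 512 Hz sampling
  rate; the drivers shift the applied SNR by `10*log10(512/fs)` so that the
  in-band noise density matches the nominal axis at any desk-scale rate;
* per-subject presence detection uses a family-wise (Bonferroni-corrected)
  surrogate threshold, the small-grid analog of averaging hundreds of gated
  frequency pairs per band.
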