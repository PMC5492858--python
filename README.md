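# bittern

Birdsong species recognition for wireless acoustic sensor networks
(WASNs), built around the monitoring problem of the common bittern
(*Botaurus stellaris*), an endangered heron whose male booming call is a
narrowband signal centered near 150 Hz — acoustically unmistakable among
the broadband calls of the 19 wetland species it cohabits with.

The package implements the centralized recognition computation such a
network runs on audio streamed from its sensor nodes, plus the analytic
arithmetic needed to decide whether a deployment is feasible:

* **Front end** — 30 ms frames (1440 samples at 48 kHz) with 50%
  overlap; corpus annotation by retaining the 35% highest-energy frames
  of each recording as birdsong.
* **Features** — 13 Mel-frequency cepstral coefficients (MFCC) per
  frame: Hamming window, 2048-point power spectrum, a 48-filter
  triangular bank spanning 20 Hz–16 kHz (linear centers up to 1 kHz,
  Mel-spaced above), log energies, DCT-II.
* **Classifier** — one Gaussian mixture model per species,
  M = 32 full-covariance components in d = 13 dimensions, trained by
  k-means-initialised EM. A frame x is labelled
  `argmax_i  P_i(x; θ_i) = Σ_k w_k N(x; μ_k, Σ_k)`, with |Σ_k| and
  Σ_k⁻¹ precomputed and all scoring in the log domain.
* **Evaluation** — stratified 10-fold cross-validation, per-fold
  per-class accuracies, and a row-percentage confusion matrix.
* **Synthetic corpus** — a seeded 20-species community (30 clips of
  10 s per species) emulating the spectral contrast of the real one:
  a 150 Hz tonal boomer among harmonic, chirping and clattering species
  up to 15 kHz, with silence gaps and white noise at a chosen SNR.
* **Deployment budget** — per-frame floating-point operation counts of
  GMM scoring, sustained system FLOPS, the number of sensors servable in
  real time by the FPGA feature pipeline, and resource-fit percentages
  against the Zynq-7000 device family.

The MFCC and GMM stages are scikit-learn-style estimators
(`MFCCExtractor`, `GMMSpeciesClassifier`) and compose with sklearn
pipelines and model selection; every stage is also exposed as plain
functions (`frame_signal`, `select_high_energy_frames`, `extract_mfcc`,
`fit_gmm`, `classify_frame`, `run_cv`, `gmm_flop_count`, ...).

## Worked example

```python
import numpy as np
from bittern import (CorpusSpec, MFCCExtractor, GMMSpeciesClassifier,
                     generate_corpus)
from bittern.evaluation import run_cv

spec = CorpusSpec(clips_per_species=6, clip_duration=4.0, seed=7)
clips, manifest = generate_corpus(spec)           # 20 species x 6 clips
ext = MFCCExtractor(energy_fraction=0.35).fit()   # top-35% energy gate
feats = ext.transform(clips)
X = np.vstack([f.vectors for f in feats])
y = np.concatenate([[f.label] * f.n_frames for f in feats])
report = run_cv(X, y, k=5, seed=7, n_mixtures=8)
print(X.shape, round(report.mean_class_accuracy.mean(), 4))
```

prints

```
(11160, 13) 0.9979
```

— 11,160 gated 13-dimensional feature vectors, and a mean per-class
5-fold cross-validated accuracy of 99.8% on this small, clean (30 dB
SNR) synthetic corpus. Synthetic species are far easier to separate than
field recordings; see `docs/methods.md` for what this does and does not
demonstrate.

The deployment side from the command line:

```sh
$ bittern budget
GMM scoring, n=20 classes x M=32 mixtures, d=13:
  subtractions           8,320
  multiplications      117,120
  additions            100,480
  total per frame      225,920
system load: 451,840,000 FLOPS (30 sensors, 15 ms frame rate)
real-time sensor capacity: 30 streams
  XC7Z010: DSP 38.75%, BRAM_BLOCKS 121.67%, LUT 25.51%, FF 21.81% -> does NOT fit
  XC7Z020: DSP 14.09%, BRAM_BLOCKS 52.14%, LUT 8.44%, FF 7.22% -> fits
  ...
```

The full pipeline is also available as subcommands:
`bittern synth | extract | train | classify | evaluate | budget`.

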