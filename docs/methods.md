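# Methods

## The recognition chain

The recognizer labels 30 ms audio frames, not whole recordings. A clip
sampled at 48 kHz is cut into 1440-sample frames advancing 720 samples
(50% overlap). Corpus annotation is purely energetic: for each
recording, the `ceil(0.35 · R)` frames with the largest sum of squared
samples are kept as birdsong and the rest discarded. Energy is measured
on raw (unwindowed) frames and the gate is applied *before* windowing,
treating the selection as corpus pre-processing upstream of the feature
chain; the order is a config decision (`energy_fraction` on
`MFCCExtractor`), not a property of the signal model.

Each retained frame is multiplied by a symmetric Hamming window
`0.54 − 0.46·cos(2πn/(L−1))` (endpoints exactly 0.08), zero-padded to
2048 points, and transformed; the one-sided magnitude-squared spectrum
enters a 48-filter triangular bank. Filter outputs are floored at 1e−12
before the natural log — a digital-silence frame otherwise produces
−∞ — and an orthonormal DCT-II reduces the 48 log energies to 13
cepstral coefficients. Coefficient 0 is retained: scaling the waveform
by c shifts every log energy by 2·ln c, which the DCT maps entirely
onto coefficient 0 and leaves coefficients 1–12 invariant (this exact
property is tested).

### The filter bank

The bank's specification — 48 filters "from 20 to 1000 Hz" with the
rest Mel-spaced up to 16 kHz — is implemented as a hybrid grid: the
number of filters assigned to the linear low band equals the number of
centers a pure-Mel 48-filter layout would place at or below 1 kHz
(12 with the defaults), spaced evenly over [20, 1000] Hz; the remaining
36 centers are Mel-spaced (`mel(f) = 2595·log10(1 + f/700)`) over
(1000, 16000] Hz. Each triangle spans the previous center to the next,
giving 50% overlap between neighbours. Setting `split_freq ≤ fmin`
recovers a conventional all-Mel bank; neither reading is asserted as
canonical, both are reachable through configuration.

## The classifier

One mixture per species. For species i with parameters θ_i:

    P_i(x; θ_i) = Σ_{k=1..M} w_k · N(x; μ_k, Σ_k),  Σ_k w_k = 1

with full covariances (M = 32, d = 13 by default). Full rather than
diagonal covariance is deliberate: the per-frame multiplication count
n·M·(d²+d+1) used by the deployment budget is exactly the cost of a
d×d Mahalanobis product per component, so the budget and the classifier
describe the same algorithm.

Training is EM initialised from k-means (k-means++ seeding, Lloyd
iterations, an emptied cluster re-seeded from the farthest point;
fixed seed, default 0). Initial weights/means/covariances are the
cluster fractions, means and scatters. Each M-step adds `reg·I`
(default 1e−6) to every covariance; EM stops when the relative gain in
total log-likelihood drops below `tol` (default 1e−6) or at `max_iter`
(200). The per-iteration log-likelihood history is kept in the model
metadata and monotonicity is asserted — not assumed — on every training
run in the cross-validation loop, with a relative slack of 1e−9 for
floating-point wiggle.

Scoring uses cached `log|Σ_k|` and `Σ_k⁻¹` (a missing cache is an
error, never a silent recompute, because precomputation is part of the
deployment cost contract) and log-sum-exp in the log domain: the
linear-domain mixture underflows at d = 13, while the argmax over
species is unchanged. Ties break to the lowest species index; they have
measure zero in float data. Classification is invariant to a common
rescaling of all models' weights (a pure log-domain shift), which is
tested directly.

Model banks serialize to versioned JSON including the caches; a file
without caches loads with a rebuild and a logged warning, a file whose
weights do not sum to 1 or whose covariance is not positive definite is
rejected.

## Evaluation protocol

Stratified 10-fold cross-validation. `frame` mode stratifies individual
feature vectors — the protocol matching a split of "audio samples" —
and is the default; `clip` mode (grouped stratification) keeps all
frames of a recording on one side of the split and is provided because
frame mode leaks intra-clip correlation, which flatters accuracy on
strongly autocorrelated data. Whether folds should be stratified per
species or split globally was an open choice; stratified was chosen so
every fold sees every species.

The pooled confusion matrix keeps raw counts; row percentages are
computed unrounded and rounded to 2 decimals only for display, so
rounding never compounds. Two-route agreement (matrix diagonal vs raw
prediction lists) and count conservation are asserted in tests.

## The synthetic community

The generator emulates the *structure* the recognizer assumes, not
birdsong realism: per-species clips of calls separated by silence over
white Gaussian noise. Defaults are the study conditions: 20 species,
30 clips per species, 10 s clips at 48 kHz. Species 8 is the bittern
surrogate — a frequency-wobbled tone at 150 Hz, bandwidth 50 Hz; the
other 19 species sit on a geometric grid from 300 Hz to 15 kHz,
cycling through three textures (harmonic stacks, 50 ms chirp trains,
band-passed pulsed noise) so spectral neighbours differ in structure.
Species names follow the reference wetland community whose per-species
recording durations ship as package data (total 8 h 18 min 10 s).

Per-clip parameters with no external anchor were fixed once at values
typical of curated field clips: SNR 30 dB (clean, close-mic recordings;
the evaluation criteria assume ≥ 20 dB), silence fraction 0.4, call
durations 0.4–1.0 s with repetition period 1.4× the call duration so
that calls cover ≈ 43% of each clip — comfortably above the 35% energy
gate, so retained frames are almost all call frames. Noise is scaled to
the requested SNR against the whole-clip signal power; silence is true
digital zero plus the noise floor, giving the energy gate a well-defined
target. Determinism is bit-exact: per-clip seeds derive from the corpus
seed by a fixed affine hash, and identical `CorpusSpec`s produce
identical WAV bytes.

**What passing tests show.** Synthetic species have disjoint, stable
spectral envelopes and no channel effects, so near-ceiling
cross-validated accuracy here demonstrates that the pipeline is
implemented correctly and separates what it is designed to separate —
not that the recognizer reaches any particular accuracy on field
recordings, whose intra-species variability, overlapping singers and
propagation effects the generator deliberately omits.

## Cross-validation problem size

The acceptance-level CV run uses the default corpus (600 clips,
≈ 233 gated frames per clip) and strides the retained frames, keeping
every 4th: at 50% overlap adjacent frames share half their samples and
carry little independent information, and ≈ 59 frames per clip
(≈ 1770 per species, well above the M·(d+1) = 448 rule of thumb for a
32-component fit) is the problem size chosen for the 10-fold run. The
stride is a choice about the CV sample, not about the corpus or the
feature chain.

## Deployment budget

Per-frame scoring cost for n classes, M components, d dimensions:
subtractions n·M·d, multiplications n·M·(d²+d+1), additions
n·M·((d−1)²+d) — exactly linear in n and M. At the reference
configuration (20, 32, 13) this is 225,920 operations per frame;
at a 15 ms frame rate and 30 sensors, 451,840,000 FLOPS sustained.

Sensor capacity is `floor(hop / latency)` with latency
`cycles_per_frame / clock_hz`: the bundled feature-pipeline figure of
49,156 cycles at 100 MHz gives 491.56 μs per frame (sometimes quoted
rounded as 500 μs; capacity is computed from exact cycles and is 30
either way against the 15 ms hop). A partial sensor is no sensor, hence
the floor; capacity 0 raises a warning.

Resource fit reports required/available per FPGA resource as
percentages rounded half-even to 2 decimals, against the bundled
Zynq-7000 capacity table. The bundled per-component IP figures come
from separate place-and-route runs and intentionally do not sum to the
packaged-IP TOTAL row, which is what fit computations use. One
published percentage (the smallest part's block-RAM load) is truncated
at 121.66 where half-even rounding of 73/60 gives 121.67; comparisons
tolerate ±0.01 for this reason.

## Known limitations

* Frame-level decisions only; no clip-level aggregation or
  one-vs-all detector for the target species.
* No delta/acceleration features, cepstral mean normalisation, or
  fixed-point emulation of the FPGA datapath.
* Inputs must already be at the configured rate (48 kHz default);
  there is no resampler.
* The white-noise, silence-plus-calls clip model contains no
  reverberation, distance attenuation or competing singers, so the
  energy gate's behaviour on real soundscapes is untested here.
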