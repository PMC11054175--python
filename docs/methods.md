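# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical conventions a user should know.

## Signal chain

**Sampling and segmentation.** Analysis runs at 22,050 Hz; 44.1 kHz input
is decimated by exact rational polyphase filtering (no drift). The
audible sound types of interest (biophonies up to ~8 kHz, geophonies
lower) sit comfortably under the 11,025 Hz Nyquist. One-minute files are
cut into non-overlapping 12-s segments (264,600 samples); a trailing
remainder shorter than 12 s is dropped, so a 60-s file yields exactly
five segments and segment concatenation reproduces the first 5×264,600
samples bit-for-bit.

**Spectrograms.** Each segment is transformed with a 1,028-point Hamming
window (a₀ = 0.53836, a₁ = 0.46164 — the "exact" coefficient pair, not
the rounded 0.54/0.46) and hop 514 (half-window overlap). The transform
length equals the window length, giving 1,028/2 + 1 = 515 one-sided
frequency bins (21.45 Hz each). Frames are *centered*: the waveform is
reflect-padded by half a window on each side, so the frame count is
1 + ⌊264,600/514⌋ = 515 and the output is square. Uncentered framing
would give 513 frames and a non-square matrix. Magnitudes are compressed
as 20·log₁₀(|S| + 1e−10) and min–max scaled to [0, 1] per spectrogram:
dB compression keeps weak high-frequency biophony visible next to loud
low-frequency energy, and the [0, 1] range matches the decoder's sigmoid
output. Two consequences are deliberate and tested: a constant (e.g.
all-zero) segment maps to the all-zero spectrogram, and any positive
rescaling of the waveform leaves the spectrogram unchanged (gain
invariance — recorder gain differences do not enter the features).

## Autoencoder

The encoder applies four strided convolutions (kernel 3; strides 3, 3, 3,
2; paddings 1, 1, 1, 0; channels 1→16→32→64→64) with ReLU activations,
tracing 515 → 172 → 58 → 20 → 9 spatially; the flattened 64×9×9 bottleneck
is the 5,184-d embedding (≈2% of the 265,225 input pixels, and
non-negative because it is post-ReLU). The decoder mirrors this with four
transposed convolutions (ReLU between, sigmoid last); output paddings are
solved automatically so the reconstruction is exactly 515×515, and
construction fails with the achieved spatial trace if a configured
schedule does not reach 9×9. The kernel/stride schedule is the minimal
standard one reaching that trace; alternatives are configurable and
validated.

Training minimizes mean squared reconstruction error with Adam
(β = 0.9/0.999). Weights and biases initialize Kaiming-style uniform
(±1/√fan-in) from the config seed — the field-standard scheme, which also
makes the "untrained model" a fair baseline: with zero biases a sigmoid
decoder would already output the near-optimal constant ≈0.5 for min–max
normalized spectrograms. The held-out fraction (default 2%, minimum one
item) is split at the *recording* level when segment ids are available,
so near-duplicate segments of one file never straddle the split; test MSE
is logged once per epoch, train MSE every iteration, and a NaN loss
aborts with a diagnostic.

The layer engine (strided conv, transposed conv as its exact adjoint,
ReLU, sigmoid, Adam) is implemented in numpy with explicit gradients,
verified against central finite differences to 1e−6 and an adjoint
identity ⟨conv(x), y⟩ = ⟨x, convᵀ(y)⟩ in the test suite.

**Problem sizes.** Default batch is 70 segments (14 one-minute files),
matching duty-cycled batch acquisition at corpus scale. The package's own
experiments and tests run on desk-scale corpora (24–48 files, 120–240
segments) and therefore use smaller batches (2–10) and 1–15 epochs so the
optimizer takes a few hundred steps — the quantity that actually governs
convergence — with learning rates 1e−3 to 3e−3.

## Projection

Embeddings are min–max normalized per feature before projection or
classification (the features are non-negative ReLU activations, so
min–max respects their natural range; z-scoring would not). PCA uses the
full SVD solver and exposes the smallest-k-for-target-variance rule
(default 90%). t-SNE routes to the exact O(n²) algorithm whenever more
than 3 output dimensions are requested — tree-accelerated implementations
are capped at 3 — so corpora should be subsampled to a few thousand
points before a 60-d t-SNE. UMAP runs with 15 neighbors and min_dist 0.1
and is deterministic under a fixed random state.

**Inverse mappings.** PCA inverts exactly on its retained subspace.
UMAP's inverse here is a k-nearest-neighbor barycentric interpolation
(k = 5, inverse-distance weights) over the fitted pairs of reduced
coordinates and normalized inputs: the simplicial inverse that umap-learn
ships triangulates the *reduced* space and is intractable beyond ~3
dimensions, while the k-NN inverse works at any output dimensionality,
is exact on training coordinates, and is what the prototype-decoding
pathway needs at 60-d. t-SNE has no inverse and the API raises a
capability error rather than approximating one.

## Clustering and validity

K-means is Lloyd's algorithm: assign each point to its nearest centroid
(Euclidean; ties break to the lowest cluster index), recompute centroid
means, iterate to an assignment fixpoint. Initialization is k-means++
from the seed with 10 restarts, keeping the best-energy solution; empty
clusters are repaired by reseeding to the farthest point. The energy
E = (1/N)Σ‖xᵢ − c(aᵢ)‖² is asserted non-increasing at every iteration,
and on exhaustively enumerable instances (n ≤ 8, k = 2) the restarted
algorithm attains the global partition minimum in tests.

Validity indices follow their standard definitions — Silhouette
(b−a)/max(a,b) with the singleton-cluster value fixed at 0,
Calinski–Harabasz Tr(B)/Tr(W)·(N−k)/(k−1), Davies–Bouldin with σ = mean
point-to-centroid distance — implemented directly and cross-checked to
1e−9 against both naive double-loop oracles and scikit-learn. Silhouette
and DB distances use exact (difference-based) norms rather than the
expanded quadratic form, which loses ~1e−8 of precision. The K sweep
(default 3–35) tabulates all three indices with appended Mean and STD
rows and flags the best K per metric. Duplicate centroids would make a DB
ratio infinite; the value is returned non-finite rather than masked.

## Interpretation

Prototype spectrograms decode a cluster's representative feature vector:
the element-wise mean of member embeddings (always available), or the
reduced-space centroid mapped back through the projection inverse
(PCA/UMAP only). When clustering ran in the full embedding space the two
pathways coincide by definition. Diel histograms count member segments
per local wall-clock hour (0–23) with a conservation invariant — summed
over clusters they reproduce the global hourly distribution. No
sunrise/sunset normalization is applied; for equatorial sites day length
is nearly constant year-round, and elsewhere the hour axis should be
interpreted accordingly.

A caveat on reading prototypes: the dominant band of a *broadband*
cluster (e.g. a 1 kHz-wide insect chorus) is a plateau tens of bins wide,
so the single argmax row is only meaningful to within that plateau; for
tonal sources (an anuran carrier) it is sharp to a few bins. The
acceptance tests assert center localization for the tonal class and
in-band placement for broadband classes for exactly this reason.

## Supervised baseline

Random Forest with 100 trees, maximum depth 16, on a seeded stratified
80/20 split. Accuracy, precision, recall and F1 are computed directly
from the 2×2 confusion matrix with "forest" as the positive class;
macro-averaged recall/F1 are reported alongside the positive-class
values because cover classes are typically imbalanced and the two
conventions differ. `compare_feature_spaces` holds the split, seed and
hyperparameters fixed across spaces so scores are directly comparable,
and accepts externally computed feature tables (e.g. acoustic-index
vectors) under the same contract.

## Synthetic corpora

The generator emulates the *structure* that matters to the pipeline —
spectral placement, temporal scheduling, amplitude ratios, file/metadata
conventions — not acoustic realism. Components are synthesized as:
4th-order Butterworth band-passed white noise (insect bands; chosen for
controllable spectral support), raised-cosine pulse trains on a sine
carrier (anuran choruses), Hanning-windowed linear FM sweeps (bird
chirps), broadband white noise (rain), sub-500 Hz low-passed noise
(river). Signals are RMS-normalized so amplitude ratios are exact; at
least 80% of each band-limited component's power lies within ±bandwidth
of its center (tested by periodogram). Scheduling is by hour-of-day sets;
a file contains exactly the components active at its hour, mixed over a
Gaussian noise floor, written as 16-bit PCM WAV with
`<RECORDER>_<YYYYMMDD>_<HHMMSS>.wav` names and a relocatable manifest
(paths relative to the manifest). Identical seeds yield byte-identical
corpora. The default study conditions used in tests place three
biophonies in disjoint spectral and diel niches (2 kHz pulses 18:00–05:00,
3.5–6 kHz chirps 06:00–11:00, 6 kHz band 12:00–17:00), 60-s files at
22,050 Hz, noise floor 0.001 RMS — a clean planted-structure regime.

What passing on this synthetic data does **not** show: robustness to
overlapping sources, reverberation and distance attenuation, wind and
anthropophony, recorder self-noise spectra, or class imbalance as found
in real deployments. Real-data behavior must be assessed on real corpora.

Rain screening is a stand-in heuristic (mean Welch PSD in 600–1,200 Hz
versus a dB threshold, returned with its score for audit); it is exposed
behind a pluggable interface so a published rain-detection method can be
substituted. The all-zero signal scores −∞ and is kept.

## Pipeline and reproducibility

The orchestrator validates the whole YAML config (unknown keys rejected)
before any stage runs, fans per-stage seeds out as global seed + stage
index, caches completed stages by hashing their effective config and
input checksums, and writes a `summary.json` listing every artifact with
a content checksum. HDF5 and npz artifacts are checksummed by dataset
*contents* (string datasets by value), not container bytes, so checksums
are stable across platforms and directories; CSVs store relative paths
for the same reason. Two end-to-end runs with the same config and seed
produce identical summaries — this is asserted in the test suite.

## Known limitations

- The numpy network trains at CPU speed; it is sized for desk-scale
  corpora (hundreds of segments), not the ~10⁵-segment scale of a real
  deployment, where a GPU framework should replace the engine behind the
  same module surface.
- t-SNE at 60 output dimensions is O(n²) exact; subsample first.
- The UMAP inverse is an interpolator: it cannot extrapolate outside the
  convex region spanned by training points.
- The rain filter is a band-energy heuristic, not a validated detector.
- Cover labels in the synthetic generator alternate by recorder and are
  not acoustically informative; classification claims are exercised on
  separable feature fixtures instead.
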