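# Methods

This note documents the signal model, the algorithmic choices and the
numerical conventions behind `ducksex`, including the points where the
design was genuinely open and what the synthetic benchmarks do and do not
demonstrate.

## Signal model and preprocessing

Input is mono 16-bit PCM WAV at 44 100 Hz, normalized to [−1, 1] by
2^(bits−1). Stereo files and other sampling rates are rejected rather than
silently converted (an undocumented downmix or resample changes energy and
Mel-bin alignment); an explicit `resample=True` enables polyphase FIR
resampling.

Pre-emphasis applies `y(n) = x(n) − α·x(n−1)` with α = 0.95. The first
output sample passes through unchanged — no history before the recording
exists, and inventing an `x(−1)` would make the filter depend on an
arbitrary convention.

Duckling calls are treated as quasi-stationary over 10–30 ms, so analysis
frames are 25 ms long. The hop is 10 ms, standard speech practice, giving
60% overlap. At 44 100 Hz a 25 ms frame is 1102.5 samples; the length is
floored to L = 1102 for determinism. Trailing samples that do not fill a
frame are dropped: `num_frames = 1 + floor((len − L)/hop)`. The Hamming
window `w(n) = 0.54 − 0.46 cos(2πn/(N−1))` is applied only where spectra
are computed (see below), and applying it twice is a state error.

## Endpoint detection

The detection statistic is the zero-product `K(i) = Z(i)·E(i)` of
short-term energy `E(i) = Σ x_i(n)²` and zero-crossing rate
`Z(i) = ½ Σ |sgn x_i(n) − sgn x_i(n−1)|`, with `sgn 0 = +1` and the n = 0
boundary term comparing a frame's first sample with itself (frames are
independent units; reaching into the previous frame would couple detection
to the hop). K is large only for frames that are simultaneously loud and
rich in ≥ kHz content, which suppresses both low-frequency stepping noise
(high E, low Z) and faint broadband noise (high Z, low E).

Detection runs on **unwindowed, pre-emphasized** frames. Unwindowed,
because the Hamming taper attenuates exactly the frame-edge sign changes Z
counts; pre-emphasized, because the front end frames the pre-emphasized
signal once and detection shares those frames.

Segmentation is dual-threshold hysteresis: segments are seeded where
`K ≥ T_high`, extended while `K ≥ T_low`, merged across gaps of at most
`merge_gap` frames (default 5) and discarded below `min_frames` (default
10, ≈ 115 ms, rejecting clicks while keeping the shortest calls). The
thresholds are relative, `T_high = 0.10·max K` and `T_low = 0.02·max K`,
so detection is gain-invariant and adapts per recording; both are exposed
as configuration.

Two recording-level refinements sit above the pure hysteresis primitive:

* **Noise-floor subtraction.** In broadband noise the zero-crossing rate
  of silence is high (≈ L/2 per frame), so the noise plateau of K can
  exceed a small fraction of its maximum and pure max-relative hysteresis
  would never terminate a segment. Whenever silence dominates a recording,
  the per-recording median of K estimates that plateau; the pipeline
  subtracts it (clipping at zero) before thresholding, making the relative
  thresholds refer to call peaks above the floor. For clean or mostly
  voiced material the median is zero or the subtraction merely rescales,
  and the primitive behaves exactly as specified.
* **One-frame hangover.** A call's decay tail drops below `T_low` about
  one frame before the call truly ends, so each segment is extended by one
  frame at its end (re-merging any overlaps). This is the classic
  release-smoothing used in voice-activity detectors.

With these defaults, both endpoints of ≥ 95% of synthetic calls at 20 dB
SNR are recovered within ±2 frames (±20 ms) of ground truth; the measured
rate is 100% across seeds (200 calls per run).

## Cepstral features

Per voiced frame: zero-pad to `n_fft = 2048` (next power of two above
L = 1102), FFT, spectral line energies `E(i,k) = |X(i,k)|²`; M = 26
triangular filters with edges equally spaced on the Mel scale
`mel(f) = 2595·log10(1 + f/700)` between 0 Hz and Nyquist, peak weight
exactly 1 at the center bin; filterbank energies
`S(i,m) = Σ_k E(i,k)·H_m(k)` floored at ε = 1e−10 so the subsequent log is
finite on silent frames; then

    mfcc(i,n) = sqrt(2/M) · Σ_{m=0}^{M−1} log S(i,m) · cos(πn(2m+1)/(2M)),  n = 1..12.

Conventions worth stating: the DCT scale is the orthonormal-style
`sqrt(2/M)`; the cosine phase offset is `2m+1` (DCT-II) by default, with a
`printed` option for the `2m−1` variant found in parts of the MFCC
literature — both are pinned against a double-loop oracle in the tests.
The 0th coefficient (overall log-energy) is excluded by default
(`include_c0` restores it); 12 coefficients are kept. M = 26 filters and
`n_fft = 2048` are defaults, not dogma, and are configurable.

Dynamics are regression deltas over a ±2-frame window,
`d_t = Σ_τ τ(c_{t+τ} − c_{t−τ}) / (2Στ²)`, with edge frames replicated;
the second order is the delta of the delta. Deltas are computed **within**
each detected segment so that call boundaries do not bleed into the
dynamics columns. The final layout is `[c1..c12 | Δ1..Δ12 | ΔΔ1..ΔΔ12]`,
36 columns always.

A gain change `x → c·x` shifts each static coefficient by the closed-form
constant `log(c²)·sqrt(2/M)·Σ_m cos(·)` and leaves the delta columns
exactly invariant; the z-score normalization (training-set statistics
only, std floored at 1e−8, applied unchanged to validation/test data)
removes the residual shift.

## Classifiers

Three frame-level softmax classifiers over the 36-vector, with male as
class 1:

* **BPNN**: dense 36→18→9→4→2, ReLU (887 parameters).
* **DNN**: dense 36→48→32→16→8→2, ReLU, dropout 0.1 after each hidden
  layer.
* **CNN**: the frame vector reshaped to a 6×6 single-channel map, four 3×3
  stride-1 same-padding convolution blocks with 128, 128, 64 and 32
  channels (ReLU + dropout 0.3 each, no pooling), flatten, dense softmax
  head. The 6×6 reshape imposes an arbitrary locality prior on unordered
  feature dimensions; it preserves the single frame as the classification
  unit. An optional `context_window=w` mode feeds a w×36 map of
  consecutive frames instead for genuine temporal context.

The layers are a self-contained float32 numpy engine with manual
backprop (`ducksex.nets`): He-normal initialization, im2col convolutions,
inverted dropout (inference is deterministic and dropout-free), fused
softmax cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999). All randomness —
init, batch shuffling, dropout masks, validation split — flows from one
seeded Generator, so a (data, seed) pair reproduces training bit-for-bit
on a fixed BLAS.

Training defaults: 100 epochs, batch 256, learning rate 1e−3, 15% of
frames held out for per-epoch validation scoring. Batch 256 is sized for
corpus-scale training sets (10⁵–10⁶ frames); on toy sets of a few hundred
examples it yields one optimizer step per epoch, so the sanity benchmarks
use batch 32. NaN loss aborts with a diagnostic rather than continuing.

## Evaluation protocol

Male is the positive class: recall is the recognition accuracy for male
ducks and specificity for female ducks; accuracy, precision and F1
complete the set, each reported as a percentage to two decimals.
Zero-denominator metrics report 0 with a warning.

A duck's sex is the majority vote over its frames' argmax labels; the
male-vote fraction is recorded per duck. A tie at exactly 0.5 deterministically
reads as male (documented, and irrelevant in practice at thousands of
frames per duck). Mean-probability aggregation is available as an option.

Splitting is always at the duck level — 120 train / 30 test per sex at
full scale, stratified and seeded — and k-fold cross-validation (default
k = 5) likewise stratifies ducks, never frames, so no individual leaks
across partitions. Class balance is enforced by sampling exactly 3000
frames per duck: without replacement when enough voiced frames exist, with
replacement and a warning otherwise.

## Synthetic corpus

The generator emulates the documented acoustics of day-old duckling
calls rather than duck physiology:

* contact calls around a 2500 Hz fundamental; per-duck offset
  ~ N(0, 50 Hz) so individuals differ and the sexes overlap slightly —
  the classification task is learnable but not saturated;
* female contour: flat, with a +150–300 Hz linear glide over the final
  15% of the call; male contour: onset +300–500 Hz above the plateau,
  decaying exponentially with τ = duration/4 (the functional forms are
  this package's choice; only the qualitative shapes are documented);
* 4 harmonics with 1/h amplitude roll-off, phase-continuous synthesis,
  raised-cosine attack (10 ms) and decay (20 ms), peak 0.8;
* calls of 0.15–0.4 s separated by 0.15–0.4 s of silence; white noise at a
  specified in-call SNR (default 20 dB); optional band-limited < 1 kHz
  bursts (pen/stepping noise), and alarm (2800–2900 Hz) / distress
  (> 3000 Hz) call modes for endpoint stress tests only.

What passing on this corpus shows: the chain is implemented correctly and
the statistical machinery (features → frame classifier → vote) extracts a
real contour difference under noise. What it does not show: performance on
real ducklings — real calls have reverberation, overlapping callers,
amplitude-modulated noise and richer within-sex variation, none of which
the generator models. Synthetic duck-level accuracies (100% at the
benchmark condition) are therefore not comparable to field accuracy.

## Problem sizes and benchmark conditions

The shipped benchmarks are scaled to desk hardware as the package's own
test design: the end-to-end benchmark uses 25 ducks per sex (20 train /
5 test) generated at the fixed benchmark seed 42, 150 sampled frames per
duck and an 8-epoch CNN (frame accuracy plateaus near 0.91 there and the
duck votes are decisive); the bookkeeping check runs the full 300-duck
roster at 1 call per duck, relying on documented replacement sampling to
reach 3000 frames each. With only 10 test ducks each individual is worth
10 accuracy points, so duck-level accuracy on re-randomized corpora is
coarse: draws exist where the CNN misreads one or two borderline females
that the BPNN, on identical features, classifies correctly.

## Known limitations

* The 6×6 CNN input geometry is a convention, not a discovery; with
  unordered inputs the convolutional prior can hurt as easily as help
  (see above).
* Endpoint thresholds assume one dominant noise regime per recording; a
  recording that is mostly calls breaks the median-as-noise-floor
  estimate (detection then degrades gracefully to pure max-relative
  hysteresis).
* The manifest assumes one duck per WAV file; multi-duck recordings must
  be split upstream.
* Metrics assume binary sex labels; no abstention class exists.
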