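# Methods

This note records the modeling choices, numerical conventions and
deliberate deviations a maintainer would otherwise have to reverse-
engineer from the code.

## Wavelet layer

The 1D Haar pair uses the orthonormal `1/√2` normalization, so the
transform is an isometry: perfect reconstruction and energy conservation
are testable invariants rather than approximations. The 2D transform is
one level only (that is all the frequency-aware block consumes); the
recursive multi-level 1D form is exposed for analysis but unused by the
network.

Axis convention. For a 2×2 block `[[p,q],[r,s]]` the subbands are
`A=(p+q+r+s)/2`, `H=(p−q+r−s)/2`, `V=(p+q−r−s)/2`, `D=(p−q−r+s)/2`.
`H` is therefore high-pass along the *horizontal axis* (it responds to
vertical edges and vertical stripes) and `V` high-pass along the vertical
axis (horizontal stripes). This is the transpose of the MATLAB/pywt
`cH/cV` naming; the cross-library test encodes the mapping explicitly.
Orientation routing in the frequency-aware block keeps the letter pairing
(`H`→horizontal-stripe attention, `V`→vertical-stripe attention); which
physical stripe orientation lands in which branch follows from the
convention above and is asserted as such in the tests.

Odd spatial extents (stage 4 of a 224 input is 7×7) are edge-replicated
by one row/column at the bottom/right before the transform and cropped
after the inverse; replication adds no spurious high-frequency energy at
the border, and the padding is recorded per subband set so reconstruction
is exact on the original support.

## Windowed attention

Four geometries: big square windows (side 8), small square windows
(side 2), horizontal stripes and vertical stripes (thickness 2). Window
sizes are clamped to the map extent; when one window covers the whole
map, shifting is disabled and the variant degenerates to global
attention (true for the big-window branch at the coarsest stage). Within
a stage, even-indexed blocks use unshifted partitions and odd-indexed
blocks shift by half the window/stripe — the standard alternation.

Shifting is realized by cyclically rolling the grid, tiling with aligned
windows, and masking pairs whose pre-roll regions differ. The defining
equivalence — masked attention on the rolled grid equals unmasked
attention run independently on every window of the shifted partition —
is exported as a checkable predicate and exercised against a dense
oracle. Ragged extents are padded with mask-excluded dummy tokens (which
self-attend for softmax safety), keeping the partition a bijection on
real tokens.

Each attention carries a learnable per-head relative-position bias table
indexed by in-window offsets, zero-initialized. The four subband
branches use independent projection weights.

## Selective state-space layer

Discretization is zero-order hold on the diagonal transition
(`exp(ΔA)`) with the Euler simplification for the input term
(`B̄ = Δ·B`). Per-channel transitions initialize to `−(1…N)` (S4D-real),
`Δ` comes from a softplus-ed low-rank projection with bias initialized
so `Δ ∈ [0.001, 0.1]`, and defaults are state 16, expansion 2, causal
conv width 4. The scan is a length-`L` loop vectorized over batch,
channels and state, with a hand-written adjoint; a literal per-step,
per-channel reference implementation serves as the recurrence oracle.

The bidirectional block wraps two directional scans in the usual gated
form (input projection with expansion, short causal convolution, SiLU,
multiplicative gate, output projection). Each direction applies its own
causal convolution in its own scan order — a single shared convolution
would break exact reversal symmetry of the two-branch construction,
which is a tested property. The output projection is zero-initialized so
the block contributes nothing at initialization; the alternative reading
(a bare ungated S6 layer) was considered and rejected because the gated
form is the standard block and the zero-init already gives the residual
identity the fusion block needs. Scan order over 2D maps is row-major;
the backward branch covers the reverse order.

## Composite blocks

Frequency-aware block residual topology: read literally, the printed
form `F_out = FFN(LN(F_fused + F_in))` makes the FFN output the entire
block output, removing the identity path and crippling optimization. The
default therefore adds the standard outer residual
(`y = F_fused + F_in; F_out = y + FFN(LN(y))`); the literal form remains
available behind `literal_ffn_residual=True`. LayerNorm precedes the
wavelet transform, and normalization is token-wise over channels.

Cross-scale fusion: bilinear resizing (half-pixel centers) is the
default alignment to the coarsest grid; a learnable strided
(patch-concat + linear) reducer is available by configuration.
Concatenation order is stage 1 → stage 4, which makes "the last `C_4`
channels" of the fused sequence unambiguous; the identity-stub test pins
both the order and the slice.

## Model assembly

Stage widths/depths/head counts are not dictated by the architecture
description, so the defaults follow the established hierarchical-
transformer tier: patch 4, base width 96, depths (2,2,6,2), heads
(3,6,12,24) — giving stage resolutions 56/28/14/7 at 224 px. The
classification head takes global average pooling of the fusion output.
Stage outputs are collected *before* each merge, matching the stated
fusion resolutions. The desk-scale preset (`tiny_config`) is 64 px,
width 32, depths (1,1,2,1), heads (2,4,8,16) — resolutions 16/8/4/2 —
chosen so every stage stays non-degenerate while a full training run
fits in CPU minutes.

A note on parameter reachability: with the mandated zero-initialized
fusion output projection, parameters upstream of it receive exactly zero
gradient at step 0 (they become live after the first update). The
connectivity tests therefore randomize that one matrix before asserting
that a scalar loss reaches every parameter. Relative-position bias
tables of 1×1 windows are structurally inert (softmax over a singleton);
reachability is asserted on a configuration whose coarsest windows hold
several tokens.

## Metrics

Precision/recall/F1 use the zero-denominator-gives-zero convention.
Multi-class aggregation is macro (unweighted over classes); micro values
are reported alongside. The rank AUC uses ascending mid-ranks: the
printed rank form with descending ranks contradicts the Mann–Whitney
identity it otherwise matches (perfect separation would score 0), so the
ascending convention is used and verified against both a brute-force
pairwise probability and a trapezoidal ROC integral. ROC curves are
exported per class as (FPR, TPR) CSV via scikit-learn's curve routine;
the AUC itself never goes through that path.

## Training protocol

Defaults: Adam, initial learning rate 1e-4, cosine annealing without
restarts with period 10 epochs, 300 epochs, batch 32, horizontal flip +
ImageNet normalization only, three seeds averaged arithmetically. The
schedule's period (10) ending long before the epoch budget (300) is an
ambiguity in the protocol as stated: the cosine reaches its minimum at
epoch 10 and the implementation holds it there, floored at 1e-6 so late
training still moves (set `lr_floor=0` for the literal endpoint, or
`stretch_schedule=True` to spread the period over the whole run). The
loss is cross-entropy; images are resized bilinearly; evaluation uses
softmax probabilities.

Desk-scale runs (the tests, the examples and the acceptance script) use
the 64 px preset with learning rate 1e-3: the protocol rate of 1e-4 is
calibrated for ~38k optimizer steps, while the desk-scale sanity runs
take 60–200 steps, so the step budget — not the protocol — sets the
appropriate rate. All protocol constants remain the defaults of
`TrainConfig` and are tested as such.

## Synthetic fixture

The generator emulates only the discriminability premise — classes that
differ by orientation- and frequency-specific texture: Gaussian-blob
smooth fields, horizontal and vertical sinusoidal stripes (period
jittered within 2.4–4.4 px so stripe energy stays inside the one-level
detail bands), and a pixel-scale checkerboard, plus additive Gaussian
pixel noise (sd 0.05 by default). It does not model H&E stain
statistics, nuclear morphology, class imbalance, or slide-level
artifacts; passing tests therefore demonstrate that the mechanism works
as specified, not that the model transfers to real histopathology.
A nearest-centroid classifier on the four subband log-energies solves a
held-out split at ≥95%, establishing the task is solvable from
frequency features alone.

## Numerical environment

The network runs on the package's own reverse-mode autodiff engine over
float32 NumPy arrays: a tape of closures per operation, hand-written
adjoints for the scan primitive, and finite-difference tests covering
every composite layer. Softmax and cross-entropy use max-shifted
stabilization; LayerNorm uses eps 1e-5; checkpoints round-trip weights
bit-exactly through `.npz` archives that embed the full configuration
and seed.

## Known limitations

No GPU path, no mixed precision, no stochastic depth/dropout (the
protocol specifies none), no pretrained weights, no slide-level
aggregation. Training at the full 224 px configuration is functional but
CPU-slow; the package's quantitative claims are confined to the
synthetic desk-scale task its tests and acceptance script actually run.
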