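# Methods

## Model

Units in the convolutional layers are leaky integrators: each keeps an
internal state `u` that relaxes toward its convolutional drive at rate
`1/τ` per frame and emits `v = 1.7159·tanh(2u/3)` (the LeCun-scaled tanh,
chosen so unit-variance inputs stay in the responsive range).  The decay
factor `(1 − 1/τ)` gives a layer an exponential memory with effective
window ~τ frames.  τ must be ≥ 1 (τ = 1 is the memoryless limit, where
the network collapses to a static per-frame CNN — a degeneracy we exploit
as an exact test oracle) and is required to be non-decreasing with depth,
mirroring the slow-timescale gradient along the visual hierarchy.

Convolution is implemented as stride-1, valid (no padding)
cross-correlation without kernel flip.  This orientation is what makes
the reference stack's printed dimension chain work out
(48−9+1 = 40, 54−15+1 = 40, 40/2 = 20, 20−7+1 = 14, 14/2 = 7, 7−7+1 = 1)
and is the convention under which saved parameters should be interpreted.
Frames are indexed (row, column); "48×54" means 48 rows by 54 columns.
Within a time step a single bottom-up sweep runs: layer *l* at step *t*
reads layer *l−1*'s activations at step *t*.  Max-pooling takes
non-overlapping window maxima and records argmax positions (first
occurrence on ties) for gradient routing.

The output head is a static affine map of the top hidden layer followed
by a softmax (stabilized by max-subtraction), recomputed at every step.
The head reads the post-activation values `v` by default; reading the raw
internal states `u` instead is supported via
`ArchitectureSpec.head_reads = "internal"` because the source convention
is ambiguous — the two differ only by a fixed squashing and we found no
behavioural difference.

## Training

The delay-response loss supervises only the final `d` steps (the appended
black frames).  The stated window condition `T − t ≤ d` literally covers
`d + 1` steps while the accompanying description says "the final d
steps"; the final-`d` reading is the default and the literal variant is
available (`window="literal"`).  With one-hot targets the per-step KL
divergence reduces to `−ln y_t[c]`; a floor of 1e−12 inside the log keeps
collapsed outputs finite rather than silently clipping gradients.

Backpropagation through time is exact: the error signal at `u_t` is the
activation-gradient at `t` plus `(1 − 1/τ)` times the error at `u_{t+1}`;
pooling routes through the recorded argmaxes; kernel gradients sum over
all spatial placements (weight sharing).  The gradient of the raw input
frame is never needed and is skipped (a pure speed optimization; all
parameter gradients are bit-identical).  Gradients are divided by the
sequence length `T` before the update.  Correctness is enforced by two
independent oracles in the test suite: central finite differences
(relative error < 1e−4 over random tiny networks spanning
τ ∈ {1, 2, 5, 100}) and, at τ = 1, a loop-coded static per-frame network
(agreement to 1e−10).

Updates are per-sequence SGD with weight decay 0.0005 applied to kernel
and output weights, never biases.  The learning rate starts at 0.1 and
follows a bold-driver schedule: ×1.05 if the monitored error decreased,
÷2 otherwise (ties count as "otherwise").  The monitor is the mean
squared error between the output distribution and the target on
supervised steps, *evaluated in a separate pass after the epoch* with the
end-of-epoch parameters.  We first implemented the monitor as a running
accumulation during the epoch; its shuffle-order noise triggered spurious
halvings that collapsed the learning rate on plateaus, and the post-epoch
evaluation — also the more literal reading of "calculated subsequent to
one epoch" — is the default (monitoring mean KL instead is available).
All weights and biases initialize i.i.d. N(0, 0.05²); initial internal
states are exactly zero; shuffling and initialization derive from one run
seed, so runs are bit-reproducible.  No gradient clipping is applied;
divergence raises an error rather than being hidden.

## Synthetic data

The generator renders binary silhouette videos (default 48×54, 40
frames) of a parametric humanoid — torso, head, legs, two articulated
arms — under several archetypes: `bounce` (whole-body vertical
oscillation), `one_arm_wave`, `two_arm_wave` (periodic arm swings),
`walk` (horizontal translation at ~0.8 px/frame with a gait bob), `grow`
(monotone crouch-to-stand), and the exact time reversals `walk_back` and
`shrink`.  A "subject" is a jitter bundle — phase shift, body-scale
multiplier (0.88–1.12), position offsets (±3 columns, ±2 rows) — shared
across that subject's classes and trials; 1% salt-and-pepper pixel noise
is applied per sequence.  Archetypes are matched in marginal pixel
statistics (foreground fraction ≈ 0.11–0.14) and differ in
spatio-temporal structure.

The order-discrimination pair is a sequence and its exact frame reversal
(noise included before reversal), so the two classes share per-frame
pixel histograms exactly and only temporal order separates them; the
test suite verifies that a per-frame logistic classifier stays at
chance.  The walking pair is the default: the slow-layer signal of the
crouch pair proved nearly degenerate because a τ = 100 integrator weights
an identical frame multiset almost uniformly, whereas end-of-episode
position is strongly order-dependent.

What the generator does **not** emulate: articulated limb kinematics,
silhouette extraction noise and holes, camera jitter, inter-subject body
topology differences, and the frame-count variability of real recordings.
Passing results on this benchmark therefore demonstrate the temporal
mechanisms — not recognition performance on real video, which requires
the real dataset and longer training.

## Experiments and problem sizes

All experiment drivers live in `mstnn.experiments`; sizes below are the
package's defaults, chosen to exercise the mechanisms at desk scale.

**Temporal-order discrimination.**  2 classes × 20 sequences (40 frames
+ 15 black), full-width reference stack (6/50/100 maps) with τ = 2/5/100
versus the all-τ=1 ablation, up to 30 epochs (training stops early once
training accuracy holds at 100% for two consecutive epochs — a runtime
cap that can only trigger after the behaviour is demonstrated; the τ = 1
arm never triggers it and runs all 30).  The full-width stack is used
because, with the fixed 0.05 init scale, narrower variants shrink the
top-layer fan-in and with it the activation scale, stalling SGD.  The
ablation cannot exceed chance by construction: its supervised-step
outputs are identical for every input sequence.

**Occlusion robustness.**  3 periodic archetypes × 6 subjects × 2
trials (30 frames + 15 black); 2 subjects held out; reduced-width stack
(4/8/24 maps — the per-frame-visible class signal tolerates the smaller
fan-in); 3 seeds, ≤ 15 epochs each on clean data only.  Trained models
are then evaluated on stripe-occluded held-out sequences (bar width
0–40 px step 5, gap 5 px, moving 2 px/frame right-to-left; bars start
flush with the right edge and wrap — the source convention for phase is
not recoverable, so this is fixed for reproducibility).  The reported
statistic is the Spearman rank correlation of the seed-averaged accuracy
with bar width.

**Contextual memory.**  3 base actions × 6 subjects, all 9 ordered pairs
per subject (42 + 42 + 15 = 99 frames); 2 subjects held out; reduced-width
stack, ≤ 26 epochs; trained twice, with top-layer τ = 100 and τ = 20.
Measured: the mean per-step activation change of the fast (τ=2) versus
slow (τ=100) layer on held-out episodes; the leave-one-subject-out
accuracy of a logistic readout of the final-step (t = 99) top-layer state
predicting the *first* action (chance 1/3), contrasted with the same
readout on the middle layer at the end of the second action (t = 84),
where the τ = 5 memory has decayed by (0.8)^42; and the best held-out
pair-category accuracy per τ.  Snapshot PCA uses centering only (no
standardization); nested cluster structure is summarized as mean
silhouette by second action (coarse) versus mean within-group silhouette
by first action (fine).

**Evaluation protocol.**  Leave-one-subject-out cross-validation;
accuracy recorded after every epoch; aggregation is mean over folds, then
mean over seeds, then max over epochs, rounded to one decimal on the
percent scale — exactly in that order.  The occlusion sweep reuses
trained models and therefore omits the max-over-epochs step.  Vote ties
break by summed window probability, then lowest class index (the source
is silent; fixed for determinism).

## Numerical choices and limitations

Float64 throughout (the exactness oracles require it).  Pooling argmax
ties take the first index.  The probability floor (1e−12) only matters
for adversarially collapsed outputs.  The bold-driver schedule remains
fragile on long plateaus — runs that fail to leave the uniform-output
regime can see the learning rate decay geometrically; the post-epoch
monitor mitigates but does not remove this.  Strided or padded
convolutions, average pooling, minibatching, momentum and data
augmentation beyond occlusion/concatenation are out of scope.  Training
the full-width stack on real-scale datasets (90 sequences × 50 epochs ×
9 folds × 5 seeds) is supported by the code but takes hours on one CPU;
the packaged experiments are sized to minutes.
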