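# mstnn

A multiple spatio-temporal scales neural network: a recurrent-convolutional
model for classifying dynamic visual image sequences, built for studying how
a hierarchy of neural timescales supports action recognition, robustness to
dynamic occlusion, and contextual recognition of action sequences.

## The model

The network is a convolutional stack whose units are **leaky integrators**.
The internal state of the *m*-th feature map in convolutional layer *l* at
time step *t* follows

    u_t^{lm} = (1 - 1/τ_l) u_{t-1}^{lm} + (1/τ_l) ( Σ_n k^{lmn} * v_t^{(l-1)n} + b^{lm} )
    v_t^{lm} = 1.7159 · tanh( (2/3) u_t^{lm} )

where `*` is a stride-1 valid cross-correlation, and τ_l is the layer's
**time constant**: the fast bottom layer (τ = 2) tracks individual frames,
the middle layer (τ = 5) integrates over movement cycles, and the slow top
layer (τ = 100) accumulates evidence across a whole episode.  Max-pooling
layers between convolutions provide spatial invariance; a static softmax
head reads the top layer at every step.  The reference stack for
48×54 silhouette frames is

    1×48×54 → conv 6×40×40 (9×15, τ=2) → pool 2 → conv 50×14×14 (7×7, τ=5)
            → pool 2 → conv 100×1×1 (7×7, τ=100) → softmax over C classes

Training uses the **delay-response method**: *d* = 15 black frames are
appended to every sequence and the Kullback–Leibler loss against the one-hot
target is applied only during those final *d* steps,

    E = Σ_t E_t,   E_t = Σ_c y*_c ln(y*_c / y_tc)  on the last d steps, 0 otherwise,

so the network must carry everything it knows about the vanished stimulus in
its internal states.  Classification is by majority vote over the per-step
argmax during the black frames.  Gradients are exact backpropagation through
time, normalized by the sequence length, with per-sequence SGD
(weight decay 5·10⁻⁴ on weights, none on biases) and a bold-driver learning
rate (×1.05 when the post-epoch error fell, ÷2 otherwise).

Because supervision happens only while the input is black, a memoryless
network (all τ = 1) is structurally blind at decision time — temporal memory
is not an optimization but the mechanism.

## A worked example

`examples/03_train_and_classify.py` trains a reduced-width stack on two
synthetic silhouette actions (vertical bounce vs two-hand wave, six
subjects) and classifies a held-out subject:

```
 epoch   mean_kl  learning_rate  train_accuracy
     0 10.397739       0.100000             0.5
     1 10.356499       0.100000             0.5
     2 10.314073       0.105000             0.6
     3 10.263909       0.110250             0.6
     4 10.203549       0.115763             0.8
     5 10.127395       0.121551             1.0
     6 10.011822       0.127628             1.0
     7  9.836096       0.134010             1.0
held-out s05_t0_bounce: true=0 predicted=0 votes=[0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
held-out s05_t0_two_arm_wave: true=1 predicted=1 votes=[1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
held-out accuracy: 1.00
```

`mean_kl` is the delay-window KL loss per sequence (15·ln 2 ≈ 10.4 at
chance); the votes are the 15 black-frame argmax decisions that the
majority vote aggregates.  The other examples cover the forward dynamics
(`01`), the synthetic generator (`02`), occlusion robustness (`04`) and the
slow layer's contextual memory on concatenated actions (`05`).

A thin CLI wraps the same operations:

```
mstnn synth --out data --subjects 9 --length 40
mstnn train --manifest data/manifest.csv --out run --epochs 20
mstnn evaluate --checkpoint run/checkpoint.npz --manifest data/manifest.csv
mstnn occlude  --checkpoint run/checkpoint.npz --manifest data/manifest.csv
```

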