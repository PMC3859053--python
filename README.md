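# arhar — AR-coefficient activity recognition from smartphone accelerometers

`arhar` recognizes six everyday activities — standing, walking,
walking-upstairs, walking-downstairs, running, hopping — from triaxial
smartphone accelerometer signals sampled at a low rate (20 Hz) with a short
decision window (3 s). It is written for researchers in wearable sensing
and biomedical time-series analysis who want a fully reproducible,
desk-scale implementation of the classic autoregressive-feature pipeline,
including a synthetic-signal generator that emulates the statistical
structure of real multi-subject, multi-pocket recordings, so every stage
can be exercised and tested without any data collection.

## The method

Activity acceleration signals show strong positive autocorrelation — a lag
plot of consecutive samples clusters along the diagonal — which identifies
them as realizations of an autoregressive (AR) process

> x[n] = Σᵢ₌₁..M aᵢ · x[n−i] + ε[n].

The pipeline is:

1. **Preprocessing** — gravity is isolated per axis by an exponential
   low-pass filter g[n] = α·g[n−1] + (1−α)·a[n] (α = 0.8) and subtracted;
   a causal order-3 moving average suppresses outliers; the signal is cut
   into 3 s windows (60 samples per axis at 20 Hz).
2. **Feature extraction** — each axis of a window is fitted with an AR
   model by Burg's maximum-entropy method (always stable). The model order
   M = 10 is selected by minimizing the Akaike information criterion
   AIC = −2L_m + 2m averaged over the three axes; the window length by the
   flattening of the signal-to-noise ratio
   SNR = 10·log₁₀(Σν² / Σ(ν−ν̄)²) of the model's one-step predictions.
   Model adequacy is checked by whiteness of held-out residuals. The
   feature vector is the 30-dimensional concatenation
   [a_x1..a_x10, a_y1..a_y10, a_z1..a_z10].
3. **Kernel discriminant analysis (KDA)** — the same activity looks very
   different depending on which pocket holds the phone, inflating
   within-class variance. With RBF kernel matrix K and class-indicator
   matrix W (W_ij = 1/m_k for same-class pairs), the discriminant
   coefficients solve KWKα = λ(KK + εI)α on the double-centered kernel;
   the top C−1 = 5 eigenvectors give a projection that suppresses
   position-induced variance.
4. **Classification** — a small feed-forward network (5 inputs, one hidden
   layer of 3 logistic units, 6 softmax outputs) trained by mini-batch
   backpropagation with momentum.

Evaluation is **subject-independent**: the people in the evaluation corpus
never appear in training. Confusion matrices are row-normalized; the
reported mean accuracy is the unweighted mean of per-class recall.

## Worked example

Generate a synthetic study (5 training subjects, 3 new evaluation
subjects, 6 activities × 5 pocket positions each), train, and evaluate:

```sh
arhar generate --out demo/train --subjects 5 --seed 0
arhar generate --out demo/eval --subjects 3 --first-subject 5 --seed 0
arhar train demo/train --bundle demo/bundle.json
arhar evaluate demo/eval --bundle demo/bundle.json
```

prints (row-normalized percentages, rows = true activity):

```
Activity            hopping  running  standing  walking  w-downstairs  w-upstairs
hopping                92.0      0.7       0.0      4.7           0.0         2.7
running                 2.0     95.3       0.0      0.7           2.0         0.0
standing                0.0      0.0     100.0      0.0           0.0         0.0
walking                 6.0      5.3       0.0     64.0           0.7        24.0
walking-downstairs      0.0      0.0       1.3      4.0          91.3         3.3
walking-upstairs        0.0      3.3       0.0     16.0           2.7        78.0
Mean                    86.8
```

86.8 % of evaluation windows from never-seen subjects are classified
correctly on (unweighted) average; the residual confusion sits between
walking and walking-upstairs, the two most similar gaits. Repeating the
experiment without the KDA stage (`arhar ablate-kda demo/train demo/eval`)
drops the mean to 75.2 % — a +11.6-point gain from suppressing
position-induced variance:

```
mean-accuracy delta (with - without): +11.6 points
```

Other subcommands: `select-order` (axis-averaged AIC curve), `select-window`
(SNR curve), `classify` (per-window online path), `eda-export`
(autocorrelation and lag-pair tables).

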