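# timbre

Decoding a rat's behavioral state from multichannel theta-band hippocampal
LFPs — with or without a phase carrier.

## The problem

Hippocampal place cells fire at progressively earlier phases of the theta
rhythm as the animal crosses their place fields (phase precession), so the
multichannel local field potential carries a phase–amplitude pattern that
encodes position. The classical way to read this pattern is **carrier-based**:
represent each electrode's theta-band signal as a complex analytic signal
`z_n(t) = |z_n| e^{iφ_n}`, take the first principal component of the complex
matrix as a global carrier θ, and demodulate every channel by subtracting the
carrier's phase. That works while theta is strong — but during immobility
theta weakens, place-cell populations drift in phase *together* relative to
the carrier (shared noise), and any decoder referenced to θ degrades.

This package implements the **carrier-free** alternative, TIMBRE (Tracking
Informative Multivariate Brain Rhythms Efficiently): a three-layer
complex-valued network

```
h(t) = softmax(|W₁ x(t)|),      y(t) = softmax(W₂ h(t) + b),
```

where `x(t)` is the whitened complex LFP, rows of the complex weight matrix
`W₁` are constrained to unit L2 norm, and `W₂` is real. The modulus discards
the oscillatory phase, making the classifier *exactly* invariant to any
time-varying phase rotation applied jointly to all channels — i.e. immune to
shared phase noise. The softmax on the hidden layer makes nodes compete, so
each learns a distinct position-tuned oscillatory pattern (a "pθ"). Training
is cross-entropy with Adam; gradients for the complex weights are
conjugate-Wirtinger derivatives, implemented by hand in numpy and verified
against finite differences.

Around the network, the package provides the full study apparatus:

| module | contents |
| --- | --- |
| `timbre.preprocess` | analytic signal, carrier extraction (complex SVD), demodulation, ridge whitening, theta-power deciles, ripple detection |
| `timbre.simulate` | phase-precessing place-cell populations, private/shared phase noise, mixing into electrode arrays, ridge-template decoding |
| `timbre.network` | the complex-valued network and optimizer |
| `timbre.decoders` | L1 logistic, Bayesian (Poisson) and ridge-RBF spike decoders, multiclass complex CSP, balanced fold assignment |
| `timbre.open_field` | 2-D position+orientation decoding on a 10×10×10 pose RBF grid |
| `timbre.metrics` | position information, θ/pθ selectivity, variance partitioning, the cross-validated correlated t-test |
| `timbre.spike_phase` | nested spike-phase prediction models that detect shared noise |
| `timbre.sessions` | synthetic maze / open-field session generator, HDF5 + flat-binary I/O |

## Worked example

`examples/03_train_timbre.py` generates a synthetic 3-arm maze session
(trajectory, Poisson spikes, and an LFP mixed from 300 phase-precessing place
cells), whitens the complex LFP, and trains the network to classify the
occupied arm:

```
session: 4500 samples, 64 electrodes, 300 cells
trained for 100 epochs; held-out arm accuracy = 100.0% (chance 33.3%)
hidden node 0: mean activation per arm = [0.187 0.226 0.657] -> prefers arm 2
hidden node 1: mean activation per arm = [0.63  0.225 0.173] -> prefers arm 0
hidden node 2: mean activation per arm = [0.183 0.549 0.17 ] -> prefers arm 1
```

Although trained only on arm labels, the three hidden nodes form a bijection
with the arms — each node's pθ is most active in exactly one arm. With 12
hidden nodes the peaks subdivide each arm (feature learning).

`examples/02_noise_dissociation.py` shows why the carrier-free readout
matters. Decoding 25 position bins from simulated LFPs (3 sessions, mean
accuracy; chance 0.04):

```
n_electrodes             8      32     128
noise   mode
none    carrier_based  0.942  0.987  0.997
        carrier_free   0.840  0.959  0.990
private carrier_based  0.458  0.622  0.675
        carrier_free   0.271  0.379  0.454
shared  carrier_based  0.284  0.303  0.327
        carrier_free   0.840  0.959  0.990
```

Private noise (independent per cell) hurts both strategies and the
carrier-based readout stays ahead; shared noise (common to all cells)
destroys carrier-based decoding while leaving the carrier-free numbers
*identical to the noiseless ones* — a common phase factor cancels inside the
modulus. The other examples cover preprocessing, spike-phase prediction,
open-field pose decoding, and the statistics layer.

A thin CLI mirrors the main workflows and is byte-deterministic in its
`--seed`:

```bash
timbre simulate session --kind maze --seed 7 --out sess.h5
timbre train --session sess.h5 --hidden 3 --out model.h5
timbre simulate noise-comparison --noise all --out noise_comparison.csv
```

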