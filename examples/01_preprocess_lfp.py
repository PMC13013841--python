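"""Preprocess a raw multichannel LFP into its analytic-signal representation.

Builds a 20 s, 8-channel synthetic recording at 1250 Hz whose channels share
an 8 Hz rhythm with channel-specific phase offsets, then runs the standard
chain: decimation to 25 Hz, 2 Hz high-pass, Hilbert transform.  Prints the
carrier's explained variance and the per-channel phase offsets recovered by
demodulation — with a common rhythm the carrier explains nearly everything
and the offsets match construction.
"""

import numpy as np

from timbre import preprocess as pp

fs, duration = 1250.0, 20.0
t = np.arange(int(fs * duration)) / fs
offsets = np.linspace(0, np.pi / 2, 8)
raw = pp.RawLFP(np.cos(2 * np.pi * 8 * t[:, None] + offsets[None, :]), fs)

lfp = pp.preprocess_lfp(raw, fs_out=25.0)
carrier = pp.extract_carrier(lfp)
demod = pp.demodulate(lfp, carrier)
keep = ~pp.edge_mask(lfp.n_samples, lfp.fs)

print(f"analytic signal: {lfp.z.shape[0]} samples x {lfp.z.shape[1]} channels")
print(f"carrier explains {100 * carrier.explained_variance_fraction:.1f}% "
      "of the variance (a single shared rhythm -> ~100%)")
recovered = np.angle(demod[keep]).mean(axis=0)
print("recovered channel phase offsets (rad):",
      np.round(recovered - recovered[0], 3))
print("constructed offsets             (rad):", np.round(offsets, 3))
# demodulation measures phase *relative* to the carrier, so only the
# differences between channels are meaningful; they match construction.
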