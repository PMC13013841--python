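"""Position and orientation decoding in the open field.

Generates a foraging session whose cells precess along the direction of
motion (making the LFP phase pattern orientation-dependent) with shared phase
noise, encodes pose on a 10 x 10 x 10 radial-basis grid, and trains
carrier-free and carrier-based decoders with a KL objective.  Position error
is in normalized arena units (x 152.4 for cm); orientation error in radians.
"""

import numpy as np

from timbre import open_field as of
from timbre import preprocess, sessions
from timbre.network import TrainConfig
from timbre.simulate import NoiseSpec

cfg = sessions.OpenFieldConfig(duration_s=240.0, n_cells=200, n_electrodes=32,
                               noise=NoiseSpec("shared", 1.0, 8.0))
sess = sessions.generate_session("open_field", cfg, seed=3)
beh = sess.behavior
basis = of.PoseRBF()
targets = of.rbf_encode_pose(beh.x, beh.y, beh.orientation, basis)

T = len(beh)
test = np.zeros(T, bool)
test[int(0.8 * T):] = True
truth = (beh.x[test].to_numpy(), beh.y[test].to_numpy(),
         beh.orientation[test].to_numpy())

inputs = {
    "carrier_free": preprocess.whiten(sess.z).v,
}
carrier = preprocess.extract_carrier(preprocess.AnalyticLFP(sess.z, sess.fs))
xd = preprocess.split_complex(preprocess.demodulate(sess.z, carrier))
inputs["carrier_based"] = (xd - xd.mean(0)) / xd.std(0)

chance = of.chance_baselines(np.c_[beh.x, beh.y], n_draws=100000)
print(f"chance position error: {chance:.3f} ({chance * of.ARENA_CM:.0f} cm)")
for mode, x in inputs.items():
    model, _ = of.train_pose_decoder(x[~test], targets[~test], mode,
                                     cfg=TrainConfig(seed=0, max_epochs=30,
                                                     batch_size=256))
    est = of.decode_pose(model.predict_proba(x[test]), basis,
                         sigma_phi_smooth=0.2, tau_s=1.6, fs=sess.fs,
                         true_pose=truth)
    print(f"{mode:14s}: position error {est.position_error.mean():.3f} "
          f"({est.position_error.mean() * of.ARENA_CM:.0f} cm), "
          f"orientation error {est.orientation_error.mean():.2f} rad")
# under shared noise the carrier-free decoder localizes the animal far
# better than the carrier-based one; both beat chance
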