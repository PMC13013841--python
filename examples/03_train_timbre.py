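"""Train the carrier-free network on a synthetic 3-arm maze session.

Generates a noiseless session (trajectory, spikes, LFP), whitens the complex
LFP, and trains the shallow complex-valued network to classify which maze arm
the animal occupies.  With 3 hidden nodes each node comes to represent one
arm; the held-out accuracy shows the LFP fully encodes arm identity.
"""

import numpy as np

from timbre import network, preprocess, sessions

sess = sessions.generate_session("maze", seed=1)
x = preprocess.whiten(sess.z).v
beh = sess.behavior
arms = beh["arm"].to_numpy()
trials = beh["trial"].to_numpy()

uniq = np.unique(trials)
val = np.isin(trials, uniq[1::5])
test = np.isin(trials, uniq[2::5])
train_mask = ~(val | test)

model = network.ComplexSoftmaxNet(x.shape[1], n_hidden=3, n_classes=3, seed=0)
model, history = network.train(model, x[train_mask], arms[train_mask],
                               x[val], arms[val],
                               network.TrainConfig(seed=0))
_, _, acc = network.predict_arm(model, x[test], np.arange(3), arms[test])

print(f"session: {sess.z.shape[0]} samples, {sess.z.shape[1]} electrodes, "
      f"{len(sess.spikes)} cells")
print(f"trained for {len(history['val_loss'])} epochs; "
      f"held-out arm accuracy = {100 * acc:.1f}% (chance 33.3%)")

h, _ = model.forward(x)
for j in range(3):
    means = [h[arms == a, j].mean() for a in range(3)]
    print(f"hidden node {j}: mean activation per arm = "
          f"{np.round(means, 3)} -> prefers arm {int(np.argmax(means))}")
# each node's p-theta is most active in exactly one arm (a node-arm bijection)
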