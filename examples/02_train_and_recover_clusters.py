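"""Train the autoencoder-clusterer on synthetic data and check recovery.

The loss combines reconstruction MSE, the information-maximization
entropy terms (maximize H(Y), minimize H(Y|X)) and an affine-consistency
KL penalty. On well-separated 4-class data the soft cluster assignments
should align with the true classes (adjusted Rand index near 1).

Runs in a few minutes on one CPU.
"""

import numpy as np

from stainclust import (
    SynthSpec,
    TrainConfig,
    agreement,
    assign_clusters,
    generate_patch_dataset,
    reduced_config,
    train,
)

seed = 0
patches, truth = generate_patch_dataset(SynthSpec(n_classes=4, n_patches=600, seed=seed))
config = TrainConfig(epochs=300, batch_size=25, learning_rate=5.0, seed=seed, n_clusters=4)
model, history = train(patches.data, config, reduced_config(4, seed=seed))

labels, soft = assign_clusters(model, patches.data)
ari, nmi = agreement(labels, truth)

mi = history.mutual_info
print(f"mutual information: epoch 1 {mi.iloc[0]:.4f} -> final {mi.iloc[-1]:.4f} nats "
      f"(upper bound ln 4 = {np.log(4):.4f})")
print(f"cluster sizes: {np.bincount(labels, minlength=4)}")
print(f"ARI = {ari:.3f}, NMI = {nmi:.3f}")
print("-> ARI 1.0 means the unsupervised clusters coincide with the true classes")
print("   up to relabeling; rising mutual information shows the assignments became")
print("   both confident (low H(Y|X)) and balanced (high H(Y)).")
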