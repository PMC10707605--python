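"""Project upper-latent embeddings to 2-D with UMAP and save a scatter.

Uses a quick, reduced training run; the scatter shows each patch at its
2-D embedding coordinate, colored by assigned cluster.
"""

import numpy as np

from stainclust import (
    SynthSpec,
    TrainConfig,
    assign_clusters,
    embed_2d,
    generate_patch_dataset,
    reduced_config,
    train,
)
from stainclust.viz_and_map import save_scatter

seed = 0
patches, truth = generate_patch_dataset(SynthSpec(n_classes=3, n_patches=240, seed=seed))
model, _ = train(
    patches.data,
    TrainConfig(epochs=120, batch_size=24, learning_rate=5.0, seed=seed, n_clusters=3),
    reduced_config(3, seed=seed),
)
labels, _ = assign_clusters(model, patches.data)
features = model.encode(patches.data)

coords = embed_2d(features, seed=seed)
save_scatter(coords, labels, "embedding_2d.png")

spread = [coords[labels == k].std(axis=0).mean() for k in np.unique(labels)]
print(f"embedded {len(coords)} patches from {features.shape[1]}-D latent space to 2-D")
print(f"mean within-cluster spread in 2-D: {np.mean(spread):.2f}")
print("wrote embedding_2d.png")
print("-> distant groups of points belong to different clusters; the layout is")
print("   for inspection only (UMAP distances are not calibrated).")
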