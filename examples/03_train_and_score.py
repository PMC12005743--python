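"""Train a shallow CNN on high-resolution faces, score phosphene stimuli.

The model never sees a phosphene image during training (it learns on
contrast-normalized high-resolution faces); its accuracy on degraded
stimuli then traces how much identity information each PIQ level retains.
"""

import numpy as np

from phospsych import ModelSpec, TrainConfig, generate_dataset, phosphenize, piq_grid, train_model

ds = generate_dataset(n_classes=4, train_per_class=36, seed=0)
spec = ModelSpec(arch="CNN_SHALLOW", n_classes=4, instance_seed=0)
model, history = train_model(spec, ds, TrainConfig(lr=1e-3, max_epochs=12))
print(f"trained {len(history)} epochs; final validation accuracy "
      f"{100 * history['val_acc'].iloc[-1]:.0f}%")

test = ds.subset("test")
print("\nTop-1 accuracy (%) on square-bitmap phosphenes, chance = 25%:")
print("P \\ G     2     4     8")
for p in (16, 32, 64):
    row = []
    for g in (2, 4, 8):
        piq = [q for q in piq_grid("human") if q.pixels == p and q.grayscales == g][0]
        stim = np.stack([phosphenize(im, piq, "ngb") for im in test.images])
        row.append(100 * (model.predict_proba(stim).argmax(1) == test.labels).mean())
    print(f"{p:5d} " + " ".join(f"{v:5.1f}" for v in row))
# accuracy should rise toward the bottom-right: more pixels and more gray
# levels each preserve more of the face
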