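"""Extrapolate human accuracy to untested PIQ levels from model accuracy.

Humans were tested on 9 of the 25 PIQ levels.  Fitting human mean accuracy
against model mean accuracy on those 9 levels gives a line that converts
model accuracy at the 16 untested levels into estimated human accuracy.
"""

import numpy as np
import pandas as pd

from phospsych import fit_linear_map, flag_dips, piq_grid, predict_linear

rng = np.random.default_rng(0)
levels = piq_grid("full")
tested = set(piq_grid("human"))

# stand-in accuracy surfaces (a real run supplies measured tables)
def acc(piq):
    z = 1.0 * np.log2(piq.pixels) + 0.5 * np.log2(piq.grayscales) - 7.0
    return 100 * (0.25 + 0.7 / (1 + np.exp(-z)))

model = pd.DataFrame(
    [{"pixels": q.pixels, "grayscales": q.grayscales, "mean": acc(q) + rng.normal(0, 1)}
     for q in levels]
)
human = pd.DataFrame(
    [{"pixels": q.pixels, "grayscales": q.grayscales,
      "mean": 0.9 * acc(q) + 5 + rng.normal(0, 1)}
     for q in levels if q in tested]
)

is_tested = model.apply(lambda r: (r.pixels, r.grayscales) in
                        {(q.pixels, q.grayscales) for q in tested}, axis=1)
lmap = fit_linear_map(model[is_tested], human)
print(f"fit on 9 tested levels: human = {lmap.slope:.2f} x model + {lmap.intercept:.1f}, "
      f"r = {lmap.r:.3f}")

est = predict_linear(lmap, model[~is_tested])
print(f"estimated human accuracy at {len(est)} untested levels, "
      f"range {est['mean'].min():.1f}-{est['mean'].max():.1f}%")

dips = flag_dips(est)
print(f"estimates dipping below both grid neighbors: {len(dips)}")
# a clean (dip-free) surface is the sanity criterion for trusting the
# extrapolation; the slope near 0.9 and r near 1 recover the relation the
# synthetic humans were built with
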