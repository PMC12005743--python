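"""Render one face as phosphene stimuli across image-quality levels.

A PIQ (phosphene image quality) level pairs a lattice resolution P with a
gray depth G.  NGB mode draws square uniform blocks (optogenetic-style
stimulation), GB mode circular Gaussian spots (electrical stimulation).
"""

import numpy as np

from phospsych import PIQLevel, phosphenize, piq_grid, render_face, sample_class_params
from phospsych.faces import Condition

face = render_face(sample_class_params(0, 0), Condition(0, "neutral"))
print(f"high-resolution face: {face.shape}, {len(np.unique(face))} gray values")

for piq in [PIQLevel(16, 2), PIQLevel(32, 4), PIQLevel(64, 8)]:
    ngb = phosphenize(face, piq, "ngb")
    gb = phosphenize(face, piq, "gb")
    print(f"P={piq.pixels:3d} G={piq.grayscales:2d}: "
          f"NGB uses {len(np.unique(ngb))} gray values (<= G), "
          f"GB peak {gb.max()} with Gaussian fall-off per phosphene")

print(f"full model grid: {len(piq_grid('full'))} levels; "
      f"human-protocol subset: {len(piq_grid('human'))} levels")
# lower P and G discard spatial and intensity information — these are the
# stimuli whose recognizability the pipeline quantifies
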