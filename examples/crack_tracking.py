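"""Track radial cracks in a drying drop via a space-time diagram.

Generates a stack of frames showing a bright drop whose dark cracks grow
inward from the rim, detects the drop contact line with Canny + circular
Hough, samples every frame on a concentric circle, and reduces the stack
to a single angle-vs-time image whose dark streaks are the cracks.
"""

import numpy as np

from microimage import crack_spacetime, make_crack_stack

frames, truth = make_crack_stack(n_frames=10, n_cracks=6, seed=1)
diagram = crack_spacetime(frames, annulus_fraction=0.75)

(r0, c0), radius = truth.centers[0], truth.radii[0]
row, col, det_radius = diagram.drop
print(f"true drop: center ({r0:.0f}, {c0:.0f}), radius {radius:.0f}")
print(f"detected:  center ({row}, {col}), radius {det_radius}")

thr = 0.5 * (diagram.matrix.max() + diagram.matrix.min())
dips_per_frame = (diagram.matrix < thr).sum(axis=1)
print(f"dark samples per frame: {dips_per_frame.tolist()}")
# dark samples appear once a crack crosses the sampling circle; the final
# row shows all cracks, the first row none
first_dark_frame = int(np.argmax(dips_per_frame > 0))
print(f"first frame with a crack on the sampling circle: {first_dark_frame}")
print(f"diagram shape (frames x angular samples): {diagram.matrix.shape}")
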