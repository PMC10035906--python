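"""Build one link under each named shape preset and report its geometry.

The link joins nodes at (0,0,0) and (2,0,0) with the reference point
below the chord at (1,-1,0), so d_ij = 2 and the curve bows upward.
"""

import numpy as np

from spatnetviz import PRESETS, ShapeParams, link_path

S_i, S_j, C = np.zeros(3), np.array([2.0, 0, 0]), np.array([1.0, -1, 0])

print(f"{'preset':<10} {'a1':>4} {'a2':>4} {'a3':>4} {'a4':>4}"
      f" {'height h':>9} {'max rise':>9} {'arc len':>8}")
for name in PRESETS:
    curve = link_path(S_i, S_j, C, ShapeParams.preset(name))
    rise = curve.polyline[:, 1].max()
    arc = np.sum(np.linalg.norm(np.diff(curve.polyline, axis=0), axis=1))
    a = PRESETS[name]
    print(f"{name:<10} {a[0]:>4} {a[1]:>4} {a[2]:>4} {a[3]:>4}"
          f" {curve.h:>9.3f} {rise:>9.3f} {arc:>8.3f}")

# height h = a1 * d_ij is the summit's distance above the chord midpoint;
# "max rise" is the highest sampled point (equals h at the summit for most
# presets); "arc len" shows how much longer the curved path is than the
# d_ij = 2 chord (exactly 2 for Straight).
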