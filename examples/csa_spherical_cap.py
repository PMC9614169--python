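"""Contact surface area estimators vs the spherical-cap closed form.

A sphere of radius r embedded to depth h in a half-space "kidney" has
contact area 2*pi*r*h.  The mesh (area-element) estimator converges to the
closed form; the voxel-face estimator is a staircase upper bound.
"""

import numpy as np

from tkp.planning import compute_csa
from tkp.volume import LabelVolume

spacing = 0.5  # mm
for r, h in [(15.0, 15.0), (15.0, 5.0), (10.0, 10.0)]:
    n = int((2 * r + 10) / spacing)
    x = np.arange(n) * spacing
    c = (n - 1) * spacing / 2.0
    kidney = np.zeros((n, n, n), int)
    kidney[x >= c + (r - h)] = 1  # embedded cap of depth h
    gx, gy, gz = np.meshgrid(x, x, x, indexing="ij", sparse=True)
    tumor = ((gx - c) ** 2 + (gy - c) ** 2 + (gz - c) ** 2 <= r * r).astype(int)
    kv = LabelVolume(kidney, (spacing,) * 3)
    tv = LabelVolume(tumor, (spacing,) * 3)
    mesh = compute_csa(kv, tv, method="mesh")
    faces = compute_csa(kv, tv, method="voxel_face")
    expect = 2 * np.pi * (r / 10) * (h / 10)
    print(f"r={r:4.0f} mm h={h:4.0f} mm  closed form {expect:6.2f} cm^2  "
          f"mesh {mesh:6.2f} ({(mesh-expect)/expect:+.1%})  "
          f"voxel-face {faces:6.2f} (upper bound)")
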