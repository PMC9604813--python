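"""Projection-matrix algebra: compose, crop-adjust, project.

Builds a calibrated radiograph geometry (P = K R [I | -t]), projects a
world point, then crops the image to a bounding box and shows that the
adjusted matrix P_hat = Q P shifts pixels by exactly the crop corner.
"""

import numpy as np

from spinerecon.geometry import (
    CropOffset,
    Extrinsics,
    Intrinsics,
    adjust_for_crop,
    compose_projection,
    project_point,
)

K = Intrinsics(focal_length=900.0, principal_point=(112, 112), image_size=(224, 224))
E = Extrinsics(rotation=np.eye(3), camera_center=np.array([0.0, 0.0, -630.0]))
P = compose_projection(K, E)

X = np.array([20.0, -10.0, 0.0])  # a world point 630 mm in front of the source
pix, in_front = project_point(P, X)
print(f"world point {X} -> pixel ({pix[0]:.2f}, {pix[1]:.2f}), in front: {in_front}")

crop = CropOffset(tx=100, ty=80)  # top-left corner of a vertebra bounding box
P_hat = adjust_for_crop(P, crop)
pix_c, _ = project_point(P_hat, X)
print(f"after cropping at (100, 80)   -> pixel ({pix_c[0]:.2f}, {pix_c[1]:.2f})")
print("shift equals the crop corner:",
      np.allclose(pix - pix_c, (crop.tx, crop.ty)))
# The pixel moves by exactly (tx, ty): the network can keep using exact
# projective geometry on cropped inputs.
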