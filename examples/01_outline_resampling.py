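"""Project a crown outline onto the cervical plane and resample it.

A digitized cervical outline is a closed 3D contour. The analysis frame
flattens it onto the cervical plane and replaces it by 24 pseudo-landmarks
at equiangular rays from the centroid of the outline area, so outlines of
different teeth become point-to-point comparable.
"""

import numpy as np

from dentomorph.outline import (
    area_centroid,
    project_to_cervical_plane,
    resample_equiangular,
)

# a slightly wavy, tilted crown contour (60 vertices in 3D)
theta = 2 * np.pi * np.arange(60) / 60
r = 4.5 + 0.5 * np.cos(2 * theta) + 0.2 * np.sin(3 * theta)
contour = np.column_stack([r * np.cos(theta), r * np.sin(theta), 0.15 * np.sin(theta)])

outline = project_to_cervical_plane(
    contour, plane_point=np.zeros(3), plane_normal=np.array([0.0, 0.0, 1.0])
)
centroid = area_centroid(outline)
pseudo = resample_equiangular(outline, k=24)

print(f"outline vertices:       {len(outline.vertices)}")
print(f"area centroid:          ({centroid[0]:.3f}, {centroid[1]:.3f}) mm")
print(f"pseudo-landmarks:       {len(pseudo)}")
radii = np.linalg.norm(pseudo - centroid, axis=1)
print(f"radial distances (mm):  min {radii.min():.3f}  max {radii.max():.3f}")
# The 24 radii encode the outline's shape; equal radii would mean a circle.
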