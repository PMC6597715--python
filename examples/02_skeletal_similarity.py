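"""Compute skeletal distances: sampling, respacing, alignment, the RDM.

Shows the full metric pipeline on four objects, then the increment series:
sliding one segment along the central segment in 10% steps produces
monotonically growing skeletal distance to the unmoved reference — the
geometry that makes graded dissimilarity experiments possible.
"""

import numpy as np

from skelsim import (
    build_exp2_bases,
    build_skeleton,
    make_increment_series,
    sample_points,
    respace,
    skeletal_distance,
    skeletal_rdm,
    skeleton_point_cloud,
)

sks = [build_skeleton(s, id=f"obj{s}") for s in (1, 2, 3, 4)]
pc = sample_points(sks[0])
rc = respace(pc)
print(f"sampled {len(pc)} points (999 per segment), respaced to {len(rc)} "
      f"points at {rc.spacing} rescaled units")

rdm = skeletal_rdm(sks)
print("pairwise skeletal distances (rescaled units = vu x 1000):")
print(np.array2string(rdm.values, precision=1))

base = build_exp2_bases(0)[0]
series = make_increment_series(base, [0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
ref = skeleton_point_cloud(series[0])
dists = [skeletal_distance(ref, skeleton_point_cloud(s)) for s in series]
print("distance to the 0% reference per increment:")
for f, d in zip((0, 10, 20, 30, 40, 50), dists):
    print(f"  {f:2d}%: {d:7.3f}")

# Distances grow strictly with the increment: each 10% relocation of the
# movable segment adds skeletal dissimilarity while the coarse arrangement
# of parts is unchanged.
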