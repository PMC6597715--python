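"""Increment-series experiment: graded skeletal change, mixed-effects test.

Morphs three reference objects in 10% skeletal increments, simulates
same/different judgments whose accuracy falls with skeletal distance, and
fits the crossed random-intercept model (subject, object) with a
likelihood-ratio test of the skeletal predictor.
"""

from skelsim import (
    Exp2Config,
    build_exp2_bases,
    build_roster_exp2,
    make_increment_series,
    simulate_exp2,
    skeletal_distance,
    skeleton_point_cloud,
)
from skelsim.analysis import exp2_mixed_model

bases = build_exp2_bases(seed=3)
objects = [s for b in bases for s in make_increment_series(b, [0, .1, .2, .3, .4, .5])]
print(f"{len(objects)} objects: 3 spatial-relation sets x 6 increments")

clouds = {o.id: skeleton_point_cloud(o) for o in objects}
pair_d = {}
for o in objects:
    ref = o.id.split("_")[0] + "_inc00"
    pair_d[(ref, o.id)] = skeletal_distance(clouds[ref], clouds[o.id])

roster = build_roster_exp2(seed=3)
cfg = Exp2Config(seed=3)
jt = simulate_exp2(cfg, pair_d, roster)
same = jt[jt["trial_type"] == "same"]
print("mean accuracy by skeletal increment:")
for inc, acc in same.groupby("increment")["correct"].mean().items():
    print(f"  {int(inc * 100):2d}%: {acc:.3f}")

agg = (
    same.groupby(["participant_id", "object_b"])
    .agg(response=("correct", "mean"), skeletal=("skel_distance", "first"))
    .reset_index()
    .rename(columns={"participant_id": "subject", "object_b": "object"})
)
res = exp2_mixed_model(agg, ["skeletal"])
print(f"skeletal effect: beta = {res.coefficients['skeletal']:+.3f}, "
      f"LRT chi2(1) = {res.lrt_chi2['skeletal']:.2f}, p = {res.lrt_p['skeletal']:.2g}")

# Accuracy declines monotonically across increments while staying above
# chance, and the mixed model attributes the decline to the skeletal
# predictor (negative beta, significant LRT).
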