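"""Re-associate two matching fragments: coarse landmark fit + trimmed ICP.

Four corresponding landmark clicks give a coarse alignment; trimmed ICP on
the two fracture surfaces refines it; the refined transform is applied to
the whole moving fragment and the clouds are merged.
"""
import numpy as np
import vrakit as vk
from vrakit.synthetic import build_match_plan

bone = vk.make_long_bone(seed=5)
fragments, truth = vk.fracture(bone, n_fragments=2, seed=5)
surfaces = {f: vk.segment_fracture(vk.roughness(c)) for f, c in fragments.items()}
plan = build_match_plan(fragments, truth, seed=5)  # the synthetic "operator"
step = plan.steps[0]

merged, icp = vk.reassociate_pair(
    fragments[step.ref_id], fragments[step.mov_id],
    surfaces[step.ref_id], surfaces[step.mov_id],
    step.ref_points, step.mov_points,
)
true_rel = truth.poses[step.ref_id].compose(truth.poses[step.mov_id].inverse())
err = icp.transform.compose(true_rel.inverse())
angle = np.degrees(np.arccos(np.clip((np.trace(err.rotation) - 1) / 2, -1, 1)))
print(f"ICP: rms={icp.final_rms:.3f} mm after {icp.iterations} iterations")
print(f"pose error vs ground truth: {angle:.3f} degrees")
print(f"merged cloud: {len(merged)} points "
      f"(= {len(fragments[step.ref_id])} + {len(fragments[step.mov_id])}, no deduplication)")
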