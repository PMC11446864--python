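# vrakit — virtual re-association of fragmented skeletal remains

After an explosion, an air crash or any mass-fatality event, disaster
victim identification (DVI) teams face hundreds to thousands of bone
fragments.  Physically gluing fragments back together is a recognised
anthropological method but requires days of cleaning and drying, and
sampling every fragment for DNA is expensive.  **Virtual re-association
(VRA)** rejoins fragments digitally from routine CT scans instead: each
fragment is segmented from the CT volume, converted to a point cloud, its
broken (fracture) faces are isolated by a roughness analysis, and
matching fragments are registered face-to-face and merged into a
whole-bone reconstruction whose accuracy can be measured against an
intact reference.

`vrakit` implements that protocol end to end as a Python library with a
thin command-line layer, plus a fully ground-truthed synthetic specimen
generator for validation (no imaging data is publicly deposited for the
original laboratory comparison).

## The method

For fragment clouds *P* (reference) and *Q* (moving), with fracture
surfaces extracted by thresholding the roughness scalar

&nbsp;&nbsp;&nbsp;&nbsp;ρ(p) = | (p − c̄) · n̂ |,&nbsp; the distance from
*p* to the least-squares plane of its neighbours within a kernel radius
(threshold ρ ≥ 1.0 mm),

re-association is two-stage:

1. **Coarse:** ≥ 3 operator-clicked landmark pairs give the closed-form
   least-squares rigid fit (SVD of the cross-covariance, Kabsch) of
   argmin<sub>R,t</sub> Σᵢ‖R qᵢ + t − pᵢ‖².
2. **Refine:** trimmed ICP on the fracture surfaces only — iterate
   nearest-neighbour correspondence, drop pairs beyond a distance gate,
   keep the best fraction by distance ("the most distant points
   excluded"), and re-solve the rigid fit (a point-to-plane variant is
   available and used for final polishing).

The refined transform is applied to the whole moving fragment, the clouds
are merged, and the merged model becomes the reference for the next
fragment.  Reconstructions are scored by registering them onto the intact
cloud and computing per-point cloud-to-cloud distances (mean μ and RMS),
plus coverage — the fraction of the intact surface within a tolerance of
the reconstruction (> 95 % counts as a full reconstruction).

## Worked example

Two matching synthetic fragments, landmark coarse alignment and trimmed
ICP (`examples/03_pair_reassociation.py`):

```
ICP: rms=0.567 mm after 13 iterations
pose error vs ground truth: 0.168 degrees
merged cloud: 33617 points (= 15241 + 18376, no deduplication)
```

The trimmed RMS settles near the face-sampling scale, the recovered pose
is within a fifth of a degree of the generator's ground truth, and the
merged cloud is the exact concatenation of the two fragments.  The full
config-driven pipeline (`examples/06_full_pipeline.py`) prints, per bone:

```
bone00: 7/7 steps merged, mean distance 0.228 mm, coverage 1.000, full reconstruction: True
bone01: 5/5 steps merged, mean distance 0.168 mm, coverage 1.000, full reconstruction: True
```

i.e. every fragment was re-associated and the reconstructed exterior
surface lies ~0.2 mm from the intact bone — comparable to the ~1 mm
accuracy reported for physically glued femurs at CT resolution.

The other examples cover the synthetic generator (`01`), roughness
segmentation (`02`), CT voxelization/region growing/surface extraction
with the ≥ 2 cm triage rule (`04`), and the published six-femur benchmark
statistics (`05`).  The same operations are available from the shell via
the `vra` command (`vra simulate | segment | subsample | roughness |
match | reassemble | evaluate | stats | run`).

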