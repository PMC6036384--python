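# fidseg

Automatic localization of a passive four-marker MRI fiducial device in 3D
MR volumes, with a synthetic MR acquisition simulator for validating the
detector across clinical abdominal pulse-sequence geometries.

## The problem

MR–ultrasound image fusion for abdominal interventions needs a reliable
link between the MR image frame and the patient. A passive fiducial
device — four cylindrical copper-sulfate reservoirs (12.7 mm inner
diameter and depth), three arranged as a scalene triangle with sides
50.7, 69.2 and 88.9 mm and a fourth 12.7 mm above the base centroid —
provides that link, but only if it can be segmented automatically in
whatever volume the clinical protocol produced: in-plane resolutions of
0.7–1.9 mm, slice thicknesses of 1.7–10 mm, slice gaps of 0–2 mm, and
axial, coronal or oblique scan planes. `fidseg` implements the device
model, the detection algorithm, the pose extraction, and a simulator that
reproduces those acquisition geometries so the detector can be validated
end to end without scanner data.

## The detector

Given an integer-intensity volume *V* with voxel-to-world affine (LPS,
mm) and the device template with marker volume
*V*<sub>marker</sub> = π·(d/2)²·depth ≈ 1608.8 mm³:

1. **Noise threshold** *N*<sub>T</sub> — the first zero-crossing of the
   forward-difference derivative of the intensity histogram (bin width 1)
   after the background peak; voxels below *N*<sub>T</sub> are zeroed.
2. **Reference signal threshold** *R*<sub>T</sub> — the mean intensity of
   26-connected sets whose physical volume lies strictly inside
   (½, 3)·*V*<sub>marker</sub>, i.e. of marker-sized objects.
3. **Iterative size/signal discrimination** — thresholds
   *ST*<sub>n</sub> = (n/4)·*R*<sub>T</sub> for n = 7…2; at each level,
   26-connected sets strictly inside (0.35, 1.3)·*V*<sub>marker</sub> are
   merged into a composite candidate image unless the merge would grow an
   object past 1.3·*V*<sub>marker</sub>.
4. **Shape discrimination** — candidates longer than 26.9 mm
   (1.5 × the marker's space diagonal) along any logical axis are removed.
5. **Inter-marker distance discrimination** — search for four candidates
   whose intensity-weighted centers of mass reproduce the six template
   separations within ±τ, with τ growing from 1 mm in 1 mm steps.

The pose is the unweighted mean of the four marker COMs plus the unit
normal of the base triangle, n̂ = unit((B−A)×(C−A)) sign-corrected toward
the apex, reported as spherical angles θ = arccos(n̂<sub>z</sub>),
φ = atan2(n̂<sub>y</sub>, n̂<sub>x</sub>) in the LPS frame. A labeled
rigid (Kabsch) fit to the template is attached for downstream coordinate
hand-off.

## Worked example

```python
import numpy as np
from fidseg import (build_template, template_distances, ScenePose,
                    preset_spec, rasterize_scene, segment_fiducial)

t = build_template()
print(np.round(template_distances(t), 1))
# [88.9 69.2 51.9 50.7 44.2 30.3]      <- the six pairwise separations, mm

scene = ScenePose.default(seed=7, v_marker=t.v_marker)   # body + confuser blobs
spec = preset_spec("lava", seed=7)                       # 0.7 x 0.7 x 1.7 mm
vol = rasterize_scene(t, scene, spec)
print(vol.shape, vol.spacing)
# (229, 157, 106) [0.7 0.7 1.7]

det = segment_fiducial(vol, t)
print(det.match_tolerance, np.round(det.device_com, 2),
      round(det.theta, 2), round(det.phi, 2))
# 1.0 [ 0.   -3.13  0.02] 90.0 -90.0
print(np.round(det.separations() - t.separations, 3))
# [ 0.002 -0.009  0.014 -0.12  -0.024 -0.058]
```

The device was matched at the tightest tolerance (τ = 1 mm). Its center
of mass lands within 0.05 mm of the true scene value (the base centroid
sits at the origin and the apex pulls the 4-marker mean 3.17 mm anterior),
the orientation is the flat-coronal (90°, −90°) the scene prescribes, and
the six measured inter-marker spacings are within 0.12 mm of truth on
this thin-slice geometry.

A `fidseg` command-line tool wraps the same pipeline
(`fidseg simulate|suite|segment|compare|evaluate`); volumes are NIfTI,
detections JSON, reports JSON/CSV, configuration YAML.

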