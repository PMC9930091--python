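"""ROI system on a brain-slice phantom: rim exclusion and mirroring.

Generates an in vivo-like phantom (ellipsoidal gel deposit in tissue, with
a short-T1 rim and a long-T1 peri-gel shell), fits the T1 map at the first
scan, segments the gel, and builds the analysis ROI system: rim-excluded
gel core, adjacent-tissue ring 10 voxels out, and contralateral mirrors.
"""

import numpy as np

from gelmri import (
    brain_spec,
    build_roi_set,
    correct_t1,
    fit_look_locker,
    generate_brain_phantom,
    region_grow,
    volume_from_mask,
)

spec = brain_spec("LC", seed=4, gel_center_offset_vox=(8, 0, 0),
                  rim_thickness_vox=1, peri_thickness_vox=2,
                  rim_t1_s=1.2, peri_t1_s=2.2)
series_list, truth = generate_brain_phantom(spec)
rmap = correct_t1(fit_look_locker(series_list[0]))

gm = truth.gel_masks[0]
seed = tuple(int(round(x)) for x in np.array(np.nonzero(gm)).mean(axis=1))
gel = region_grow(rmap.t1_s, seed, tolerance=0.15)
roi = build_roi_set(gel, rim_depth=2, tissue_offset=10, ring_width=2,
                    mirror_axis=0, planar_axis=2)

print(f"gel volume: {volume_from_mask(gel, spec.voxel_size_mm):.2f} uL "
      f"(truth {volume_from_mask(gm, spec.voxel_size_mm):.2f} uL)")
for name, mask in [("gel", roi.gel), ("core (rim-excluded)", roi.core),
                   ("rim band", roi.rim), ("adjacent tissue", roi.adjacent),
                   ("core mirror", roi.core_mirror),
                   ("adjacent mirror", roi.adjacent_mirror)]:
    t1 = rmap.t1_s[mask & rmap.mask]
    mean_t1 = f"{t1.mean():.3f} s" if t1.size else "n/a"
    print(f"{name:22s} {int(mask.sum()):5d} voxels  mean T1 {mean_t1}")

print("\nThe core excludes the 2-voxel band along the gel rim (partial-volume")
print("protection); mirrored ROIs give contrast-free contralateral references.")
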