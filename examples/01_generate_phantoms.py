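"""Generate a two-class phantom cohort and inspect its composition.

Each volume contains one ellipsoidal tumor: class 1 (HGG-like) has a core
that is bright in the contrast channel (ET-like) with a relatively wide
edema-like rim; class 0 (LGG-like) has a dark core (NET-like) with a
narrow rim. Whole-tumor sizes overlap between classes, so composition —
not size — separates them.
"""

import numpy as np

from vqradiomics import PhantomSpec, generate_phantoms

spec = PhantomSpec(n_volumes_per_class=5, seed=0)
volumes = generate_phantoms(spec)

print(f"{len(volumes)} volumes, image shape {volumes[0].image.shape} (C,W,H,I)")
for v in volumes:
    counts = np.bincount(v.labels.ravel(), minlength=4)
    print(f"{v.volume_id}  grade={'HGG' if v.grade else 'LGG'}  "
          f"NET={counts[1]:5d}  ED={counts[2]:5d}  ET={counts[3]:5d}")
# NET voxels appear only in LGG-like volumes and ET voxels only in
# HGG-like ones; ED (rim) volumes are comparable across classes.
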