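"""Inject the four contouring-error categories into a phantom contour.

Each category mimics a clinical failure mode: boundary (over/under
delineation), volume (convex blob added/removed or slices truncated),
non-adjacent slice (a disconnected 'ditzel' misclick), and position
(gross displacement or a label swap).  Prints how each error moves the
contour's volume, centroid and part count.
"""

import numpy as np

from oarqa import ErrorSpec, PhantomConfig, generate_structure_set, inject_error
from oarqa.features import count_parts

sset = generate_structure_set(PhantomConfig(), seed=3, set_id="demo")
contour = sset["parotid_l"]

print(f"{'error':<28}{'dVol %':>8}{'shift mm':>10}{'parts':>7}")
for category, severity in [("boundary", "moderate"), ("boundary", "major"),
                           ("volume", "moderate"), ("volume", "major"),
                           ("nonadjacent_slice", "moderate"),
                           ("position", "moderate"), ("position", "major")]:
    bad = inject_error(contour, sset.image,
                       ErrorSpec(category, severity, seed=11))
    dvol = 100.0 * (bad.volume_cc() - contour.volume_cc()) / contour.volume_cc()
    shift = np.linalg.norm(bad.centroid_mm() - contour.centroid_mm())
    print(f"{category + '/' + severity:<28}{dvol:>8.1f}{shift:>10.1f}"
          f"{count_parts(bad):>7}")
# ditzels add a part without moving the centroid much; position errors move
# the centroid by tens of mm; boundary/volume errors mostly change volume.
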