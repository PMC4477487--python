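"""WANS: what H/D exchange reveals about microfibril surfaces.

Generates a paired H/D wide-angle neutron dataset, forms the D - H
difference, fits both patterns jointly on the shared-position hypothesis,
and searches the meridional difference for the 00l peaks that appear only
after deuteration.
"""

import numpy as np

from fibrilscatter.simulate import GroundTruth, generate_wans_pair
from fibrilscatter.wans import (
    check_equatorial_consistency,
    detect_meridional,
    difference_profile,
    fit_hd_pair,
)

truth = GroundTruth.bamboo(seed=1)
h_eq, d_eq, h_mer, d_mer = generate_wans_pair(truth)

diff = difference_profile(d_eq, h_eq, normalisation="window")
j = np.argmin(diff.delta_intensity)
print(f"D - H difference: strongest negative lobe at q = {diff.q[j]:.2f} nm^-1")
print("(deuteration depresses the 1-10 reflection most, so the dip flags a")
print("pair of reflections hopelessly overlapped in the raw patterns)\n")

pair = fit_hd_pair(h_eq, d_eq)
print(f"Joint H/D fit (shared positions): q(1-10) = {pair.q_1m10:.3f} nm^-1, "
      f"q(110) = {pair.q_110:.3f} nm^-1")
report = check_equatorial_consistency(pair.h_fit, pair.d_fit)
print(f"Equatorial d-spacings consistent between H and D forms: {report['pass']}")
print("-> deuterated chains pack with the same lattice, so the exchanged")
print("   hydroxyls sit on microfibril surfaces, not in the crystal interior.\n")

mer_diff = difference_profile(d_mer, h_mer, normalisation="none")
for det in detect_meridional(mer_diff, fibre_repeat_c=truth.fibre_repeat_c):
    state = "detected" if det["detected"] else "absent"
    print(f"  00{det['l']} at q = {det['q']:.2f} nm^-1 "
          f"(expected {det['q_expected']:.2f}): {state}")
print("Meridional 001/002 appear only in the D form: the exchanged surface")
print("chains are staggered irregularly along the fibre axis.")
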