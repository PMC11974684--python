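"""REC2-NUC geometry of a conformational ensemble.

Builds a synthetic two-domain ensemble whose centre-of-mass separation
fluctuates around 9 A, then measures per-frame COM distances, heavy-atom
contacts (< 3.5 A, hydrogens excluded), persistent residue pairs, and the
KDE of the distance distribution.
"""

import numpy as np

from cas12akin import (
    DOMAIN_PRESETS,
    EnsembleSpec,
    com_distance_series,
    contact_residue_pairs,
    contact_series,
    generate_ensemble,
    kde_density,
)

domains = DOMAIN_PRESETS["FnCas12a"]  # REC2 340-591, NUC 1079-1254
spec = EnsembleSpec(n_frames=200, distance_mean=9.0, distance_sd=1.5, seed=4)
ensemble = generate_ensemble(spec, domains)

series = contact_series(ensemble, domains, cutoff=3.5)
print(f"{ensemble.n_frames} frames, {ensemble.n_atoms} atoms")
print(f"COM distance: {series.distances.mean():.2f} +/- {series.distances.std():.2f} A")
print(f"contacts/frame: {series.contacts.mean():.1f} (max {series.contacts.max()})")

# the synthetic domains tumble freely, so individual residue pairs recur in
# only a few percent of frames; a real clamped trajectory shows persistent
# pairs at the default 10% threshold
pairs = contact_residue_pairs(ensemble, domains, min_frame_fraction=0.02)
print("most recurrent residue contacts (rec2_res, nuc_res, frame fraction):")
for rec2_res, nuc_res, frac in pairs[:5]:
    print(f"  {rec2_res:5d}  {nuc_res:5d}  {frac:.2f}")

grid, density = kde_density(series.distances)
print(f"distance KDE peaks at {grid[np.argmax(density)]:.2f} A")
# Tighter clamping (smaller distance, more contacts) correlates with faster
# target-strand cleavage across orthologues.
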