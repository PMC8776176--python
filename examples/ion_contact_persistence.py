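"""Persistence of an ion-coordination contact across a trajectory.

Mimics tracking a bound metal ion: a probe atom sits within coordination
distance (<= 3 A) of a binding residue for part of the trajectory and
drifts away for the rest.  The persistence is the fraction of frames in
contact, reported per partner residue.
"""

import numpy as np
import pandas as pd

from pbflex import Ensemble, atom_mask, contact_persistence

n_frames = 200
coords = np.zeros((n_frames, 3, 3))
coords[:, 1, 1] = 15.0  # second binding residue, far off the probe's path
# probe (resid 999): coordinated for the first 169 frames, then released
coords[:, 2, 0] = 2.2
coords[169:, 2, 0] = 8.0

atoms = pd.DataFrame(
    {
        "chain": ["A", "A", "A"],
        "resid": [607, 642, 999],
        "resname": ["VAL", "GLU", "CA"],
        "name": ["CA", "CA", "CA"],
        "b_factor": [0.0, 0.0, 0.0],
    }
)
ensemble = Ensemble(coords, atoms)

result = contact_persistence(
    ensemble,
    site_mask=atom_mask(ensemble, resids=[999]),
    partner_mask=atom_mask(ensemble, resids=[607, 642]),
    cutoff=3.0,
)
print(f"overall contact persistence: {result.overall:.3f}")
print(result.to_frame().to_string(index=False))
print(
    "\n0.845 means the ion stays coordinated to residue 607 for 84.5% of\n"
    "the simulated frames; residue 642 never comes within the 3 A cutoff\n"
    "(fraction 0.000)."
)
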