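"""Assign Protein Blocks to a synthetic ensemble and classify flexibility.

Builds a 30-frame backbone ensemble for a 14-residue segment — a rigid
beta-strand core with one loop-like mixture position — runs the
coordinates through dihedral computation and PB assignment, and prints
the per-position Neq with its flexibility class.
"""

import pandas as pd

from pbflex import (
    GeneratorSpec,
    assign_ensemble,
    compute_dihedrals,
    flex_profile,
    generate_coordinate_mode,
    pb_frequencies,
)

spec = GeneratorSpec.uniform_background(
    14,
    background="d",  # beta-strand core everywhere ...
    overrides={7: {"h": 0.3, "i": 0.3, "b": 0.2, "f": 0.2}},  # ... except a mobile loop
    n_frames=30,
    sigma=8.0,
    mode="coordinate",
    seed=42,
)
ensemble, _, _ = generate_coordinate_mode(spec)
pb = assign_ensemble(compute_dihedrals(ensemble))
flex = flex_profile(pb_frequencies(pb), min_count=5)

with pd.option_context("display.float_format", "{:.3f}".format):
    print(flex.to_frame()[["neq", "flex_class"]].dropna(subset=["neq"]))
print(
    "\nNeq ~1 marks positions sampling a single block (rigid strand); the\n"
    "mixture position and its window neighbours stand out with elevated\n"
    "Neq (more blocks visited over the trajectory).  Because adjacent\n"
    "assignment windows overlap, a single mobile position lifts Neq over\n"
    "a ~5-residue neighbourhood — just as a flexible loop does in real\n"
    "trajectories."
)
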