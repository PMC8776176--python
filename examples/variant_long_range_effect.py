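"""Detect a long-range variant effect in a WT-vs-variant comparison.

Emulates the hallmark pattern of integrin leg-domain missense variants:
the mutated position keeps its local conformation while a distant loop
changes its PB distribution.  Two synthetic systems are drawn — identical
targets except one distant position swapped from pure strand (d) to pure
loop (h) — compared, and the report printed.
"""

import json

from pbflex import (
    GeneratorSpec,
    SystemRun,
    compare_systems,
    flex_profile,
    generate_string_mode,
    inject_variant_effect,
    pb_frequencies,
)

base = GeneratorSpec.uniform_background(
    40,
    overrides={715: {"b": 0.5, "h": 0.5}, 725: {"m": 0.7, "l": 0.3}},
    first_resid=701,
    n_frames=5000,
    seed=7,
)
wt_spec, var_spec = inject_variant_effect(base, site=705, distant=735, effect="h")

from dataclasses import replace


def as_system(label, spec, seed):
    profile = pb_frequencies(generate_string_mode(replace(spec, seed=seed)))
    return SystemRun(label=label, pb_profile=profile, flex=flex_profile(profile))


report = compare_systems(
    as_system("wt", wt_spec, 7), as_system("variant", var_spec, 8),
    mutation_site=705,
)
print(json.dumps(report.to_dict(), indent=2, sort_keys=True))
print(
    "\nThe mutation site (705) shows near-zero dPB — its local structure is\n"
    "conserved — while residue 735, thirty residues away, is flagged with\n"
    "dPB = 2 (complete d -> h swap): a long-range, allostery-like effect."
)
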