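"""Reported marginal means of the source field study, used as worked-example
inputs.

The study compared a burned and an unburned patch of one distylous
*Palicourea rigida* population.  Raw field data were not deposited; what is
available are the published back-transformed marginal means (+- SE) per group
and the percent effect sizes derived from them.  These constants let the
percent-effect arithmetic be exercised against the published numbers, with
the convention that for area comparisons the unburned (no-fire) group is the
reference and for morph comparisons the second-named group is the reference.
"""

from __future__ import annotations

from .effects import GroupMean

#: (name, trait, focal GroupMean, reference GroupMean, published percent)
REPORTED_PERCENT_EFFECTS: list[tuple[str, str, GroupMean, GroupMean, float]] = [
    ("inflorescence_length_fire_vs_no_fire", "inflorescence_length",
     GroupMean("fire", 24.26, 0.62), GroupMean("no_fire", 26.77, 0.61), -9.38),
    ("fruits_s_morph_fire_vs_no_fire", "n_fruits",
     GroupMean("fire:S", 121.47, 0.09), GroupMean("no_fire:S", 89.77, 0.07), 35.31),
    ("corolla_length_fire_vs_no_fire", "corolla_length",
     GroupMean("fire", 13.54, 0.02), GroupMean("no_fire", 14.21, 0.02), -4.71),
    ("stigma_height_l_vs_s", "stigma_height",
     GroupMean("L", 16.46, 0.21), GroupMean("S", 10.42, 0.21), 57.97),
    ("anther_height_s_vs_l", "anther_height",
     GroupMean("S", 16.51, 0.01), GroupMean("L", 10.83, 0.01), 52.45),
    ("stigma_length_l_morph_fire_vs_no_fire", "stigma_length",
     GroupMean("fire:L", 1.03, 0.05), GroupMean("no_fire:L", 1.55, 0.05), -33.55),
    ("stigma_length_s_vs_l", "stigma_length",
     GroupMean("S", 3.89, 0.04), GroupMean("L", 1.29, 0.04), 201.55),
    ("anther_length_fire_vs_no_fire", "anther_length",
     GroupMean("fire", 3.48, 0.02), GroupMean("no_fire", 3.70, 0.02), -5.95),
    ("nectar_calories_s_vs_l", "nectar_calories",
     GroupMean("S", 13.64, 0.68), GroupMean("L", 12.06, 0.71), 13.10),
]
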