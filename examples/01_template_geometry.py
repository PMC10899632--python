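"""Where does an elongating polymerase collide with chromatin?

Builds the default transcription template (stall at +58, end at +231, five
histone dimers on the tandem positioning sequence) and prints the
transcript positions at which the TEC leading edge meets each dimer.
"""

from tecelong import (
    barrier_encounter_positions,
    default_template,
    make_landscape,
)

template = default_template()
positions = barrier_encounter_positions(template)

print(f"stall at +{template.stall_pos}, template end at +{template.full_length}")
print(f"barrier encounters at: {positions}")
print("(first contact at +70; one more every 30 nt, the dimer footprint)")

for variant in ("HTkA-free", "WT", "E19K/G52K"):
    ls = make_landscape(template, variant)
    print(f"{variant:>10}: first-barrier strength beta = {ls.barrier_factors[0]:g}")
print("beta divides the stepping rate at the first collision;")
print("beta = 1 means the landscape poses no barrier at all.")
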