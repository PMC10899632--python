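"""Simulate one elongation restart time course and watch the seven-bin
transcript-length composition evolve.

Compares a WT chromatin landscape with the tight-binding double mutant:
the mutant's molecules pile up at the first barrier (+70, bin 2) while WT
transcripts reach full length within the standard 240 s window.
"""

import numpy as np

from tecelong import (
    default_bin_scheme,
    default_template,
    make_landscape,
    simulate_ensemble,
    transient_distribution,
)
from tecelong.simulate import params_for_condition

template = default_template()
scheme = default_bin_scheme()

for variant in ("WT", "E19K/G52K"):
    landscape = make_landscape(template, variant)
    params = params_for_condition(variant, tfs=False, n_molecules=5000, seed=7)
    print(f"\n{variant} chromatin, {params.n_molecules} molecules:")
    print("   t(s)  " + "  ".join(f"bin{b}" for b in range(1, 8)) + "   mean(nt)")
    for dist in simulate_ensemble(params, landscape, template):
        f = dist.bin_fractions(scheme)
        print(f"  {dist.time_s:5.0f}  " + "  ".join(f"{x:.2f}" for x in f)
              + f"   {dist.mean_length:6.1f}")
    # exact check for the last timepoint, no sampling noise
    oracle = transient_distribution(params, landscape, template, 240.0)
    print(f"  oracle mean at 240 s: {oracle.mean_length:.1f} nt "
          "(exact CTMC transient)")

print("\nbin 1 holds the still-stalled +58 species; bin 7 the full-length")
print("+231 transcripts. The mutant's mass stalls in bin 2 (the +70 pause).")
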