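"""Station BLUPs, variance components and heritability.

Generates a replicated two-location station trial, fits the simplified
mixed model (environment fixed; genotype, replicate and block random),
and prints the variance components with broad- and narrow-sense
heritability on the trial-mean basis.
"""

import numpy as np

from plbreed.benchmark import fit_gblup, heritability, kinship_vanraden, station_blup
from plbreed.synthetic_data import (
    gen_markers,
    gen_station_design,
    gen_station_trial,
    gen_true_model,
)

markers = gen_markers(120, 300, seed=1)
model = gen_true_model(markers, seed=2, shift_sd=0.0)
design = gen_station_design(markers.index, n_reps=2, seasons=("2012",), seed=3)
plots, _ = gen_station_trial(design, model, seed=4, n_raters=(2, 2))

blups, vc = station_blup(plots, trait="gy")
print("variance components:", {k: round(v, 4) for k, v in vc.items()})

K = kinship_vanraden(markers)
gm = fit_gblup(blups, K)
est = heritability(vc, n_reps=2, n_locs=2, genomic_var=gm.var_u)
print(f"H2 = {est.H2:.2f}  (genotypic share of the trial-mean variance)")
print(f"h2 = {est.h2:.2f}  (additive genomic variance in the same ratio)")
true_vg = float(np.var(model.yield_scale * model.log_worth_base))
print(f"true genetic variance {true_vg:.4f} vs estimated {vc['var_g']:.4f}")
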