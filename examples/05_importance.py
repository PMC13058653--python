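"""LMG relative importance of molecular predictors for a contrast map.

Builds a response map from two smooth predictors plus noise and shows
that the LMG decomposition splits the model R-squared into per-predictor
shares that recover the planted ordering, with bootstrap CIs.
"""

import numpy as np
import pandas as pd

from mindgrad import (
    build_spin_ensemble,
    fit_importance,
    generate_annotation_map,
    generate_parcellation,
)

parc = generate_parcellation(34, seed=1).left_only()
x1 = generate_annotation_map(parc, 0.5, seed=10)
x2 = generate_annotation_map(parc, 0.5, seed=11)
x3 = generate_annotation_map(parc, 0.5, seed=12)
rng = np.random.default_rng(0)
y = 0.6 * x1 + 0.3 * x2 + 0.4 * rng.standard_normal(len(x1))

ensemble = build_spin_ensemble(parc, n_spins=1000, seed=13)
result = fit_importance(
    y, pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}),
    ensemble=ensemble, n_boot=1000, seed=1,
)
print(f"adjusted R2 = {result.adjusted_r2:.3f} "
      f"(p_spin = {result.p_spin_fit:.4f})")
print(result.to_frame().round(3).to_string(index=False))
# Shares sum exactly to the model R2; x1 (coefficient 0.6) should claim
# the largest percentage share and x3 (no true effect) close to zero.
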