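"""Parameter recovery on an unconfounded affine dose-response design.

The generator draws y = 0.5 + 2*t + noise with treatment independent of
the covariates, so the true curve slope is exactly 2 everywhere.  The
fitted model's curve slope at a mid-range covariate profile should land
within a few percent of 2, and improve with sample size.
"""
import warnings

import numpy as np

import hnet
from hnet.synthetic_data import generate_linear_dgp

warnings.simplefilter("ignore", hnet.ExtrapolationWarning)
grid = hnet.DoseGrid.uniform(0.0, 1.0, 65)

for n in (200, 2000):
    ds, _ = generate_linear_dgp(n=n, p=2, slope_fn=2.0, intercept_fn=0.5,
                                confounding_strength=0.0, noise_sd=0.2, seed=1)
    model = hnet.fit(ds, hnet.TrainConfig(max_epochs=200, n_restarts=1), seed=0)
    curve = model.predict_curve(np.full(2, 0.5), grid)
    slope = np.polyfit(grid.points, curve, 1)[0]
    print(f"n={n:5d}: fitted average curve slope = {slope:.3f}  (truth 2.0)")
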