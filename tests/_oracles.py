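"""Independent oracles shared by the test suite.

These are deliberately written apart from the production code paths: a
coarse-grid + Nelder-Mead optimizer for the two-parameter directional
kurtosis decay, against which the closed-form linear fit is checked.
"""

import numpy as np
from scipy.optimize import minimize


def nelder_mead_fit(y, bvals):
    """Fit (D_app, K_app) by direct minimization of the squared residuals."""
    b = np.asarray(bvals, dtype=float)

    def loss(x):
        d, k = x
        pred = -b * d + b**2 * d**2 * k / 6.0
        return np.sum((pred - y) ** 2)

    grid_d = np.linspace(1e-5, 4e-3, 40)
    grid_k = np.linspace(0.0, 3.0, 40)
    best = min(((d, k) for d in grid_d for k in grid_k), key=loss)
    res = minimize(
        loss, best, method="Nelder-Mead",
        options=dict(xatol=1e-14, fatol=1e-24, maxiter=20000, maxfev=20000),
    )
    return res.x
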