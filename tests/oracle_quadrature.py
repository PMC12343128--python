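"""Brute-force quadrature oracle for the observer's marginal likelihoods.

Evaluates the cue-evidence integrals directly on dense trapezoidal grids
over the latent hand position (and, for the perturbed cause, the rotation),
independently of the closed-form bivariate-Gaussian implementation it
checks.  Trapezoidal quadrature of smooth, rapidly decaying integrands is
spectrally accurate, so with steps of a tenth of the smallest SD and
±12 SD ranges the results are good far beyond the 1e-6 relative tolerance
used in the tests.
"""

import numpy as np


def _norm_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (np.sqrt(2.0 * np.pi) * sd)


def quad_marginals(x_v, x_c, sigma_v, sigma_c, sigma_h, sigma_r, b):
    """(density_nopert, density_pert) by direct numerical integration."""
    lo = min(x_v, x_c, b) - 12.0 * max(sigma_v, sigma_c, sigma_h)
    hi = max(x_v, x_c, b) + 12.0 * max(sigma_v, sigma_c, sigma_h)
    step = min(sigma_v, sigma_c, sigma_h) / 10.0
    xh = np.arange(lo, hi + step, step)

    f_no = _norm_pdf(x_v, xh, sigma_v) * _norm_pdf(x_c, xh, sigma_c) * _norm_pdf(xh, b, sigma_h)
    d_no = np.trapezoid(f_no, xh)

    r_half = 12.0 * sigma_r + abs(x_v - b) + 12.0 * sigma_v
    r_step = min(sigma_v, sigma_r) / 10.0
    r = np.arange(-r_half, r_half + r_step, r_step)
    f_pe = (
        _norm_pdf(x_v, xh[:, None] + r[None, :], sigma_v)
        * _norm_pdf(x_c, xh[:, None], sigma_c)
        * _norm_pdf(xh[:, None], b, sigma_h)
        * _norm_pdf(r[None, :], 0.0, sigma_r)
    )
    d_pe = np.trapezoid(np.trapezoid(f_pe, r, axis=1), xh)
    return float(d_no), float(d_pe)


# (sigma_r, b, sigma_c, sigma_h, sigma_v): spans extreme precision ratios
ORACLE_SETTINGS = [
    (4.0, 0.5, 0.6, 2.5, 1.0),
    (4.0, 0.5, 0.6, 2.5, 2.2),
    (2.0, -1.0, 0.4, 1.5, 1.0),
    (8.0, 2.0, 1.2, 5.0, 3.4),
    (0.5, 0.0, 0.2, 2.5, 1.0),
    (20.0, 0.0, 0.6, 2.5, 1.0),
    (4.0, 0.0, 5.0, 0.5, 0.3),
    (4.0, 5.0, 0.05, 2.5, 1.0),
    (1.0, 0.0, 1.0, 1.0, 5.0),
    (10.0, -3.0, 2.0, 8.0, 0.5),
]

# (x_v, x_c) offsets from the bias, shared across settings
ORACLE_CUE_OFFSETS = [
    (0.0, 0.0),
    (1.0, 0.5),
    (-2.0, 1.0),
    (4.0, -1.0),
    (8.0, 2.0),
    (-8.0, -2.0),
    (2.0, 2.0),
    (-4.0, 0.0),
    (6.0, 5.0),
    (0.3, -0.7),
]
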