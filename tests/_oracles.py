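"""Independent oracles used by the test suite.

These deliberately re-derive quantities by a different route than the package
(vectorized Gauss-Newton instead of scipy trust-region, exhaustive grid
search instead of bisection) so agreement is informative.
"""

import numpy as np


def monoexp_t2_vectorized(te_s: np.ndarray, signals: np.ndarray, n_iter: int = 60):
    """Row-wise (S0, T2) least-squares monoexponential fits.

    ``signals`` has shape (m, k) for m independent series over k echoes.
    Log-linear initialization followed by Gauss-Newton on (ln S0, R2).
    Returns T2 in seconds, shape (m,).
    """
    te = np.asarray(te_s, dtype=float)
    y = np.asarray(signals, dtype=float)
    ly = np.log(y)
    k = te.size
    tbar = te.mean()
    r = -((ly - ly.mean(axis=1, keepdims=True)) @ (te - tbar)) / np.sum((te - tbar) ** 2)
    a = ly.mean(axis=1) + r * tbar
    for _ in range(n_iter):
        m = np.exp(a[:, None] - np.outer(r, te))  # model values
        e = m - y
        # J columns per row: dm/da = m, dm/dr = -te*m
        g_a = np.sum(m * e, axis=1)
        g_r = -np.sum(te * m * e, axis=1)
        h_aa = np.sum(m * m, axis=1)
        h_ar = -np.sum(te * m * m, axis=1)
        h_rr = np.sum(te * te * m * m, axis=1)
        det = h_aa * h_rr - h_ar * h_ar
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = -(h_rr * g_a - h_ar * g_r) / det
        dr = -(h_aa * g_r - h_ar * g_a) / det
        a = a + da
        r = r + dr
    return 1.0 / r


def stress_oef_grid_search(
    myo_stress_t2app_ms: float,
    r20t: float,
    r21t: float,
    mbv: float,
    te_ms: np.ndarray,
    alpha_myo: np.ndarray,
    step: float = 1e-4,
) -> float:
    """Exhaustive-grid inversion of the stress forward map.

    For every OEF on a ``step`` grid of [0, 1], build the noise-free
    two-compartment signal (tau = TE/3), reduce it to an apparent T2 with the
    vectorized fitter above, and return the grid OEF whose predicted apparent
    T2 is closest to the measured one.  ``alpha_myo`` is the (k, 3) array of
    myocardial alpha coefficients matching ``te_ms``.
    """
    te_ms = np.asarray(te_ms, dtype=float)
    te_s = te_ms / 1000.0
    tau_s = te_s / 3.0
    grid = np.arange(0.0, 1.0 + step / 2, step)
    a1, a2, a3 = alpha_myo[:, 0], alpha_myo[:, 1], alpha_myo[:, 2]
    r2b = a1[None, :] + a2[None, :] * grid[:, None] + a3[None, :] * grid[:, None] ** 2
    r2t = r20t + max(r21t, 0.0) * (grid[:, None] * mbv * tau_s[None, :]) ** 2
    sig = mbv * np.exp(-te_s[None, :] * r2b) + (1 - mbv) * np.exp(-te_s[None, :] * r2t)
    t2_pred_ms = monoexp_t2_vectorized(te_s, sig) * 1000.0
    return float(grid[np.argmin(np.abs(t2_pred_ms - myo_stress_t2app_ms))])
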