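"""Regenerate the confined-vs-free critical values frozen in spt_modes.diffusion.

The classifier calls a segment confined when its fitted anomalous exponent
falls below the size-q quantile of the null distribution of the same
estimator applied to free 2D Brownian segments of the same length. The Wald
standard error from the nonlinear fit is miscalibrated for this test (MSD
points are strongly correlated and the null distribution of the exponent is
left-skewed), so the critical values are calibrated directly by simulation
here: free walks with localization noise (sigma = 20 nm, dt = 20 ms),
pooled over diffusion coefficients spanning the membrane-receptor range
(0.05-0.3 µm²/s).

Run:  python scripts/calibrate_classifier.py
and paste the printed table into ALPHA_CRIT in src/spt_modes/diffusion.py.
"""

import math
import warnings

import numpy as np
from scipy.optimize import curve_fit

DT = 0.020
SIGMA_LOC = 0.020
D_GRID = (0.05, 0.10, 0.15, 0.30)
L_GRID = (20, 25, 30, 40, 50, 70, 100, 150, 200, 300, 500, 800)
SIZES = (0.025, 0.05, 0.075, 0.10)
REPS_PER_D = 400
SEED = 20260927


def make_free(rng, length, d):
    steps = rng.normal(0.0, math.sqrt(2 * d * DT), size=(length, 2))
    steps[0] = 0.0
    return np.cumsum(steps, axis=0) + rng.normal(0.0, SIGMA_LOC, size=(length, 2))


def msd(pos, maxlag):
    out = np.empty(maxlag)
    for n in range(1, maxlag + 1):
        d = pos[n:] - pos[:-n]
        out[n - 1] = (d**2).sum(1).mean()
    return out


def alpha_hat(pos):
    length = len(pos)
    maxlag = min(length - 1, max(4, int(0.6 * length)))
    m = msd(pos, maxlag)
    lags = np.arange(1.0, maxlag + 1)
    t = lags * DT
    s = np.maximum(m, 1e-12) * np.sqrt(
        (2 * lags**2 + 1) / (3 * lags * (length - lags + 1))
    )

    def model(tt, g, a, c):
        return 4.0 * g * np.power(tt, a) + c

    g0 = max((m[-1] - m[0]) / (4.0 * (t[-1] - t[0])), 1e-8)
    p0 = (g0, 1.0, max(m[0] - 4.0 * g0 * t[0], 1e-12))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, m, p0=p0, sigma=s,
                bounds=([1e-9, 0.01, 0.0], [np.inf, 2.0, np.inf]), maxfev=3000,
            )
        return popt[1]
    except (RuntimeError, ValueError):
        return np.nan


def main():
    rng = np.random.default_rng(SEED)
    print("ALPHA_CRIT = {")
    print(f"    'lengths': {list(L_GRID)},")
    rows = {q: [] for q in SIZES}
    for length in L_GRID:
        reps = REPS_PER_D if length <= 200 else REPS_PER_D // 2
        a = []
        for d in D_GRID:
            a += [alpha_hat(make_free(rng, length, d)) for _ in range(reps)]
        a = np.asarray(a)
        a = a[np.isfinite(a)]
        for q in SIZES:
            rows[q].append(round(float(np.quantile(a, q)), 3))
    for q in SIZES:
        print(f"    {q}: {rows[q]},")
    print("}")


if __name__ == "__main__":
    main()
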