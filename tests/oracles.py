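"""Independent oracles used only by the tests.

The scalar delay-equation oracle integrates segment by segment (method of
steps) with scipy's Radau solver at tight tolerance, interpolating the past
with a cubic spline over densely stored samples.  It shares no code with
the package integrator.
"""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline


def oracle_scalar_dde(alpha, h, tau, t_end, x_hist=1.0, rtol=1e-10, atol=1e-12):
    """High-accuracy reference solution of dx/dt = alpha/(1+x(t-tau)^h) - x."""
    T = np.array([-tau, 0.0])
    X = np.array([x_hist, x_hist])
    t = 0.0
    while t < t_end:
        spl = CubicSpline(T, X)
        seg_end = min(t + tau, t_end)

        def rhs(tt, y):
            return [alpha / (1.0 + max(spl(tt - tau), 0.0) ** h) - y[0]]

        sol = solve_ivp(rhs, (t, seg_end), [X[-1]], method="Radau",
                        rtol=rtol, atol=atol, dense_output=True)
        tt = np.linspace(t, seg_end, max(int((seg_end - t) / 0.002), 8))[1:]
        T = np.concatenate([T, tt])
        X = np.concatenate([X, sol.sol(tt)[0]])
        t = seg_end
    return T, X


def oracle_period(T, X, t_min):
    """Period from mean-level up-crossings of an oracle trajectory."""
    m = T >= t_min
    tw, xw = T[m], X[m]
    level = 0.5 * (xw.max() + xw.min())
    s = xw - level
    idx = np.where((s[:-1] < 0) & (s[1:] >= 0))[0]
    crossings = tw[idx] + (tw[idx + 1] - tw[idx]) * (-s[idx]) / (s[idx + 1] - s[idx])
    if len(crossings) < 3:
        raise RuntimeError("oracle trajectory has too few crossings")
    return float(np.diff(crossings).mean())
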