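"""Fixed-step RK4 core for the delayed system (numba-compiled).

The six-dimensional state is integrated with classical RK4 at a fixed
step h, using the method of steps for the delayed TNF-production term:
the step size must divide the delay exactly, so the delayed
proinflammatory stock at whole-step stage times is read directly from
stored nodes.  At half-step stage times it is interpolated from the four
surrounding nodes (4-point Lagrange midpoint rule, O(h^4), consistent
with RK4's order); before t=0 the history is the constant initial value.

State layout: [resting, proinflammatory, et, lps, tnf, ccl2].
Parameter vector layout matches ModelParameters field order.
"""

import numpy as np
from numba import njit

# indices into the parameter vector (ModelParameters field order)
_MAX_ACT, _AC50, _N, _IMM, _KLPS, _MAX_SYN, _SC50, _M, _TD, _KTNF = range(10)
_CR, _CI, _CE, _KCCL2 = 10, 11, 12, 13


@njit(cache=False)
def _hill_nb(lps, vmax, c50, coef):
    if lps <= 0.0:
        return 0.0
    x = np.exp(coef * (np.log(lps) - np.log(c50)))
    return vmax * x / (1.0 + x)


@njit(cache=False)
def _rhs(y, p_del, pv, out):
    """Derivatives at one stage; p_del is the delayed proinflammatory stock."""
    a = _hill_nb(y[3], pv[_MAX_ACT], pv[_AC50], pv[_N])
    syn = _hill_nb(y[3], pv[_MAX_SYN], pv[_SC50], pv[_M])
    act = y[0] * a
    imm = y[1] * pv[_IMM]
    out[0] = -act
    out[1] = act - imm
    out[2] = imm
    out[3] = -y[3] * pv[_KLPS]
    out[4] = p_del * syn - y[4] * pv[_KTNF]
    out[5] = (
        y[0] * pv[_CR] + y[1] * pv[_CI] + y[2] * pv[_CE] - y[5] * pv[_KCCL2]
    )


@njit(cache=False)
def _p_node(hist, j, p0):
    """Proinflammatory stock at node j; constant history before t=0."""
    if j < 0:
        return p0
    return hist[j, 1]


@njit(cache=False)
def _p_half(hist, j, i_done, p0):
    """Proinflammatory stock at node time (j + 1/2)h.

    Uses the 4-point Lagrange midpoint formula when the stencil
    j-1..j+2 lies within stored nodes (index <= i_done), else falls
    back to linear interpolation; history padding below t=0.
    """
    if j < 0:  # stage time lies in the constant pre-history
        return p0
    if j - 1 < 0:
        # centered stencil would cross the derivative kink at t=0 (constant
        # history meets dynamics); use a one-sided forward cubic instead
        if j + 3 <= i_done:
            return (0.3125 * hist[j, 1] + 0.9375 * hist[j + 1, 1]
                    - 0.3125 * hist[j + 2, 1] + 0.0625 * hist[j + 3, 1])
    elif j + 2 <= i_done:
        return (-_p_node(hist, j - 1, p0) + 9.0 * _p_node(hist, j, p0)
                + 9.0 * _p_node(hist, j + 1, p0) - _p_node(hist, j + 2, p0)) / 16.0
    if j + 1 <= i_done:
        return 0.5 * (_p_node(hist, j, p0) + _p_node(hist, j + 1, p0))
    return _p_node(hist, j, p0)


@njit(cache=False)
def integrate(y0, pv, h, n_steps, td_steps):
    """Integrate n_steps of size h from y0; returns (n_steps+1, 6) nodes."""
    ys = np.empty((n_steps + 1, 6))
    ys[0] = y0
    p0 = y0[1]
    y = y0.copy()
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    yt = np.empty(6)
    for i in range(n_steps):
        if td_steps == 0:
            _rhs(y, y[1], pv, k1)
            for q in range(6):
                yt[q] = y[q] + 0.5 * h * k1[q]
            _rhs(yt, yt[1], pv, k2)
            for q in range(6):
                yt[q] = y[q] + 0.5 * h * k2[q]
            _rhs(yt, yt[1], pv, k3)
            for q in range(6):
                yt[q] = y[q] + h * k3[q]
            _rhs(yt, yt[1], pv, k4)
        else:
            pd0 = _p_node(ys, i - td_steps, p0)
            pdh = _p_half(ys, i - td_steps, i, p0)
            pd1 = _p_node(ys, i + 1 - td_steps, p0)
            _rhs(y, pd0, pv, k1)
            for q in range(6):
                yt[q] = y[q] + 0.5 * h * k1[q]
            _rhs(yt, pdh, pv, k2)
            for q in range(6):
                yt[q] = y[q] + 0.5 * h * k2[q]
            _rhs(yt, pdh, pv, k3)
            for q in range(6):
                yt[q] = y[q] + h * k3[q]
            _rhs(yt, pd1, pv, k4)
        for q in range(6):
            y[q] = y[q] + (h / 6.0) * (k1[q] + 2.0 * k2[q] + 2.0 * k3[q] + k4[q])
        ys[i + 1] = y
    return ys
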