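"""Numba kernels for constrained voxel-wise least-squares fitting.

All kernels work in scaled coordinates: b in 1e3 s/mm² and ADC in
1e-3 mm²/s, so the exponent -ADC*b is unchanged but fractions and ADCs
share a common O(1) scale; gradient steps then behave uniformly across
parameters.  Parameter vector layout (fractions first, then ADCs):

=========  ==============================================  ====
model      layout                                          code
=========  ==============================================  ====
biexp      [f_slow, adc_slow, adc_fast]                    0
triexp     [f_very_slow, f_slow, adc_vs, adc_s, adc_f]     1
modtriexp  [f0, f_slow, adc_slow, adc_fast]                2
=========  ==============================================  ====

Constraints: all entries >= 0 and the fraction block sums to <= 1 (the
implied fast fraction absorbs the remainder).
"""

import numpy as np
from numba import njit

MODEL_CODES = {"biexp": 0, "triexp": 1, "modtriexp": 2}
N_FRACTIONS = {"biexp": 1, "triexp": 2, "modtriexp": 2}


@njit(cache=False)
def model_eval(code, x, b, out):
    """Normalized model signal at each (scaled) b."""
    n = b.size
    if code == 0:
        fs, a_s, a_f = x[0], x[1], x[2]
        for i in range(n):
            out[i] = fs * np.exp(-a_s * b[i]) + (1.0 - fs) * np.exp(-a_f * b[i])
    elif code == 2:
        f0, fs, a_s, a_f = x[0], x[1], x[2], x[3]
        ff = 1.0 - f0 - fs
        for i in range(n):
            out[i] = f0 + fs * np.exp(-a_s * b[i]) + ff * np.exp(-a_f * b[i])
    else:
        fvs, fs, a_vs, a_s, a_f = x[0], x[1], x[2], x[3], x[4]
        ff = 1.0 - fvs - fs
        for i in range(n):
            out[i] = (fvs * np.exp(-a_vs * b[i]) + fs * np.exp(-a_s * b[i])
                      + ff * np.exp(-a_f * b[i]))


@njit(cache=False)
def rss_value(code, x, b, y):
    """Residual sum of squares of the model against data ``y``."""
    n = b.size
    m = np.empty(n)
    model_eval(code, x, b, m)
    s = 0.0
    for i in range(n):
        r = m[i] - y[i]
        s += r * r
    return s


@njit(cache=False)
def _rss_grad(code, x, b, y, g):
    """RSS and its gradient wrt the parameter vector."""
    rss = 0.0
    for j in range(g.size):
        g[j] = 0.0
    n = b.size
    if code == 0:
        fs, a_s, a_f = x[0], x[1], x[2]
        for i in range(n):
            es = np.exp(-a_s * b[i])
            ef = np.exp(-a_f * b[i])
            r = fs * es + (1.0 - fs) * ef - y[i]
            rss += r * r
            g[0] += 2.0 * r * (es - ef)
            g[1] += -2.0 * r * fs * b[i] * es
            g[2] += -2.0 * r * (1.0 - fs) * b[i] * ef
    elif code == 2:
        f0, fs, a_s, a_f = x[0], x[1], x[2], x[3]
        ff = 1.0 - f0 - fs
        for i in range(n):
            es = np.exp(-a_s * b[i])
            ef = np.exp(-a_f * b[i])
            r = f0 + fs * es + ff * ef - y[i]
            rss += r * r
            g[0] += 2.0 * r * (1.0 - ef)
            g[1] += 2.0 * r * (es - ef)
            g[2] += -2.0 * r * fs * b[i] * es
            g[3] += -2.0 * r * ff * b[i] * ef
    else:
        fvs, fs, a_vs, a_s, a_f = x[0], x[1], x[2], x[3], x[4]
        ff = 1.0 - fvs - fs
        for i in range(n):
            evs = np.exp(-a_vs * b[i])
            es = np.exp(-a_s * b[i])
            ef = np.exp(-a_f * b[i])
            r = fvs * evs + fs * es + ff * ef - y[i]
            rss += r * r
            g[0] += 2.0 * r * (evs - ef)
            g[1] += 2.0 * r * (es - ef)
            g[2] += -2.0 * r * fvs * b[i] * evs
            g[3] += -2.0 * r * fs * b[i] * es
            g[4] += -2.0 * r * ff * b[i] * ef
    return rss


@njit(cache=False)
def _project(x, nf):
    """Project in place onto {fractions >= 0, sum <= 1} x {ADCs >= 0}.

    The fraction block is projected onto the simplex slice by Euclidean
    projection: clip negatives; if the sum still exceeds one, shift by the
    water-filling threshold found by bisection.
    """
    s = 0.0
    mx = 0.0
    for j in range(nf):
        if x[j] < 0.0:
            x[j] = 0.0
        s += x[j]
        if x[j] > mx:
            mx = x[j]
    if s > 1.0:
        lo = 0.0
        hi = mx
        for _ in range(100):
            th = 0.5 * (lo + hi)
            t = 0.0
            for j in range(nf):
                v = x[j] - th
                if v > 0.0:
                    t += v
            if t > 1.0:
                lo = th
            else:
                hi = th
        th = 0.5 * (lo + hi)
        for j in range(nf):
            v = x[j] - th
            x[j] = v if v > 0.0 else 0.0
    for j in range(nf, x.size):
        if x[j] < 0.0:
            x[j] = 0.0
    return x


@njit(cache=False)
def descent(code, nf, x0, b, y, max_iter, rel_tol, step0):
    """Projected gradient descent with Barzilai-Borwein (spectral) steps.

    Backtracking halves the trial step until the objective decreases; the
    accepted step seeds the next BB step length.  Stops when the relative
    RSS decrease falls below ``rel_tol`` or no decreasing step exists.

    Returns (x, rss, n_iterations, converged).
    """
    x = x0.copy()
    _project(x, nf)
    npar = x.size
    g = np.zeros(npar)
    gn = np.zeros(npar)
    xn = np.zeros(npar)
    rss = _rss_grad(code, x, b, y, g)
    s = step0
    nit = 0
    converged = False
    for it in range(max_iter):
        nit = it + 1
        improved = False
        st = s
        rn = rss
        for _ in range(60):
            for j in range(npar):
                xn[j] = x[j] - st * g[j]
            _project(xn, nf)
            rn = _rss_grad(code, xn, b, y, gn)
            if rn < rss:
                improved = True
                break
            st *= 0.5
        if not improved:
            converged = True  # stationary: no descent direction step helps
            break
        rel = (rss - rn) / (rss if rss > 1e-300 else 1e-300)
        dxdg = 0.0
        dxdx = 0.0
        for j in range(npar):
            dx = xn[j] - x[j]
            dg = gn[j] - g[j]
            dxdg += dx * dg
            dxdx += dx * dx
        tmp = x; x = xn; xn = tmp
        tmp = g; g = gn; gn = tmp
        rss = rn
        s = dxdx / dxdg if dxdg > 0.0 else st * 2.0
        if rel < rel_tol:
            converged = True
            break
    return x, rss, nit, converged


@njit(cache=False)
def _resid_jac(code, x, b, y, r, J):
    """Residuals and Jacobian (d residual / d parameter)."""
    n = b.size
    if code == 0:
        fs, a_s, a_f = x[0], x[1], x[2]
        for i in range(n):
            es = np.exp(-a_s * b[i])
            ef = np.exp(-a_f * b[i])
            r[i] = fs * es + (1.0 - fs) * ef - y[i]
            J[i, 0] = es - ef
            J[i, 1] = -fs * b[i] * es
            J[i, 2] = -(1.0 - fs) * b[i] * ef
    elif code == 2:
        f0, fs, a_s, a_f = x[0], x[1], x[2], x[3]
        ff = 1.0 - f0 - fs
        for i in range(n):
            es = np.exp(-a_s * b[i])
            ef = np.exp(-a_f * b[i])
            r[i] = f0 + fs * es + ff * ef - y[i]
            J[i, 0] = 1.0 - ef
            J[i, 1] = es - ef
            J[i, 2] = -fs * b[i] * es
            J[i, 3] = -ff * b[i] * ef
    else:
        fvs, fs, a_vs, a_s, a_f = x[0], x[1], x[2], x[3], x[4]
        ff = 1.0 - fvs - fs
        for i in range(n):
            evs = np.exp(-a_vs * b[i])
            es = np.exp(-a_s * b[i])
            ef = np.exp(-a_f * b[i])
            r[i] = fvs * evs + fs * es + ff * ef - y[i]
            J[i, 0] = evs - ef
            J[i, 1] = es - ef
            J[i, 2] = -fvs * b[i] * evs
            J[i, 3] = -fs * b[i] * es
            J[i, 4] = -ff * b[i] * ef
    s = 0.0
    for i in range(n):
        s += r[i] * r[i]
    return s


@njit(cache=False)
def lm_polish(code, nf, x0, b, y, max_iter, rel_tol):
    """Projected Levenberg-Marquardt refinement from a near-optimal start.

    Damped Gauss-Newton steps projected onto the feasible set; the damping
    factor grows tenfold on rejection and shrinks on acceptance.  Returns
    (x, rss, n_iterations).
    """
    x = x0.copy()
    _project(x, nf)
    npar = x.size
    n = b.size
    r = np.zeros(n)
    J = np.zeros((n, npar))
    rss = _resid_jac(code, x, b, y, r, J)
    lam = 1e-6
    nit = 0
    for it in range(max_iter):
        nit = it + 1
        gvec = J.T @ r
        # active set: parameters pinned at the zero bound whose gradient
        # points outward are dropped from the Gauss-Newton system, else the
        # clipped coordinate corrupts the step for the free parameters
        free = np.empty(npar, dtype=np.int64)
        nfree = 0
        for j in range(npar):
            if x[j] <= 0.0 and gvec[j] > 0.0:
                continue
            free[nfree] = j
            nfree += 1
        if nfree == 0:
            break
        Jf = np.zeros((n, nfree))
        for c in range(nfree):
            Jf[:, c] = J[:, free[c]]
        gf = np.zeros(nfree)
        for c in range(nfree):
            gf[c] = gvec[free[c]]
        ok = False
        rel = 0.0
        for _ in range(40):
            A = Jf.T @ Jf
            for j in range(nfree):
                A[j, j] = A[j, j] * (1.0 + lam) + 1e-300
            df = np.linalg.solve(A, -gf)
            xn = x.copy()
            for c in range(nfree):
                xn[free[c]] = x[free[c]] + df[c]
            _project(xn, nf)
            rn_r = np.zeros(n)
            Jn = np.zeros((n, npar))
            rn = _resid_jac(code, xn, b, y, rn_r, Jn)
            if rn < rss:
                rel = (rss - rn) / (rss if rss > 1e-300 else 1e-300)
                x = xn
                r = rn_r
                J = Jn
                rss = rn
                lam = max(lam * 0.3, 1e-12)
                ok = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        if not ok:
            break
        if rel < rel_tol:
            break
    return x, rss, nit


@njit(cache=False)
def fit_one(code, nf, x0, b, y, max_iter, rel_tol, step0, extra_starts):
    """Full single-curve fit: descent + LM from x0, then LM from extra starts.

    ``extra_starts`` is an (m, npar) array of deterministic alternative
    initializations (each gets a short descent then LM polish); the lowest
    RSS wins.  Returns (x_best, rss_best, iterations_total, converged).
    """
    xd, rd, nit, conv = descent(code, nf, x0, b, y, max_iter, rel_tol, step0)
    xb, rb, nlm = lm_polish(code, nf, xd, b, y, 200, 1e-15)
    total = nit + nlm
    for m in range(extra_starts.shape[0]):
        xs = extra_starts[m].copy()
        xd2, rd2, nit2, _ = descent(code, nf, xs, b, y, 400, rel_tol, step0)
        xp2, rp2, nlm2 = lm_polish(code, nf, xd2, b, y, 200, 1e-15)
        total += nit2 + nlm2
        if rp2 < rb:
            xb = xp2
            rb = rp2
    # one more alternation: projected LM can stall on an active constraint
    # boundary, which the projected BB descent then slides along
    xd3, rd3, nit3, _ = descent(code, nf, xb, b, y, 2000, rel_tol, step0)
    xp3, rp3, nlm3 = lm_polish(code, nf, xd3, b, y, 200, 1e-15)
    total += nit3 + nlm3
    if rp3 < rb:
        xb = xp3
        rb = rp3
    return xb, rb, total, conv
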