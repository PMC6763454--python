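"""Independent reference implementations used only to cross-check the package.

Each oracle takes the slow-but-obvious route: full 4th-order tensor algebra,
double loops over pixels, exhaustive grid search.  They deliberately share no
code with the implementation paths they check.
"""

import numpy as np

_VOIGT = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def voigt_to_full(c6: np.ndarray) -> np.ndarray:
    """Expand a 6x6 Voigt stiffness into the full 3x3x3x3 tensor."""
    c = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(_VOIGT):
        for b, (k, l) in enumerate(_VOIGT):
            val = c6[a, b]
            for ii, jj in ((i, j), (j, i)):
                for kk, ll in ((k, l), (l, k)):
                    c[ii, jj, kk, ll] = val
    return c


def full_to_voigt(c: np.ndarray) -> np.ndarray:
    c6 = np.zeros((6, 6))
    for a, (i, j) in enumerate(_VOIGT):
        for b, (k, l) in enumerate(_VOIGT):
            c6[a, b] = c[i, j, k, l]
    return c6


def rotate_full_tensor(c6: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Rotate via the full index transformation C'_ijkl = R_ia R_jb R_kc R_ld C_abcd."""
    c = voigt_to_full(c6)
    cr = np.einsum("ia,jb,kc,ld,abcd->ijkl", r, r, r, r, c)
    return full_to_voigt(cr)


def brute_neighbor_distances(c_prime, gamma, mask, stride):
    """Double-loop neighbor angular distances (right then below, row-major)."""
    h, w = mask.shape
    out = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            a = _director(c_prime[i, j], gamma[i, j])
            if j + stride < w and mask[i, j + stride]:
                out.append(_dist(a, _director(c_prime[i, j + stride], gamma[i, j + stride])))
            if i + stride < h and mask[i + stride, j]:
                out.append(_dist(a, _director(c_prime[i + stride, j], gamma[i + stride, j])))
    return np.asarray(out)


def _director(cp, g):
    cp, g = np.radians(cp), np.radians(g)
    return np.array([np.cos(g) * np.sin(cp), np.sin(g), np.cos(g) * np.cos(cp)])


def _dist(a, b):
    return np.degrees(np.arccos(min(1.0, abs(float(np.dot(a, b))))))


def grid_search_fit(values, angles_deg, baseline_a, amplitude_b):
    """Exhaustive coarse-to-fine search for (c', gamma) minimising the SSR
    of A + B cos^2(gamma) cos^2(chi - c'). Final resolution 0.01 degrees."""
    chi = np.radians(np.asarray(angles_deg))

    def ssr(cp, g):
        model = baseline_a + amplitude_b * np.cos(np.radians(g)) ** 2 * np.cos(chi - np.radians(cp)) ** 2
        return float(np.sum((values - model) ** 2))

    best = (None, None, np.inf)
    for cp in np.arange(-90.0, 90.0, 1.0):
        for g in np.arange(0.0, 90.5, 1.0):
            s = ssr(cp, g)
            if s < best[2]:
                best = (cp, g, s)
    cp0, g0, _ = best
    for step in (0.1, 0.01):
        cps = np.arange(cp0 - 10 * step, cp0 + 10 * step + step / 2, step)
        gs = np.arange(max(0.0, g0 - 10 * step), min(90.0, g0 + 10 * step) + step / 2, step)
        best = (cp0, g0, ssr(cp0, g0))
        for cp in cps:
            for g in gs:
                s = ssr(cp, g)
                if s < best[2]:
                    best = (cp, g, s)
        cp0, g0, _ = best
    return cp0, g0


def riemann_integral(f_x, f_y, x_max, n=1_000_000):
    """Rectangle-rule integral of a piecewise-linear curve on [0, x_max]."""
    xs = (np.arange(n) + 0.5) * (x_max / n)
    ys = np.interp(xs, f_x, f_y)
    return float(ys.sum() * x_max / n)
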