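"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's LP machinery: vertices of the flux
polytope are enumerated directly from the nullspace structure, and the
phase ODEs are integrated with scipy. Slow but trustworthy at toy sizes.
"""

from itertools import combinations, product

import numpy as np
from scipy.integrate import solve_ivp


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-9):
    """All vertices of {v : S v = 0, lb <= v <= ub} by active-set search.

    A vertex fixes d = n - rank(S) variables at a bound; every choice of
    d indices and bound sides is solved and feasibility-checked.
    Exponential — use only for networks of a dozen reactions.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    vertices = []
    for idx in combinations(range(n), d):
        free = [j for j in range(n) if j not in idx]
        for sides in product((0, 1), repeat=d):
            fixed = {j: (lb[j] if s == 0 else ub[j])
                     for j, s in zip(idx, sides)}
            rhs = -S[:, list(idx)] @ np.array([fixed[j] for j in idx])
            A = S[:, free]
            sol, residual, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.empty(n)
            for j, s in fixed.items():
                v[j] = s
            for j, s in zip(free, sol):
                v[j] = s
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
                vertices.append(v)
    return vertices


def lp_max_by_enumeration(S, lb, ub, c) -> float:
    """max c.v over the polytope via vertex enumeration."""
    verts = enumerate_vertices(S, lb, ub)
    assert verts, "polytope has no vertices (infeasible?)"
    return max(float(np.dot(c, v)) for v in verts)


def integrate_tf(t_c, S_c, mu2, f2, A_c, rtol=1e-10):
    """Substrate-depletion time by integrating S' = -f2 A, A' = mu2 A."""

    def rhs(t, y):
        S, A = y
        return [-f2 * A, mu2 * A]

    def dry(t, y):
        return y[0]

    dry.terminal = True
    dry.direction = -1
    res = solve_ivp(rhs, (t_c, t_c + 1e7), [S_c, A_c], events=dry,
                    rtol=rtol, atol=1e-12, max_step=1.0)
    assert res.t_events[0].size == 1
    return float(res.t_events[0][0])


def phase1_constants(mu1, f1, q, A0, S0, P0):
    """Closed-form t_c, A_c, S_c for exponential phase-1 growth.

    dP/dt = -q A with A = A0 e^(mu1 t) gives
    t_c = (1/mu1) ln(1 + P0 mu1 / (q A0)); A_c = A0 + mu1 P0 / q;
    S_c = S0 - f1 P0 / q. The mu1 = 0 limit is t_c = P0 / (q A0).
    """
    if mu1 == 0.0:
        t_c = P0 / (q * A0)
        return t_c, A0, S0 - f1 * A0 * t_c
    t_c = np.log(1.0 + P0 * mu1 / (q * A0)) / mu1
    A_c = A0 + mu1 * P0 / q
    S_c = S0 - f1 * P0 / q
    return float(t_c), float(A_c), float(S_c)
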