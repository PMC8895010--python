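"""Independent numerical oracles shared across test modules."""

import numpy as np
from scipy.linalg import solve_banded

import mesocluster as mc


def fd_oracle(params, R, plateau, grid, n_fd=40001):
    """Finite-difference solve of the screened steady-state dimer equation.

    Solves D₂(u'' + 2u'/r) − k₂u = −k₂·Δ·1{r≤R} for the dimer excess u on
    a fine uniform mesh (R snapped to a node), with a no-flux inner and a
    decayed outer boundary, then interpolates onto ``grid``.  This is an
    independent route to the steady profile: banded linear algebra instead
    of the analytic matched sinh/exponential solution.
    """
    D2, k2 = params.D2, params.k2
    lam = mc.screening_length(D2, k2)
    r = np.linspace(lam * 1e-3, grid[-1], n_fd)
    r[np.argmin(np.abs(r - R))] = R
    h = np.diff(r)
    ab = np.zeros((3, n_fd))
    rhs = -k2 * np.where(r <= R, plateau, 0.0)
    hm, hp = h[:-1], h[1:]
    mid = slice(1, n_fd - 1)
    lower = 2 * D2 / (hm * (hm + hp)) - 2 * D2 / (r[mid] * (hm + hp))
    upper = 2 * D2 / (hp * (hm + hp)) + 2 * D2 / (r[mid] * (hm + hp))
    diag = -2 * D2 / (hm * hp) - k2
    ab[0, 2:] = upper
    ab[1, mid] = diag
    ab[2, :-2] = lower
    ab[1, 0] = 1.0
    ab[0, 1] = -1.0
    rhs[0] = 0.0
    ab[1, -1] = 1.0
    ab[2, -2] = 0.0
    rhs[-1] = 0.0
    u = solve_banded((1, 1), ab, rhs)
    return np.interp(grid, r, u)
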