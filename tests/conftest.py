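"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own solve/fit paths:
exact Gaussian elimination over Fractions for linear systems, closed-form
OLS for slopes, and lattice search for Michaelis-Menten minimisation.
"""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import settings as _hsettings

from wlpenergy import PathwayModel, Reaction, RedoxCouple, build_balance_system

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")


def gauss_solve_fractions(A_rows, b):
    """Solve A x = b exactly by Gauss-Jordan elimination over Fractions.

    Returns the unique solution vector, or raises ValueError when the
    system is singular/inconsistent.  Independent of sympy.
    """
    m = [list(map(Fraction, row)) + [Fraction(bi)] for row, bi in zip(A_rows, b)]
    n_rows, n_cols = len(m), len(m[0]) - 1
    pivots = []
    r = 0
    for c in range(n_cols):
        pivot = next((i for i in range(r, n_rows) if m[i][c] != 0), None)
        if pivot is None:
            continue
        m[r], m[pivot] = m[pivot], m[r]
        piv = m[r][c]
        m[r] = [v / piv for v in m[r]]
        for i in range(n_rows):
            if i != r and m[i][c] != 0:
                factor = m[i][c]
                m[i] = [vi - factor * vr for vi, vr in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
        if r == n_rows:
            break
    for i in range(r, n_rows):
        if m[i][-1] != 0:
            raise ValueError("inconsistent system")
    if len(pivots) < n_cols:
        raise ValueError("underdetermined system")
    x = [Fraction(0)] * n_cols
    for row_idx, c in enumerate(pivots):
        x[c] = m[row_idx][-1]
    return x


def brute_force_flux(model: PathwayModel):
    """Dense exact solve of the balance system, bypassing solve_flux."""
    A, b, _ = build_balance_system(model)
    rows = [[Fraction(int(A[i, j].p), int(A[i, j].q)) for j in range(A.cols)] for i in range(A.rows)]
    rhs = [Fraction(int(b[i].p), int(b[i].q)) for i in range(b.rows)]
    x = gauss_solve_fractions(rows, rhs)
    return {rxn.id: xi for rxn, xi in zip(model.reactions, x)}


def ols_slope(t, y):
    """Closed-form least-squares slope of y on t."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tbar, ybar = t.mean(), y.mean()
    return float(((t - tbar) * (y - ybar)).sum() / ((t - tbar) ** 2).sum())


def ols_slope_se(t, y):
    """Standard error of the OLS slope."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    slope = ols_slope(t, y)
    intercept = y.mean() - slope * t.mean()
    resid = y - (intercept + slope * t)
    dof = max(t.size - 2, 1)
    s2 = float(resid @ resid) / dof
    return float(np.sqrt(s2 / ((t - t.mean()) ** 2).sum()))


def mm_grid_search(s, v, km_range, vmax_range, n_grid=400):
    """Lattice minimiser of the Michaelis-Menten SSR (fit oracle)."""
    s = np.asarray(s, float)
    v = np.asarray(v, float)
    kms = np.linspace(*km_range, n_grid)
    vmaxs = np.linspace(*vmax_range, n_grid)
    best = (np.inf, None, None)
    for km in kms:
        pred = np.outer(vmaxs, s / (km + s))
        ssr = ((pred - v) ** 2).sum(axis=1)
        i = int(np.argmin(ssr))
        if ssr[i] < best[0]:
            best = (float(ssr[i]), float(km), float(vmaxs[i]))
    return best[1], best[2]


@pytest.fixture
def single_reaction_model():
    """Minimal model: one reaction A -> P with A external."""
    return PathwayModel(
        reactions=[Reaction("R", chem={"A": -1, "P": 1})],
        couples=[],
        external_species={"A"},
        product="P",
    )


@pytest.fixture
def co_acetate_model():
    from wlpenergy import get_scenario

    return get_scenario("fig5a_co_acetate").model
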