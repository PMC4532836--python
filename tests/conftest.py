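"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.optimize import linprog

from cuproforce.refstructs import synthetic_azurin_pdb, synthetic_plastocyanin_pdb
from cuproforce.structure import parse_structure


@pytest.fixture(scope="session")
def azurin_model():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return parse_structure(synthetic_azurin_pdb(), "A")


@pytest.fixture(scope="session")
def plastocyanin_model():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return parse_structure(synthetic_plastocyanin_pdb(), "A")


# ---------------------------------------------------------------------------
# Brute-force dip oracle: minimise the sup-norm distance from the empirical
# CDF over piecewise-linear unimodal CDFs by linear programming, enumerating
# every possible mode position (each gap between data values, and an atom at
# each data value).  Only feasible for small n; used to validate the fast
# hull-based implementation.
# ---------------------------------------------------------------------------

def _lp_dip_case(u, a, b, kind, m):
    K = len(u)
    nv = K + 1 if kind == "atom" else K
    A_ub, b_ub = [], []

    def row(coefs, rhs):
        r = np.zeros(nv + 1)
        for idx, cval in coefs:
            r[idx] = cval
        A_ub.append(r)
        b_ub.append(rhs)

    if kind == "atom":
        j = m

        def gi(k):
            return k - 1 if k < j else k

        gL, gR = j - 1, j
    else:

        def gi(k):
            return k - 1

    for k in range(1, K + 1):
        if kind == "atom" and k == m:
            row([(gR, -1), (nv, -1)], -a[k - 1])
            row([(gR, 1), (nv, -1)], a[k - 1])
            row([(gL, -1), (nv, -1)], -b[k - 1])
            row([(gL, 1), (nv, -1)], b[k - 1])
        else:
            row([(gi(k), -1), (nv, -1)], -a[k - 1])
            row([(gi(k), 1), (nv, -1)], b[k - 1])
    for i1 in range(nv - 1):
        row([(i1, 1), (i1 + 1, -1)], 0.0)
    if kind == "gap":
        left = [(u[k - 1], gi(k)) for k in range(1, m + 1)]
        right = [(u[k - 1], gi(k)) for k in range(m + 1, K + 1)]
    else:
        left = [(u[k - 1], gi(k)) for k in range(1, m)] + [(u[m - 1], gL)]
        right = [(u[m - 1], gR)] + [(u[k - 1], gi(k)) for k in range(m + 1, K + 1)]

    def slope_rows(pts, convex):
        for (x0, i0), (x1, i1), (x2, i2) in zip(pts, pts[1:], pts[2:]):
            c0 = -1.0 / (x1 - x0)
            c1 = 1.0 / (x1 - x0) + 1.0 / (x2 - x1)
            c2 = -1.0 / (x2 - x1)
            if convex:
                row([(i0, c0), (i1, c1), (i2, c2)], 0.0)
            else:
                row([(i0, -c0), (i1, -c1), (i2, -c2)], 0.0)

    slope_rows(left, True)
    slope_rows(right, False)
    c = np.zeros(nv + 1)
    c[nv] = 1.0
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=[(0, 1)] * nv + [(0, 1)], method="highs")
    assert res.status == 0, res.message
    return res.fun


def dip_bruteforce(sample) -> float:
    """Exact dip by LP over all unimodal piecewise-linear CDFs (small n)."""
    x = np.sort(np.asarray(sample, dtype=float))
    u, counts = np.unique(x, return_counts=True)
    n = x.size
    cum = np.cumsum(counts)
    a, b = cum / n, (cum - counts) / n
    K = len(u)
    cases = [("gap", m) for m in range(K + 1)] + [("atom", j) for j in range(1, K + 1)]
    return min(_lp_dip_case(u, a, b, kind, m) for kind, m in cases)
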