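"""Restricted cubic spline (natural spline) basis.

The basis follows Harrell's parameterization: with knots
``t_1 < ... < t_K`` the expansion of ``x`` has ``K - 1`` columns — the
identity term plus ``K - 2`` nonlinear terms that are cubic between the
boundary knots and linear beyond them.  Weight models use 3 knots and
dose-response curves use 5 knots.
"""

from __future__ import annotations

import numpy as np

# default quantile positions for knot placement, keyed by knot count
DEFAULT_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def rcs_knots(x, n_knots: int = 3) -> np.ndarray:
    """Knot locations at the standard quantiles of ``x``.

    Falls back to evenly spaced quantiles for knot counts without a
    conventional placement rule.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    qs = DEFAULT_KNOT_QUANTILES.get(n_knots)
    if qs is None:
        qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(x, qs)
    if np.unique(knots).size != len(knots):
        raise ValueError("degenerate knots: covariate has too few distinct values")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline design columns for ``x``.

    Returns an array of shape ``(n, K - 1)``: column 0 is ``x`` itself,
    columns 1.. are the restricted cubic terms, scaled by the squared
    boundary-knot span so coefficients stay on a comparable scale.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    t_first, t_pen, t_last = knots[0], knots[-2], knots[-1]
    norm = (t_last - t_first) ** 2

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - t_pen) * (t_last - tj) / (t_last - t_pen)
            + pos3(x - t_last) * (t_pen - tj) / (t_last - t_pen)
        ) / norm
        cols.append(term)
    return np.column_stack(cols)
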