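"""Single-ligand dose-response fitting and Relative Ligand Strength.

Each ligand's gradient is summarized by a Hill function with the baseline
pinned at zero (responses are background-subtracted),

    y(c) = ymax * c**n / (EC50**n + c**n)

fit jointly over all biological replicates by least squares.  Relative
Ligand Strength (RLS) is the ligand's measured top-dose activity normalized
to the strongest ligand's, on a 0-1 scale; it deliberately uses the
measured top-dose median rather than the fitted ymax so that ligands whose
response has not saturated at the highest tested dose still receive a
defined (if underestimated) strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["HillCurve", "fit_hill", "relative_ligand_strength"]


class HillCurve(BaseEstimator, RegressorMixin):
    """Hill dose-response regressor with fixed zero baseline.

    Parameters
    ----------
    n_bounds : (low, high)
        Bounds on the Hill coefficient (default [0.1, 10]).
    ec50_bounds_factor : float
        EC50 is bounded within [min dose / f, max dose * f] (default 100).

    Attributes (after ``fit``)
    ----------
    ymax_ : float        saturating response
    ec50_ : float        dose of half-maximal response
    hill_ : float        Hill coefficient (logarithmic sensitivity)
    rss_ : float         residual sum of squares at the optimum
    non_activator_ : bool   set when no response rises above baseline

    Fitting is deterministic: a fixed 3x3 grid of (EC50, n) starting points
    is refined by bounded least squares and the best local optimum returned.
    """

    def __init__(self, n_bounds=(0.1, 10.0), ec50_bounds_factor=100.0):
        self.n_bounds = n_bounds
        self.ec50_bounds_factor = ec50_bounds_factor

    @staticmethod
    def _hill(c, ymax, ec50, n):
        c = np.asarray(c, dtype=float)
        with np.errstate(divide="ignore"):
            r = np.where(c > 0, c**n / (ec50**n + c**n), 0.0)
        return ymax * r

    def fit(self, X, y):
        """Fit to doses ``X`` (1d or column vector) and responses ``y``.

        Replicate measurements appear as repeated doses; all points are
        weighted equally.
        """
        c = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if c.shape != y.shape:
            raise ValueError("doses and responses must have equal length")
        pos = c > 0
        if np.unique(c[pos]).size < 4:
            raise ValueError("need at least 4 distinct nonzero doses")
        if not np.any(y > 0):
            self.ymax_, self.ec50_, self.hill_ = 0.0, float(np.median(c[pos])), 1.0
            self.rss_ = float(np.sum(y**2))
            self.non_activator_ = True
            return self
        self.non_activator_ = False
        f = self.ec50_bounds_factor
        ec50_lo, ec50_hi = c[pos].min() / f, c[pos].max() * f
        n_lo, n_hi = self.n_bounds
        ymax0 = float(np.max(y))
        best = None
        for ec50_0 in np.geomspace(c[pos].min(), c[pos].max(), 3):
            for n0 in (0.5, 1.0, 2.0):
                sol = least_squares(
                    lambda p: self._hill(c, p[0], np.exp(p[1]), p[2]) - y,
                    x0=[ymax0, np.log(ec50_0), n0],
                    bounds=([0.0, np.log(ec50_lo), n_lo],
                            [np.inf, np.log(ec50_hi), n_hi]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                rss = float(np.sum(sol.fun**2))
                if best is None or rss < best[0]:
                    best = (rss, sol.x)
        self.rss_ = best[0]
        self.ymax_ = float(best[1][0])
        self.ec50_ = float(np.exp(best[1][1]))
        self.hill_ = float(best[1][2])
        return self

    def predict(self, X):
        return self._hill(np.asarray(X, dtype=float).ravel(),
                          self.ymax_, self.ec50_, self.hill_)


def fit_hill(doses, responses, **kwargs) -> HillCurve:
    """Functional wrapper over :class:`HillCurve`."""
    return HillCurve(**kwargs).fit(doses, responses)


def relative_ligand_strength(top_dose_responses: dict[str, np.ndarray]) -> pd.Series:
    """RLS per ligand: median top-dose response over the strongest ligand's.

    Negative medians are clipped to zero, so RLS lies in [0, 1] with the
    strongest ligand at exactly 1.
    """
    if not top_dose_responses:
        raise ValueError("no ligands supplied")
    med = {
        lig: max(float(np.median(np.asarray(v, dtype=float))), 0.0)
        for lig, v in top_dose_responses.items()
    }
    top = max(med.values())
    if top == 0.0:
        return pd.Series({lig: 0.0 for lig in med}, name="rls")
    return pd.Series({lig: m / top for lig, m in med.items()}, name="rls")
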