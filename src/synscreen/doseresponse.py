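"""Monotherapy dose-response fitting under a three-parameter Hill model.

The model is the zero-bottom Hill (log-logistic) curve

    y(d) = emax * d**H / (ec50**H + d**H)

with ``y`` fractional inhibition (0 = vehicle, 1 = complete inhibition),
``d`` dose in µM, ``emax`` the efficacy ceiling, ``ec50`` the *relative*
EC50 (curve midpoint) and ``H`` the Hill slope.  The bottom asymptote is
pinned at zero, matching how normalized viability screens are fit in
practice: a well with no drug shows no inhibition by construction.

Two IC50 notions coexist for partial-efficacy curves and are both exposed:
the relative IC50 equals ``ec50`` (half of the fitted span), while the
absolute IC50 is the dose at which the curve crosses 50% inhibition of
control, ``ec50 * (0.5 / (emax - 0.5))**(1/H)``, undefined when the ceiling
never reaches 50%.

EC_F, the dose achieving F% of the fitted span, follows from the Hill
algebra: ``EC_F = (F / (100 - F))**(1/H) * ec50``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DoseResponsePoint",
    "HillFit",
    "HillCurve",
    "UnfittableCurveError",
    "fit_hill",
    "hill",
    "predict",
    "ec_f",
    "absolute_ic50",
    "invert_effect",
]

#: Default fitting bounds: (emax, ec50 in µM, Hill slope).
DEFAULT_BOUNDS = ((1e-6, 1.2), (1e-6, 1e3), (0.1, 10.0))


class UnfittableCurveError(ValueError):
    """Raised when a monotherapy curve cannot be fit (too few points,
    constant response, or optimizer failure)."""

    def __init__(self, message: str, compound: str | None = None):
        if compound is not None:
            message = f"{compound}: {message}"
        super().__init__(message)
        self.compound = compound


@dataclasses.dataclass(frozen=True)
class DoseResponsePoint:
    """One (dose, response) observation; dose in µM, response as
    fractional inhibition."""

    dose: float
    response: float

    def __post_init__(self):
        if not math.isfinite(self.dose) or self.dose < 0:
            raise ValueError(f"dose must be finite and non-negative, got {self.dose}")
        if not math.isfinite(self.response):
            raise ValueError(f"response must be finite, got {self.response}")


@dataclasses.dataclass(frozen=True)
class HillFit:
    """A fitted zero-bottom Hill curve.

    Attributes
    ----------
    emax : float
        Fractional-inhibition ceiling, in (0, 1.2].
    ec50_rel : float
        Relative EC50 (curve midpoint) in µM.
    hill_slope : float
        Hill coefficient H > 0.
    rss : float
        Residual sum of squares of the fit.
    n_points : int
        Number of points used.
    """

    emax: float
    ec50_rel: float
    hill_slope: float
    rss: float = float("nan")
    n_points: int = 0

    def predict(self, dose):
        return hill(dose, self.emax, self.ec50_rel, self.hill_slope)


def hill(dose, emax, ec50, h):
    """Zero-bottom Hill curve y(d) = emax * d^H / (ec50^H + d^H).

    Vectorized over ``dose``; y(0) = 0 exactly.
    """
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        r = (d / ec50) ** h
    out = emax * r / (1.0 + r)
    out = np.where(d == 0, 0.0, out)
    return out if out.ndim else float(out)


def predict(fit: HillFit, dose):
    """Fitted inhibition at ``dose`` (µM)."""
    return fit.predict(dose)


class HillCurve(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for the three-parameter zero-bottom Hill curve.

    Parameters
    ----------
    bounds : tuple of pairs, default DEFAULT_BOUNDS
        ((emax_lo, emax_hi), (ec50_lo, ec50_hi), (h_lo, h_hi)); ec50 bounds
        in µM.  Curves from viability screens are bounded to keep
        low-efficacy and biphasic data identifiable.
    n_starts : int, default 5
        Deterministic multi-start count; EC50 initial values are placed at
        quantiles of the nonzero doses.

    Attributes
    ----------
    emax_ : float
        Fitted efficacy ceiling.
    ec50_ : float
        Fitted relative EC50 (µM).
    hill_slope_ : float
        Fitted Hill coefficient.
    rss_ : float
        Residual sum of squares.
    n_points_ : int
        Number of observations fit.

    Examples
    --------
    >>> d = np.array([0.01, 0.1, 0.3, 1.0, 3.0, 10.0])
    >>> y = hill(d, 1.0, 1.0, 1.0)
    >>> HillCurve().fit(d, y).ec50_
    1.0...
    """

    def __init__(self, bounds=DEFAULT_BOUNDS, n_starts=5):
        self.bounds = bounds
        self.n_starts = n_starts

    def fit(self, X, y, compound: str | None = None):
        """Least-squares fit on the inhibition scale.

        X : array-like of doses in µM, shape (n,) or (n, 1)
        y : array-like of fractional inhibitions, shape (n,)
        """
        d = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if d.shape != y.shape:
            raise ValueError("dose and response arrays must have equal length")
        if not (np.isfinite(d).all() and np.isfinite(y).all()):
            raise UnfittableCurveError("non-finite dose or response", compound)
        if (d < 0).any():
            raise UnfittableCurveError("negative dose", compound)
        nonzero = np.unique(d[d > 0])
        if d.size < 4 or nonzero.size < 3:
            raise UnfittableCurveError(
                f"need >= 4 points with >= 3 distinct nonzero doses, "
                f"got {d.size} points / {nonzero.size} distinct nonzero doses",
                compound,
            )
        if np.ptp(y) <= 1e-12:
            raise UnfittableCurveError("constant response, curve unfittable", compound)

        (e_lo, e_hi), (c_lo, c_hi), (h_lo, h_hi) = self.bounds
        # optimize over (emax, log10 ec50, H); doses stay linear in the model
        lo = np.array([e_lo, math.log10(c_lo), h_lo])
        hi = np.array([e_hi, math.log10(c_hi), h_hi])

        def resid(p):
            return hill(d, p[0], 10.0 ** p[1], p[2]) - y

        emax0 = float(np.clip(np.max(y), max(e_lo, 0.05), e_hi))
        qs = np.linspace(0.1, 0.9, max(self.n_starts, 1))
        ec0s = np.quantile(nonzero, qs)
        best = None
        for ec0 in ec0s:
            x0 = np.clip(
                np.array([emax0, math.log10(ec0), 1.0]), lo + 1e-12, hi - 1e-12
            )
            sol = least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success and not np.isfinite(best.cost):
            raise UnfittableCurveError("optimizer failed to converge", compound)

        self.emax_ = float(best.x[0])
        self.ec50_ = float(10.0 ** best.x[1])
        self.hill_slope_ = float(best.x[2])
        self.rss_ = float(2.0 * best.cost)
        self.n_points_ = int(d.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "emax_")
        d = np.asarray(X, dtype=float).reshape(-1)
        return hill(d, self.emax_, self.ec50_, self.hill_slope_)

    def to_fit(self) -> HillFit:
        """The fitted curve as an immutable :class:`HillFit` record."""
        check_is_fitted(self, "emax_")
        return HillFit(
            emax=self.emax_,
            ec50_rel=self.ec50_,
            hill_slope=self.hill_slope_,
            rss=self.rss_,
            n_points=self.n_points_,
        )


def fit_hill(points, bounds=DEFAULT_BOUNDS, compound: str | None = None) -> HillFit:
    """Fit a zero-bottom Hill curve to (dose, response) points.

    ``points`` is an iterable of :class:`DoseResponsePoint` or (dose,
    response) pairs.  Deterministic given identical inputs and options.
    """
    d, y = [], []
    for p in points:
        if isinstance(p, DoseResponsePoint):
            d.append(p.dose)
            y.append(p.response)
        else:
            d.append(float(p[0]))
            y.append(float(p[1]))
    est = HillCurve(bounds=bounds).fit(np.array(d), np.array(y), compound=compound)
    return est.to_fit()


def ec_f(fit: HillFit, F: float) -> float:
    """Dose achieving F% of the fitted response span.

    EC_F = (F / (100 - F))**(1/H) * EC50; F must lie strictly in (0, 100).
    At F = 50 this is the relative EC50 exactly, for every Hill slope.
    """
    if not 0 < F < 100:
        raise ValueError(f"F must be in (0, 100), got {F}")
    return (F / (100.0 - F)) ** (1.0 / fit.hill_slope) * fit.ec50_rel


def absolute_ic50(fit: HillFit) -> float:
    """Dose at which fitted inhibition crosses 0.5 of control.

    Returns ``nan`` ("not reached") when the efficacy ceiling is at or
    below 50%; for a full-efficacy curve (emax = 1) this coincides with
    the relative EC50.
    """
    if fit.emax <= 0.5:
        return float("nan")
    return fit.ec50_rel * (0.5 / (fit.emax - 0.5)) ** (1.0 / fit.hill_slope)


def invert_effect(fit: HillFit, y: float) -> float:
    """Dose producing fractional inhibition ``y`` on the fitted curve.

    The inverse of the Hill curve: d = ec50 * (y / (emax - y))**(1/H),
    defined for 0 < y < emax.  Round-trips with :func:`predict`.
    """
    if not 0 < y < fit.emax:
        raise ValueError(f"y must be in (0, emax={fit.emax}), got {y}")
    return fit.ec50_rel * (y / (fit.emax - y)) ** (1.0 / fit.hill_slope)
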