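"""Dose-matrix synergy scoring with four reference models.

An 8x8 checkerboard matrix crosses 7 half-log doses of each drug (the
midpoint anchored at its IC50) plus a zero-dose level per axis, so the
first row and column are the monotherapy curves and cell (0, 0) is the
vehicle control.  For every off-axis cell the observed fractional
inhibition is compared against the expectation of a reference null model:

Bliss   expected = yA + yB - yA*yB          (probabilistic independence;
                                             observed monotherapy axes)
HSA     expected = max(yA, yB)              (best single agent; observed axes)
Loewe   expected y* solves dA/DA(y*) + dB/DB(y*) = 1, with DA, DB the
        inverse fitted monotherapy curves (dose additivity)
ZIP     expected from conditional Hill fits along each row and column with
        the partner's fitted effect as a fixed baseline; the deviation is
        taken from the Bliss combination of the *fitted* marginals, so an
        unchanged potency scores exactly zero

The deviation matrix delta (fractional scale) is summarized as an overall
score (100 x mean over off-axis cells), a Most Synergistic Area (the 3x3
window with the highest mean delta), and a Combination Sensitivity Score
(normalized area under each drug's curve when titrated at the partner's
IC50, averaged over both directions).  A pair is called synergistic only
when every model's score clears +tau (default 5 on the percent scale),
antagonistic when all fall below -tau, additive otherwise.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
from scipy.optimize import brentq, least_squares

from .doseresponse import HillFit, UnfittableCurveError, fit_hill, hill, invert_effect

__all__ = [
    "DoseGrid",
    "ResponseSurface",
    "MSAResult",
    "SynergyScores",
    "design_matrix",
    "fit_axes",
    "delta_bliss",
    "delta_hsa",
    "delta_loewe",
    "delta_zip",
    "summarize_overall",
    "most_synergistic_area",
    "css",
    "classify_interaction",
    "score_surface",
]

HALF_LOG = math.sqrt(10.0)


@dataclasses.dataclass(frozen=True)
class DoseGrid:
    """Per-axis dose levels in µM: a zero level first, then 7 nonzero
    doses in half-log geometric progression."""

    doses_a: tuple[float, ...]
    doses_b: tuple[float, ...]

    def __post_init__(self):
        for name, ds in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            arr = np.asarray(ds, float)
            if arr[0] != 0.0 or (arr[1:] <= 0).any():
                raise ValueError(f"{name}: exactly one zero level, first")
            if not (np.diff(arr) > 0).all():
                raise ValueError(f"{name}: doses must be strictly increasing")
            ratios = arr[2:] / arr[1:-1]
            if not np.allclose(ratios, HALF_LOG, rtol=1e-6):
                raise ValueError(f"{name}: nonzero doses must step by half a log")


@dataclasses.dataclass(frozen=True)
class ResponseSurface:
    """Mean fractional inhibition on a dose grid; rows index drug A doses,
    columns drug B doses.  Cell (0, 0) is the vehicle control."""

    grid: DoseGrid
    inhibition: np.ndarray
    n_reps: int = 1

    def __post_init__(self):
        inh = np.asarray(self.inhibition, float)
        object.__setattr__(self, "inhibition", inh)
        na, nb = len(self.grid.doses_a), len(self.grid.doses_b)
        if inh.shape != (na, nb):
            raise ValueError(f"inhibition shape {inh.shape} != grid ({na}, {nb})")
        if not np.isfinite(inh).all():
            raise ValueError("non-finite inhibition values")
        if abs(inh[0, 0]) >= 0.1:
            raise ValueError(
                f"vehicle-control cell (0,0) should be ~0 after normalization, "
                f"got {inh[0, 0]:.3g}"
            )

    @property
    def y_a(self) -> np.ndarray:
        """Observed monotherapy inhibition for drug A (nonzero doses)."""
        return self.inhibition[1:, 0]

    @property
    def y_b(self) -> np.ndarray:
        """Observed monotherapy inhibition for drug B (nonzero doses)."""
        return self.inhibition[0, 1:]

    def transpose(self) -> "ResponseSurface":
        """Swap the drug roles (A <-> B)."""
        return ResponseSurface(
            grid=DoseGrid(self.grid.doses_b, self.grid.doses_a),
            inhibition=self.inhibition.T.copy(),
            n_reps=self.n_reps,
        )


@dataclasses.dataclass(frozen=True)
class MSAResult:
    """Top-left index (within the off-axis 7x7 delta matrix) and percent
    score of the most synergistic 3x3 window."""

    row: int
    col: int
    mean_delta: float


@dataclasses.dataclass(frozen=True)
class SynergyScores:
    """Full synergy report for one drug pair."""

    deltas: Mapping[str, np.ndarray]
    overall: Mapping[str, float]
    msa: Mapping[str, MSAResult]
    css: float
    label: str
    partial: bool = False


def design_matrix(ic50_a: float, ic50_b: float) -> DoseGrid:
    """Half-log 8x8 grid with each drug's IC50 at the center nonzero dose.

    Nonzero doses are ic50 * 10**(m/2) for m = -3..3, so the top:bottom
    nonzero ratio is 10^3; a zero-dose level is prepended on each axis.
    """
    if not (ic50_a > 0 and ic50_b > 0):
        raise ValueError(f"IC50s must be positive, got {ic50_a}, {ic50_b}")

    def axis(ic50):
        return (0.0,) + tuple(ic50 * 10.0 ** (m / 2.0) for m in range(-3, 4))

    return DoseGrid(axis(ic50_a), axis(ic50_b))


def fit_axes(surface: ResponseSurface) -> tuple[HillFit, HillFit]:
    """Fit the two monotherapy margins of a surface (zero-dose anchor
    included)."""
    da = np.asarray(surface.grid.doses_a)
    db = np.asarray(surface.grid.doses_b)
    fit_a = fit_hill(list(zip(da, surface.inhibition[:, 0])), compound="drug A axis")
    fit_b = fit_hill(list(zip(db, surface.inhibition[0, :])), compound="drug B axis")
    return fit_a, fit_b


def delta_bliss(surface: ResponseSurface) -> np.ndarray:
    """Deviation from Bliss independence, off-axis cells, using the
    observed monotherapy axes: y - (yA + yB - yA*yB)."""
    ya = surface.y_a[:, None]
    yb = surface.y_b[None, :]
    return surface.inhibition[1:, 1:] - (ya + yb - ya * yb)


def delta_hsa(surface: ResponseSurface) -> np.ndarray:
    """Deviation from the highest single agent: y - max(yA, yB), with
    observed axes."""
    ya = surface.y_a[:, None]
    yb = surface.y_b[None, :]
    return surface.inhibition[1:, 1:] - np.maximum(ya, yb)


def delta_loewe(
    surface: ResponseSurface, fit_a: HillFit, fit_b: HillFit, tol: float = 1e-9
) -> np.ndarray:
    """Deviation from Loewe dose additivity.

    For each off-axis cell (dA, dB) the expected effect y* solves the
    additivity equation dA/DA(y*) + dB/DB(y*) = 1, where DA, DB invert the
    fitted monotherapy curves; solved by bracketed root-finding on
    (0, min(emaxA, emaxB)).  Cells whose doses exceed both curves' reach
    (no sign change in the bracket) are flagged as NaN.

    A drug combined with itself ("sham" combination) satisfies additivity
    exactly, so its delta is identically zero.
    """
    y_max = min(fit_a.emax, fit_b.emax)
    eps = 1e-12
    lo, hi = eps, y_max - eps
    out = np.empty((7, 7))
    for i, da in enumerate(surface.grid.doses_a[1:]):
        for j, db in enumerate(surface.grid.doses_b[1:]):

            def g(y):
                return da / invert_effect(fit_a, y) + db / invert_effect(fit_b, y) - 1.0

            glo, ghi = g(lo), g(hi)
            if glo == 0.0:
                y_star = lo
            elif ghi == 0.0:
                y_star = hi
            elif np.sign(glo) == np.sign(ghi):
                out[i, j] = np.nan  # flagged: no root within the curves' reach
                continue
            else:
                y_star = brentq(g, lo, hi, xtol=min(tol, 1e-12))
            out[i, j] = surface.inhibition[1 + i, 1 + j] - y_star
    return out


def _fit_conditional(doses, y, baseline, emax, ec50_init, h_init, bounds):
    """Fit y = baseline + (1 - baseline) * Hill(d; emax fixed, ec50, h).

    Returns fitted values at ``doses``; raises on degenerate input.
    """
    d = np.asarray(doses, float)
    y = np.asarray(y, float)
    scaled = (y - baseline) / (1.0 - baseline)
    if np.ptp(scaled) <= 1e-12:
        raise UnfittableCurveError("constant conditional response")
    (_, _), (c_lo, c_hi), (h_lo, h_hi) = bounds
    lo = np.array([math.log10(c_lo), h_lo])
    hi = np.array([math.log10(c_hi), h_hi])

    def resid(p):
        return hill(d, emax, 10.0 ** p[0], p[1]) - scaled

    x0 = np.clip(
        np.array([math.log10(ec50_init), h_init]), lo + 1e-12, hi - 1e-12
    )
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    fitted = hill(d, emax, 10.0 ** sol.x[0], sol.x[1])
    return baseline + (1.0 - baseline) * fitted


def delta_zip(
    surface: ResponseSurface, fit_a: HillFit, fit_b: HillFit
) -> np.ndarray:
    """Deviation under the zero-interaction-potency construction.

    Along each off-axis row and column a conditional Hill curve is fit with
    the partner's fitted marginal effect as a fixed baseline (only EC50 and
    slope refit; the ceiling stays at the marginal's).  Each cell's fitted
    effect is the mean of its row- and column-conditional predictions, and
    delta is that mean minus the Bliss combination of the *fitted*
    marginals — so a surface whose potencies are unchanged by the partner
    scores exactly zero.  A conditional fit that fails falls back to the
    observed values along its line.
    """
    da = np.asarray(surface.grid.doses_a[1:])
    db = np.asarray(surface.grid.doses_b[1:])
    if len(da) < 4 or len(db) < 4:
        raise ValueError("ZIP needs >= 4 cells per off-axis row and column")
    yhat_a = fit_a.predict(da)  # fitted marginal of A at its 7 doses
    yhat_b = fit_b.predict(db)
    obs = surface.inhibition[1:, 1:]
    from .doseresponse import DEFAULT_BOUNDS

    # conditional along rows (A titrated at fixed B dose j)
    pred_rows = np.empty((7, 7))
    for j in range(7):
        base = min(float(yhat_b[j]), 0.99)
        try:
            pred_rows[:, j] = _fit_conditional(
                da, obs[:, j], base, fit_a.emax, fit_a.ec50_rel,
                fit_a.hill_slope, DEFAULT_BOUNDS,
            )
        except (UnfittableCurveError, ValueError):
            pred_rows[:, j] = obs[:, j]
    # conditional along columns (B titrated at fixed A dose i)
    pred_cols = np.empty((7, 7))
    for i in range(7):
        base = min(float(yhat_a[i]), 0.99)
        try:
            pred_cols[i, :] = _fit_conditional(
                db, obs[i, :], base, fit_b.emax, fit_b.ec50_rel,
                fit_b.hill_slope, DEFAULT_BOUNDS,
            )
        except (UnfittableCurveError, ValueError):
            pred_cols[i, :] = obs[i, :]

    fitted_effect = 0.5 * (pred_rows + pred_cols)
    null = yhat_a[:, None] + yhat_b[None, :] - yhat_a[:, None] * yhat_b[None, :]
    return fitted_effect - null


def summarize_overall(delta: np.ndarray) -> float:
    """Overall delta score: 100 x mean of the off-axis delta cells;
    flagged (NaN) cells are excluded; NaN if every cell is flagged."""
    delta = np.asarray(delta, float)
    if np.isnan(delta).all():
        return float("nan")
    return 100.0 * float(np.nanmean(delta))


def most_synergistic_area(delta: np.ndarray) -> MSAResult:
    """Exhaustive scan for the 3x3 window with the highest mean delta.

    Ties break toward the smallest (row, col).  Windows that are entirely
    flagged are skipped; partially flagged windows average their valid
    cells.
    """
    delta = np.asarray(delta, float)
    nr, nc = delta.shape
    if nr < 3 or nc < 3:
        raise ValueError("delta matrix must be at least 3x3")
    best = None
    for r in range(nr - 2):
        for c in range(nc - 2):
            win = delta[r : r + 3, c : c + 3]
            if np.isnan(win).all():
                continue
            score = 100.0 * float(np.nanmean(win))
            if best is None or score > best.mean_delta:
                best = MSAResult(row=r, col=c, mean_delta=score)
    if best is None:
        return MSAResult(row=0, col=0, mean_delta=float("nan"))
    return best


def css(surface: ResponseSurface, fit_a: HillFit, fit_b: HillFit) -> float:
    """Combination Sensitivity Score.

    For each direction, take the grid line where the partner sits at its
    nonzero dose nearest to its IC50 (relative EC50), integrate the
    observed inhibition over log10(dose) along that line by the trapezoid
    rule, normalize by the area of constant full inhibition over the same
    span, and express as percent; CSS is the mean of the two directions.
    An IC50 outside the tested range falls back to the nearest edge line.
    """
    da = np.asarray(surface.grid.doses_a[1:])
    db = np.asarray(surface.grid.doses_b[1:])

    def auc_pct(doses, values):
        lx = np.log10(doses)
        span = lx[-1] - lx[0]
        return 100.0 * float(np.trapezoid(values, lx)) / span

    j_star = int(np.argmin(np.abs(np.log10(db) - math.log10(fit_b.ec50_rel))))
    i_star = int(np.argmin(np.abs(np.log10(da) - math.log10(fit_a.ec50_rel))))
    css_a = auc_pct(da, surface.inhibition[1:, 1 + j_star])  # A titrated at B's IC50
    css_b = auc_pct(db, surface.inhibition[1 + i_star, 1:])  # B titrated at A's IC50
    return 0.5 * (css_a + css_b)


def classify_interaction(scores: Mapping[str, float], tau: float = 5.0) -> str:
    """Strict cross-model call: synergistic iff every model's score > tau,
    antagonistic iff every score < -tau, additive otherwise.  Models with
    NaN scores (e.g. Loewe unavailable) are dropped from the rule."""
    vals = [v for v in scores.values() if not math.isnan(v)]
    if not vals:
        return "additive"
    if all(v > tau for v in vals):
        return "synergistic"
    if all(v < -tau for v in vals):
        return "antagonistic"
    return "additive"


def score_surface(
    surface: ResponseSurface,
    fit_a: HillFit | None = None,
    fit_b: HillFit | None = None,
    tau: float = 5.0,
) -> SynergyScores:
    """Score one dose-matrix with all four reference models.

    Marginal fits are derived from the surface's own axes when not given.
    If a margin cannot be fit, Loewe and ZIP are reported as unavailable
    (NaN) and the classification is flagged partial.
    """
    partial = False
    if fit_a is None or fit_b is None:
        try:
            fit_a, fit_b = fit_axes(surface)
        except UnfittableCurveError:
            fit_a = fit_b = None
            partial = True

    deltas: dict[str, np.ndarray] = {
        "bliss": delta_bliss(surface),
        "hsa": delta_hsa(surface),
    }
    nan7 = np.full((7, 7), np.nan)
    if fit_a is not None and fit_b is not None:
        deltas["loewe"] = delta_loewe(surface, fit_a, fit_b)
        deltas["zip"] = delta_zip(surface, fit_a, fit_b)
        css_val = css(surface, fit_a, fit_b)
    else:
        deltas["loewe"] = nan7
        deltas["zip"] = nan7
        css_val = float("nan")

    overall = {m: summarize_overall(d) for m, d in deltas.items()}
    msa = {m: most_synergistic_area(d) for m, d in deltas.items()}
    label = classify_interaction(overall, tau=tau)
    return SynergyScores(
        deltas=deltas, overall=overall, msa=msa, css=css_val,
        label=label, partial=partial,
    )
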