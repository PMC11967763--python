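"""Dose-response curve fitting, normalized AUC and sensitivity stratification.

Viability (percent of vehicle) versus log10 concentration is fit with the
fixed-slope normalized-response log-logistic family

    Y(X) = 100 / (1 + 10**(X - logIC50)),    X = log10(concentration [M])

i.e. top = 100, bottom = 0, unit Hill slope, with logIC50 the single free
parameter.  A variable-slope variant (free Hill coefficient) is available
behind a flag.

Normalized AUC is defined as the mean normalized viability over the tested
log-concentration window: the trapezoidal area of viability (clipped to
[0, 100]) over [Xmin, Xmax], divided by 100 * (Xmax - Xmin).  It lies in
[0, 1]; 0.5 is the "half-maximal average viability" boundary.  Samples with
normalized AUC < 0.5 are classified sensitive, >= 0.5 resistant.  By default
the AUC integrates the observed points (replicates averaged per
concentration); integrating the fitted curve is optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .concordance import InsufficientDataError
from .screen import DegenerateVehicleError

__all__ = [
    "DoseResponseFit",
    "normalize_viability",
    "logistic_response",
    "fit_curve",
    "normalized_auc",
    "classify_response",
    "combination_curve",
]


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a log(inhibitor)-vs-normalized-response fit."""

    logIC50: float
    hill: float  # 1.0 in the fixed-slope family
    sse: float
    converged: bool
    family: str  # "fixed_slope" or "variable_slope"
    n_points: int
    message: str = ""

    @property
    def ic50(self) -> float:
        return 10.0 ** self.logIC50

    def predict(self, log10_conc: np.ndarray) -> np.ndarray:
        return logistic_response(np.asarray(log10_conc, float), self.logIC50, self.hill)


def normalize_viability(raw: Sequence[float], vehicle_mean: float) -> np.ndarray:
    """Percent-of-vehicle viability: 100 * raw / vehicle_mean."""
    if vehicle_mean <= 0:
        raise DegenerateVehicleError(f"vehicle mean must be > 0, got {vehicle_mean}")
    return 100.0 * np.asarray(raw, dtype=float) / vehicle_mean


def logistic_response(x: np.ndarray, logic50: float, hill: float = 1.0) -> np.ndarray:
    """Normalized-response curve Y = 100 / (1 + 10**(hill * (X - logIC50)))."""
    return 100.0 / (1.0 + 10.0 ** (hill * (x - logic50)))


def _prepare(points: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not {"concentration", "viability"} <= set(points.columns):
        raise ValueError("points need 'concentration' and 'viability' columns")
    conc = points["concentration"].to_numpy(float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0 (molar)")
    return np.log10(conc), points["viability"].to_numpy(float)


def fit_curve(
    points: pd.DataFrame, variable_slope: bool = False
) -> DoseResponseFit:
    """Least-squares fit of the normalized-response family to (conc, viability).

    Requires >= 4 points at >= 3 distinct concentrations.  The fixed-slope fit
    is a one-parameter problem solved by a coarse grid over the tested range
    extended by 2 logs, refined with bounded scalar minimization; the
    variable-slope fit adds a free Hill coefficient and uses ``curve_fit``
    started from the fixed-slope solution.
    """
    x, y = _prepare(points)
    if x.size < 4 or np.unique(x).size < 3:
        raise InsufficientDataError(
            "need >=4 points at >=3 distinct concentrations to fit a curve"
        )

    def sse(l50: float) -> float:
        r = y - logistic_response(x, l50)
        return float(r @ r)

    lo, hi = x.min() - 2.0, x.max() + 2.0
    grid = np.linspace(lo, hi, 241)
    best = grid[int(np.argmin([sse(g) for g in grid]))]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        sse,
        bounds=(max(lo, best - 2 * step), min(hi, best + 2 * step)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    l50, best_sse, ok = float(res.x), float(res.fun), bool(res.success)
    hill = 1.0
    family = "fixed_slope"
    message = "" if ok else str(res.message)

    if variable_slope:
        family = "variable_slope"
        try:
            popt, _ = optimize.curve_fit(
                lambda xx, l, h: logistic_response(xx, l, h),
                x, y, p0=[l50, 1.0], maxfev=10000,
            )
            l50, hill = float(popt[0]), float(popt[1])
            r = y - logistic_response(x, l50, hill)
            best_sse, ok, message = float(r @ r), True, ""
        except RuntimeError as e:  # no convergence: keep fixed-slope fallback
            ok, message = False, str(e)

    return DoseResponseFit(
        logIC50=l50, hill=hill, sse=best_sse, converged=ok,
        family=family, n_points=int(x.size), message=message,
    )


def normalized_auc(
    points: Optional[pd.DataFrame] = None,
    fit: Optional[DoseResponseFit] = None,
    x_range: Optional[tuple[float, float]] = None,
    n_curve_points: int = 256,
) -> float:
    """Mean normalized viability over the tested log-concentration window.

    Trapezoidal area of viability over X in [Xmin, Xmax] divided by
    100 * (Xmax - Xmin), with viability clipped to [0, 100]; result in [0, 1].
    From observed points (replicates averaged per concentration) when
    ``points`` is given, else from the fitted curve sampled densely.
    """
    if points is not None:
        x, y = _prepare(points)
        df = pd.DataFrame({"x": x, "y": y}).groupby("x", sort=True)["y"].mean()
        xs, ys = df.index.to_numpy(), df.to_numpy()
        if x_range is not None:
            lo, hi = x_range
            keep = (xs >= lo) & (xs <= hi)
            xs, ys = xs[keep], ys[keep]
    elif fit is not None:
        if x_range is None:
            raise ValueError("x_range is required when integrating a fitted curve")
        xs = np.linspace(x_range[0], x_range[1], n_curve_points)
        ys = fit.predict(xs)
    else:
        raise ValueError("provide points or a fit")
    if xs.size < 2:
        raise InsufficientDataError("normalized AUC needs >=2 distinct concentrations")
    ys = np.clip(ys, 0.0, 100.0)
    width = xs[-1] - xs[0]
    return float(np.trapezoid(ys, xs) / (100.0 * width))


def classify_response(auc_norm: float) -> str:
    """'sensitive' when normalized AUC < 0.5, 'resistant' when >= 0.5."""
    if not (0.0 <= auc_norm <= 1.0):
        raise ValueError(f"normalized AUC must be in [0,1], got {auc_norm}")
    return "sensitive" if auc_norm < 0.5 else "resistant"


def combination_curve(
    points: pd.DataFrame, rel_tol: float = 1e-6, variable_slope: bool = False
) -> DoseResponseFit:
    """Fit a fixed-ratio two-drug combination as a single agent.

    ``points`` carries ``concentration_a``/``concentration_b`` columns for the
    two components plus ``viability``; the a:b ratio must be constant across
    the dilution series (within ``rel_tol``).  The series is then fit on the
    component-a concentration axis with the same machinery as a single drug.
    """
    need = {"concentration_a", "concentration_b", "viability"}
    if not need <= set(points.columns):
        raise ValueError(f"combination points need columns {sorted(need)}")
    ca = points["concentration_a"].to_numpy(float)
    cb = points["concentration_b"].to_numpy(float)
    if np.any(ca <= 0) or np.any(cb <= 0):
        raise ValueError("combination concentrations must be > 0")
    ratio = cb / ca
    if np.ptp(ratio) > rel_tol * np.abs(ratio).max():
        raise ValueError("combination series is not a fixed-ratio dilution")
    single = points.rename(columns={"concentration_a": "concentration"})
    return fit_curve(single[["concentration", "viability"]], variable_slope)
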