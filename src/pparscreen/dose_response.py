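"""Hill-model fitting: EC50 from dose-response data, and the shared engine
for apparent-Kd estimation from thermal-shift and fluorescence-quench series.

Model (four-parameter logistic on concentration, "Hill1" form)::

    y(x) = START + (END - START) * x**n / (k**n + x**n)

with baseline START = y(0), plateau END = y(inf), half-transition
concentration k (EC50 or Kd_app) and Hill coefficient n > 0.  Fitting is
nonlinear least squares over (START, END, log10 k, log n); the log
parameterization enforces positivity of k and n, and multi-start
initialization (k from the geometric mean of the design and from the
half-range response crossing; n in {0.5, 1, 2}) guards against local minima.
Standard errors are asymptotic (delta method for k and n); R^2 is
1 - SSres/SStot on the fitted scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["BindingFit", "FitError", "hill1", "fit_hill", "fit_dose_response", "ec50_report"]

Direction = Literal["increasing", "decreasing"]


class FitError(RuntimeError):
    """Raised when a Hill fit cannot be performed; carries the best residual."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass
class BindingFit:
    """A converged Hill fit; ``k`` is EC50 or Kd_app depending on the assay."""

    model: str  # hill_increasing | hill_decreasing
    start: float
    end: float
    k: float
    n: float
    r_squared: float
    k_se: float | None = None
    n_se: float | None = None
    start_se: float | None = None
    end_se: float | None = None
    residual_ss: float = 0.0
    n_points: int = 0
    conc_unit: str | None = None

    @property
    def amplitude(self) -> float:
        return self.end - self.start

    def predict(self, x):
        return hill1(x, self.start, self.end, self.k, self.n)


def hill1(x, start: float, end: float, k: float, n: float):
    """Evaluate the Hill model; accepts scalars or arrays, x >= 0."""
    x = np.asarray(x, dtype=float)
    if k <= 0 or n <= 0:
        raise ValueError("k and n must be positive")
    frac = np.zeros_like(x)
    pos = x > 0
    # 1 / (1 + (k/x)^n), computed in log space for numeric range safety
    frac[pos] = 1.0 / (1.0 + np.exp(n * (np.log(k) - np.log(x[pos]))))
    out = start + (end - start) * frac
    return float(out) if out.ndim == 0 else out


def _unpack(
    params: np.ndarray, fix_start: float | None, fix_n: float | None
) -> tuple[float, float, float, float]:
    p = list(params)
    start = fix_start if fix_start is not None else p.pop(0)
    end = p.pop(0)
    k = 10.0 ** p.pop(0)
    n = fix_n if fix_n is not None else math.exp(p.pop(0))
    return start, end, k, n


def _predict(
    params: np.ndarray,
    x: np.ndarray,
    fix_start: float | None,
    fix_n: float | None,
) -> np.ndarray:
    start, end, k, n = _unpack(params, fix_start, fix_n)
    return hill1(x, start, end, k, n)


def fit_hill(
    x: Sequence[float],
    y: Sequence[float],
    direction: Direction = "increasing",
    fix_start: float | None = None,
    fix_n: float | None = None,
    conc_unit: str | None = None,
) -> BindingFit:
    """Least-squares Hill fit of response ``y`` against concentration ``x``.

    ``x`` may include 0 (vehicle anchor for START).  ``fix_start`` pins the
    baseline (used by the thermal-shift Kd fit, where the shift at zero ligand
    is zero by construction); ``fix_n`` pins the Hill coefficient (single-site
    binding), appropriate for sparse titrations that cannot identify n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.any(x < 0) or not np.all(np.isfinite(y)):
        raise ValueError("concentrations must be >= 0 and responses finite")
    span = float(np.ptp(y))
    scale = max(1.0, float(np.max(np.abs(y))))
    if span <= 1e-12 * scale:
        raise FitError("no transition: all responses equal")

    xp = x[x > 0]
    if xp.size < 3:
        raise FitError("need at least 3 positive concentrations")

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # crude asymptote guesses from the design extremes
    lo_group = ys[: max(2, len(ys) // 5)]
    hi_group = ys[-max(2, len(ys) // 5):]
    y_lo, y_hi = float(np.mean(lo_group)), float(np.mean(hi_group))
    start0 = fix_start if fix_start is not None else y_lo
    end0 = y_hi if abs(y_hi - start0) > 1e-12 else start0 + span

    # k inits: geometric mean of the design; concentration at half-range crossing
    k_inits = [float(np.exp(np.mean(np.log(xp))))]
    half = 0.5 * (y_lo + y_hi)
    crossing = None
    for i in range(len(xs) - 1):
        lo, hi = sorted((ys[i], ys[i + 1]))
        if lo <= half <= hi and xs[i + 1] > 0:
            crossing = math.sqrt(max(xs[i], xs[i + 1] * 1e-3) * xs[i + 1])
            break
    if crossing:
        k_inits.append(crossing)

    log10x = np.log10(xp)
    bounds_lo = [-np.inf, log10x.min() - 3.0]
    bounds_hi = [np.inf, log10x.max() + 3.0]
    if fix_n is None:
        bounds_lo.append(math.log(0.05))
        bounds_hi.append(math.log(20.0))
    if fix_start is None:
        bounds_lo = [-np.inf] + bounds_lo
        bounds_hi = [np.inf] + bounds_hi

    best = None
    n_starts = (1.0,) if fix_n is not None else (0.5, 1.0, 2.0)
    for k0 in k_inits:
        for n0 in n_starts:
            p0 = [end0, math.log10(k0)]
            if fix_n is None:
                p0.append(math.log(n0))
            if fix_start is None:
                p0 = [start0] + p0
            try:
                res = least_squares(
                    lambda p: _predict(p, x, fix_start, fix_n) - y,
                    p0,
                    bounds=(bounds_lo, bounds_hi),
                    method="trf",
                )
            except Exception:
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise FitError("Hill fit failed to converge from all starts")

    params = best.x
    resid = best.fun
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    start, end, k, n = _unpack(params, fix_start, fix_n)

    # asymptotic covariance via the Jacobian at the optimum
    ses: list[float | None] = [None] * len(params)
    dof = len(x) - len(params)
    if dof > 0 and ss_res > 0:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.inv(jtj) * (ss_res / dof)
            ses = list(np.sqrt(np.clip(np.diag(cov), 0, None)))
        except np.linalg.LinAlgError:
            pass
    start_se = None if fix_start is not None else ses.pop(0)
    end_se = ses.pop(0)
    log10k_se = ses.pop(0)
    logn_se = None if fix_n is not None else ses.pop(0)
    k_se = k * math.log(10) * log10k_se if log10k_se is not None else None
    n_se = n * logn_se if logn_se is not None else None

    model = "hill_increasing" if end >= start else "hill_decreasing"
    return BindingFit(
        model=model,
        start=float(start),
        end=float(end),
        k=float(k),
        n=float(n),
        r_squared=r2,
        k_se=k_se,
        n_se=n_se,
        start_se=start_se,
        end_se=end_se,
        residual_ss=ss_res,
        n_points=len(x),
        conc_unit=conc_unit,
    )


def fit_dose_response(
    points: pd.DataFrame,
    direction: Direction = "increasing",
    normalize: bool = False,
    conc_unit: str | None = None,
) -> BindingFit:
    """Fit a transactivation dose-response curve; ``k`` is the EC50.

    ``points`` needs columns ``concentration`` and ``response`` (optional
    ``replicate``).  Requires >=5 distinct positive concentrations spanning at
    least 2 orders of magnitude; zero-concentration rows are kept as baseline
    anchors but excluded from the span check.  ``normalize=True`` rescales raw
    responses to [0, 1] between the minimum- and maximum-concentration means
    before fitting.
    """
    for col in ("concentration", "response"):
        if col not in points.columns:
            raise ValueError(f"points table missing column {col!r}")
    x = points["concentration"].to_numpy(dtype=float)
    y = points["response"].to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    distinct = np.unique(x[x > 0])
    if distinct.size < 5:
        raise ValueError(
            f"need >=5 distinct positive concentrations, got {distinct.size}"
        )
    span_decades = math.log10(distinct.max() / distinct.min())
    if span_decades < 2.0:
        raise ValueError(
            f"concentrations span {span_decades:.2f} decades; need >= 2"
        )
    if normalize:
        mu_lo = float(np.mean(y[x == x.min()]))
        mu_hi = float(np.mean(y[x == x.max()]))
        if mu_hi == mu_lo:
            raise FitError("no transition: normalization anchors equal")
        y = (y - mu_lo) / (mu_hi - mu_lo)
    if conc_unit is None and "conc_unit" in points.columns:
        units = set(points["conc_unit"].dropna().astype(str))
        conc_unit = units.pop() if len(units) == 1 else None
    return fit_hill(x, y, direction=direction, conc_unit=conc_unit)


_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def ec50_report(
    fits: Mapping[str, BindingFit], r2_floor: float = 0.9
) -> pd.DataFrame:
    """Tabulate per-ligand EC50s sorted ascending (most potent first).

    Molar-unit fits get an ``ec50_nM`` display column; fits whose R^2 falls
    below ``r2_floor`` are annotated low-quality.
    """
    rows = []
    for ligand, fit in fits.items():
        factor = _UNIT_TO_MOLAR.get(fit.conc_unit or "M")
        rows.append(
            {
                "ligand": ligand,
                "ec50": fit.k,
                "conc_unit": fit.conc_unit,
                "ec50_nM": fit.k * factor / 1e-9 if factor else None,
                "hill_n": fit.n,
                "r_squared": fit.r_squared,
                "low_quality": fit.r_squared < r2_floor,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("ec50", kind="stable")
        .reset_index(drop=True)
    )
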