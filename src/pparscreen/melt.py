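"""Thermal shift assay (differential scanning fluorimetry) analysis.

A melt curve is dye fluorescence versus temperature over a ramp (the standard
protocol here runs 9-89 degC at 1 degC/min).  Protein unfolding exposes
hydrophobic surface, the dye signal rises sigmoidally, and past the unfolding
transition aggregation makes the signal decay again.  The analysis chain is:

1. truncate the curve at its global fluorescence maximum (drops the
   aggregation decay);
2. fit a Boltzmann sigmoid
   ``F(T) = F_pre + (F_post - F_pre) / (1 + exp((Tm - T)/a))``
   initialized at the maximum of a smoothed dF/dT; a derivative-maximum
   estimate serves as an independent cross-check (the two must agree within
   0.5 degC for a curve to count as a real transition);
3. quality gates (amplitude, R^2 >= 0.95, Tm well inside the window) decide
   between ``status="ok"`` and ``status="no_transition"`` — flat or
   destabilized curves are a status, never an exception;
4. ligand-induced stabilization is the shift dTm = Tm(holo) - Tm(apo),
   classified against configurable thresholds (>= 5 degC stabilizer,
   >= 2 degC weak);
5. quantitative mode fits dTm versus ligand concentration with an increasing
   Hill model whose baseline is pinned at 0, yielding an apparent Kd.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .dose_response import BindingFit, FitError, fit_hill

__all__ = [
    "MeltCurve",
    "TmResult",
    "DeltaTm",
    "truncate_at_peak",
    "extract_tm",
    "tm_by_derivative",
    "delta_tm",
    "classify_stabilization",
    "fit_tsa_kd",
]


@dataclass
class MeltCurve:
    """One temperature-fluorescence trace for one condition/replicate."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    condition_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence lengths differ")
        if self.temperatures.size < 20:
            raise ValueError("melt curve needs >= 20 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not (
            np.all(np.isfinite(self.temperatures))
            and np.all(np.isfinite(self.fluorescence))
        ):
            raise ValueError("melt curve contains missing/non-finite values")


@dataclass
class TmResult:
    """Fitted melting temperature; ``status='no_transition'`` encodes ND."""

    status: Literal["ok", "no_transition"]
    tm: float | None = None
    tm_sd: float | None = None
    slope_a: float | None = None  # transition width (degC)
    amplitude: float | None = None
    r_squared: float | None = None
    condition_id: str = ""
    replicate: int = 0
    reason: str | None = None  # why a curve was declared no_transition

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class DeltaTm:
    """Holo-minus-apo melting-temperature shift and its classification."""

    value: float | None
    sd: float | None
    classification: Literal["stabilizer", "weak", "none", "ND"]


def truncate_at_peak(curve: MeltCurve) -> MeltCurve:
    """Keep points up to and including the global fluorescence maximum."""
    idx = int(np.argmax(curve.fluorescence))
    # bypass the >=20-point validation for degenerate truncations; extract_tm
    # turns those into a no_transition status
    out = MeltCurve.__new__(MeltCurve)
    out.temperatures = curve.temperatures[: idx + 1]
    out.fluorescence = curve.fluorescence[: idx + 1]
    out.condition_id = curve.condition_id
    out.replicate = curve.replicate
    return out


def _smoothed_derivative_peak(t: np.ndarray, f: np.ndarray) -> float | None:
    """Temperature of max dF/dT from a Savitzky-Golay smoothed derivative,
    refined by quadratic interpolation around the grid maximum."""
    if t.size < 7:
        return None
    window = min(11, t.size if t.size % 2 == 1 else t.size - 1)
    if window < 5:
        return None
    dt = float(np.median(np.diff(t)))
    df = savgol_filter(f, window_length=window, polyorder=3, deriv=1, delta=dt)
    i = int(np.argmax(df))
    if i == 0 or i == df.size - 1:
        return float(t[i])
    # parabola through the three points around the maximum
    y0, y1, y2 = df[i - 1], df[i], df[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(t[i] + shift * (t[i + 1] - t[i] if shift >= 0 else t[i] - t[i - 1]))


def tm_by_derivative(curve: MeltCurve, truncate: bool = True) -> float | None:
    """Model-free Tm estimate: location of the smoothed dF/dT maximum."""
    c = truncate_at_peak(curve) if truncate else curve
    return _smoothed_derivative_peak(c.temperatures, c.fluorescence)


def _boltzmann(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    f_pre, f_post, tm, log_a = params
    a = math.exp(log_a)
    z = np.clip((tm - t) / a, -500.0, 500.0)
    return f_pre + (f_post - f_pre) / (1.0 + np.exp(z))


def extract_tm(
    curve: MeltCurve,
    r2_min: float = 0.95,
    edge_margin: float = 2.0,
    method_agreement: float = 0.5,
) -> TmResult:
    """Boltzmann-fit melting temperature with quality gating.

    The curve is truncated at its peak, fitted, and accepted (``status="ok"``)
    only if the fit converged with positive amplitude, R^2 >= ``r2_min``, Tm at
    least ``edge_margin`` degC inside the truncated window, amplitude at least
    3x the pre-transition residual scale, and agreement with the model-free
    derivative estimate within ``method_agreement`` degC.  Anything else is
    ``status="no_transition"`` with a reason.
    """
    meta = dict(condition_id=curve.condition_id, replicate=curve.replicate)
    trunc = truncate_at_peak(curve)
    t, f = trunc.temperatures, trunc.fluorescence
    if t.size < 10:
        return TmResult(status="no_transition", reason="peak at curve start", **meta)
    span = float(np.ptp(f))
    if span <= 0:
        return TmResult(status="no_transition", reason="flat curve", **meta)

    tm0 = _smoothed_derivative_peak(t, f)
    if tm0 is None:
        tm0 = float(t[t.size // 2])
    n_edge = max(3, t.size // 10)
    p0 = np.array(
        [float(np.mean(f[:n_edge])), float(np.mean(f[-n_edge:])), tm0, math.log(1.5)]
    )
    try:
        res = least_squares(
            lambda p: _boltzmann(p, t) - f,
            p0,
            bounds=(
                [-np.inf, -np.inf, t[0] - 5.0, math.log(0.05)],
                [np.inf, np.inf, t[-1] + 5.0, math.log(20.0)],
            ),
            method="trf",
        )
    except Exception:
        return TmResult(status="no_transition", reason="fit failed", **meta)
    if not (res.success and np.all(np.isfinite(res.x))):
        return TmResult(status="no_transition", reason="fit failed", **meta)

    f_pre, f_post, tm, log_a = res.x
    a = math.exp(log_a)
    amplitude = f_post - f_pre
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((f - np.mean(f)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    # parametric SD of Tm from the asymptotic covariance
    tm_sd = None
    dof = t.size - 4
    if dof > 0 and ss_res > 0:
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac) * (ss_res / dof)
            tm_sd = float(math.sqrt(max(cov[2, 2], 0.0)))
        except np.linalg.LinAlgError:
            pass

    def reject(reason: str) -> TmResult:
        return TmResult(
            status="no_transition",
            tm=float(tm),
            tm_sd=tm_sd,
            slope_a=float(a),
            amplitude=float(amplitude),
            r_squared=r2,
            reason=reason,
            **meta,
        )

    if amplitude <= 0:
        return reject("non-positive amplitude")
    if r2 < r2_min:
        return reject(f"R^2 {r2:.3f} below {r2_min}")
    if not (t[0] + edge_margin <= tm <= t[-1] - edge_margin):
        return reject("Tm too close to window edge")
    pre_mask = t < tm - 3.0 * a
    if np.count_nonzero(pre_mask) >= 5:
        pre_resid = float(np.median(np.abs(res.fun[pre_mask])))
        if pre_resid > 0 and amplitude < 3.0 * pre_resid:
            return reject("amplitude below noise floor")
    tm_deriv = _smoothed_derivative_peak(t, f)
    if tm_deriv is not None and abs(tm_deriv - tm) > method_agreement:
        return reject(
            f"derivative Tm {tm_deriv:.2f} disagrees with fit {tm:.2f}"
        )
    return TmResult(
        status="ok",
        tm=float(tm),
        tm_sd=tm_sd,
        slope_a=float(a),
        amplitude=float(amplitude),
        r_squared=r2,
        **meta,
    )


def _aggregate(results: Sequence[TmResult]) -> TmResult:
    """Combine replicate TmResults: mean Tm, SD across replicates."""
    ok = [r for r in results if r.ok]
    if not ok:
        return TmResult(
            status="no_transition",
            condition_id=results[0].condition_id if results else "",
            reason="no replicate produced a transition",
        )
    tms = [r.tm for r in ok]
    sd = statistics.stdev(tms) if len(tms) > 1 else (ok[0].tm_sd or 0.0)
    return TmResult(
        status="ok",
        tm=statistics.fmean(tms),
        tm_sd=sd,
        slope_a=statistics.fmean([r.slope_a for r in ok]),
        amplitude=statistics.fmean([r.amplitude for r in ok]),
        r_squared=min(r.r_squared for r in ok),
        condition_id=ok[0].condition_id,
    )


def delta_tm(
    holo: TmResult | Sequence[TmResult],
    apo: TmResult | Sequence[TmResult],
    t_weak: float = 2.0,
    t_strong: float = 5.0,
) -> DeltaTm:
    """Tm shift holo - apo with quadrature SD and stabilization class.

    Sequences of replicate results are aggregated first (mean Tm, SD across
    replicates).  If either side has no transition the shift is ND.
    """
    h = _aggregate(list(holo)) if not isinstance(holo, TmResult) else holo
    a = _aggregate(list(apo)) if not isinstance(apo, TmResult) else apo
    if not (h.ok and a.ok):
        return DeltaTm(value=None, sd=None, classification="ND")
    value = h.tm - a.tm
    sd = None
    if h.tm_sd is not None and a.tm_sd is not None:
        sd = math.sqrt(h.tm_sd**2 + a.tm_sd**2)
    return DeltaTm(
        value=value,
        sd=sd,
        classification=classify_stabilization(value, t_weak, t_strong),
    )


def classify_stabilization(
    value: float | None, t_weak: float = 2.0, t_strong: float = 5.0
) -> Literal["stabilizer", "weak", "none", "ND"]:
    """Tiered call on a Tm shift: stabilizer / weak / none (ND if undefined)."""
    if value is None:
        return "ND"
    if value >= t_strong:
        return "stabilizer"
    if value >= t_weak:
        return "weak"
    return "none"


def fit_tsa_kd(
    series: Sequence[tuple[float, TmResult | Sequence[TmResult]]],
    apo: TmResult | Sequence[TmResult],
    conc_unit: str | None = None,
    fix_n: float | None = 1.0,
) -> BindingFit:
    """Apparent Kd from a quantitative thermal shift titration.

    ``series`` pairs ligand concentrations with the Tm result(s) at that
    concentration.  The shift dTm(c) = Tm(c) - Tm(apo) is fitted with an
    increasing Hill model whose baseline is fixed at 0; ``k`` is Kd_app.
    The Hill coefficient defaults to 1 (single-site binding) because the
    short titrations typical of this assay cannot identify it; pass
    ``fix_n=None`` to float it.  Needs >= 5 concentrations with a usable
    transition.
    """
    a = _aggregate(list(apo)) if not isinstance(apo, TmResult) else apo
    if not a.ok:
        raise ValueError("apo condition has no usable transition")
    conc, shifts = [], []
    for c, r in series:
        res = _aggregate(list(r)) if not isinstance(r, TmResult) else r
        if res.ok:
            conc.append(float(c))
            shifts.append(res.tm - a.tm)
    if len(conc) < 5:
        raise ValueError(
            f"need >= 5 concentrations with usable transitions, got {len(conc)}"
        )
    shifts_arr = np.asarray(shifts)
    if float(np.ptp(shifts_arr)) <= 1e-9 * max(1.0, float(np.max(np.abs(shifts_arr)))):
        raise FitError("no concentration dependence in the Tm shifts")
    return fit_hill(
        np.asarray(conc), shifts_arr, direction="increasing", fix_start=0.0,
        fix_n=fix_n, conc_unit=conc_unit,
    )
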