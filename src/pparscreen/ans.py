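"""ANS fluorescence-quenching binding analysis.

ANS (8-anilinonaphthalene-1-sulfonic acid) fluoresces strongly (~480 nm
emission, 380 nm excitation) when lodged in a hydrophobic protein pocket.  A
ligand that competes for the pocket displaces the probe and quenches the
signal, so the emission maximum versus ligand concentration falls as a
decreasing Hill curve whose midpoint is an apparent Kd.  A ligand that never
quenches (flat series) gets a ``no_displacement`` verdict: its Kd is not
determinable by this assay.

Intensities are normalized to the vehicle (no-ligand) spectrum before
fitting; the fitted Kd is invariant to this rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter

from .dose_response import BindingFit, FitError, fit_hill

__all__ = [
    "EmissionSpectrum",
    "QuenchPoint",
    "AnsFitResult",
    "emission_max",
    "build_quench_series",
    "fit_ans_kd",
]


@dataclass
class EmissionSpectrum:
    """Fluorescence emission scan at one ligand concentration."""

    wavelengths: np.ndarray  # nm, increasing, should cover 480 nm
    intensities: np.ndarray
    condition_id: str = ""
    concentration: float = 0.0
    conc_unit: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelength and intensity lengths differ")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if not (self.wavelengths[0] <= 480.0 <= self.wavelengths[-1]):
            raise ValueError("spectrum must cover 480 nm")


@dataclass
class QuenchPoint:
    """Peak-intensity readout at one concentration, vehicle-normalized."""

    concentration: float
    f_max: float
    f_norm: float
    conc_unit: str | None = None


@dataclass
class AnsFitResult:
    """Either a Kd_app fit or a no-displacement verdict."""

    displaced: bool
    fit: BindingFit | None = None

    @property
    def verdict(self) -> str:
        return "kd_determined" if self.displaced else "no_displacement"


def emission_max(
    spectrum: EmissionSpectrum,
    smooth_window: int = 5,
    expected_nm: float = 480.0,
    shift_tolerance_nm: float = 15.0,
) -> tuple[float, float]:
    """Peak (wavelength, intensity) after a moving-median smoothing pass.

    Ties break to the lower wavelength.  A peak further than
    ``shift_tolerance_nm`` from the expected 480 nm band raises a warning
    (spectral shifts can indicate scattering or inner-filter artifacts).
    """
    if not np.any(spectrum.intensities > 0):
        raise ValueError("all-zero spectrum: no emission signal")
    smoothed = median_filter(spectrum.intensities, size=smooth_window, mode="nearest")
    # median smoothing plateaus a smooth band's crest: break ties between
    # equal smoothed maxima by raw intensity, then by lower wavelength
    peak = float(smoothed.max())
    ties = np.flatnonzero(smoothed >= peak * (1.0 - 1e-12))
    idx = int(ties[np.argmax(spectrum.intensities[ties])])
    wl = float(spectrum.wavelengths[idx])
    if abs(wl - expected_nm) > shift_tolerance_nm:
        warnings.warn(
            f"emission maximum at {wl:.0f} nm deviates from the expected "
            f"{expected_nm:.0f} nm band ({spectrum.condition_id or 'spectrum'})",
            stacklevel=2,
        )
    return wl, float(smoothed[idx])


def build_quench_series(
    spectra: Sequence[EmissionSpectrum],
    vehicle_id: str,
    min_points: int = 5,
    smooth_window: int = 5,
) -> list[QuenchPoint]:
    """Vehicle-normalized peak intensities, sorted by concentration.

    The vehicle spectrum anchors f_norm = 1; at least ``min_points`` ligand
    concentrations are required for a meaningful fit downstream.
    """
    vehicle = [s for s in spectra if s.condition_id == vehicle_id]
    if not vehicle:
        raise ValueError(f"vehicle spectrum {vehicle_id!r} not found")
    f_vehicle = float(
        np.mean([emission_max(v, smooth_window)[1] for v in vehicle])
    )
    if f_vehicle <= 0:
        raise ValueError("vehicle spectrum has no signal at the emission maximum")
    ligand = [s for s in spectra if s.condition_id != vehicle_id]
    by_conc: dict[float, list[EmissionSpectrum]] = {}
    for s in ligand:
        by_conc.setdefault(float(s.concentration), []).append(s)
    if len(by_conc) < min_points:
        raise ValueError(
            f"need >= {min_points} ligand concentrations, got {len(by_conc)}"
        )
    points = []
    for conc, reps in by_conc.items():
        # replicate spectra at one concentration enter as their mean peak
        f_max = float(np.mean([emission_max(s, smooth_window)[1] for s in reps]))
        points.append(
            QuenchPoint(
                concentration=conc,
                f_max=f_max,
                f_norm=f_max / f_vehicle,
                conc_unit=reps[0].conc_unit,
            )
        )
    points.append(
        QuenchPoint(
            concentration=vehicle[0].concentration,
            f_max=f_vehicle,
            f_norm=1.0,
            conc_unit=vehicle[0].conc_unit,
        )
    )
    return sorted(points, key=lambda p: p.concentration)


def fit_ans_kd(
    series: Sequence[QuenchPoint], quench_floor: float = 0.1
) -> AnsFitResult:
    """Decreasing Hill fit of f_norm versus concentration; ``k`` is Kd_app.

    If the fitted quench amplitude (START - END) falls below ``quench_floor``
    — or the series is flat — the ligand did not displace the probe and the
    result is a ``no_displacement`` verdict rather than a Kd.
    """
    x = np.array([p.concentration for p in series], dtype=float)
    y = np.array([p.f_norm for p in series], dtype=float)
    units = {p.conc_unit for p in series if p.conc_unit}
    unit = units.pop() if len(units) == 1 else None
    try:
        fit = fit_hill(x, y, direction="decreasing", conc_unit=unit)
    except FitError as err:
        if "no transition" in str(err):
            return AnsFitResult(displaced=False)
        raise
    if fit.start - fit.end < quench_floor:
        return AnsFitResult(displaced=False, fit=fit)
    return AnsFitResult(displaced=True, fit=fit)
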