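"""Synthetic-data generators with planted ground truth.

Every input the analysis consumes can be generated here: screening plates
with lognormal transfection noise and planted activators/cytotoxic wells,
Hill-shaped dose-response points, Boltzmann melt curves with post-transition
aggregation decay, and Gaussian ANS emission bands scaled by a decreasing
Hill quench factor.  All generators are pure functions of their config and
seed — identical inputs give byte-identical outputs.

Generative model for a screen well:

* ``renilla ~ lognormal(mean=renilla_mu, CV=renilla_cv)`` — multiplicative
  transfection variability;
* ``firefly = renilla * baseline_ratio * fold * (1 + eps)``,
  ``eps ~ N(0, cv)`` — so the firefly/Renilla ratio is fold-centered with
  Gaussian measurement noise.  Negative controls have fold 1; positive
  controls use the reference-agonist fold (default 56) with their own,
  larger CV (positive-control variability is plate-visible in real screens);
* cytotoxic wells draw Renilla suppressed far below the control band (and
  firefly with it), so the 5xSD Renilla rule catches them.

Defaults reflect the campaign this pipeline is designed around: a 560-sample
library in 96-well plates (80 samples each), planted activator folds spread
over 1.3-2.1, a 56-fold positive control, melt curves on the 9-89 degC,
1 degC grid, and the standard titration designs (0.3-50 uM for pure ligands,
5-100 ug/mL for extracts in quantitative TSA, 0.003-1 mg/mL for extracts in
ANS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ans import EmissionSpectrum
from .melt import MeltCurve
from .plate import (
    Role,
    ScreeningPlate,
    WellAddress,
    WellRecord,
    default_screen_layout,
    sample_positions,
)

__all__ = [
    "ScreenSimConfig",
    "HillSimConfig",
    "MeltSimConfig",
    "simulate_screen",
    "simulate_confirmation",
    "simulate_dose_response",
    "simulate_melt_curve",
    "simulate_tsa_titration",
    "simulate_quench_series",
    "simulate_campaign",
    "LIGAND_CONCENTRATIONS_UM",
    "EXTRACT_TSA_CONCENTRATIONS_UGML",
    "EXTRACT_ANS_CONCENTRATIONS_MGML",
    "DECADE_CONCENTRATIONS_M",
]

#: standard ligand titration (uM) for quantitative TSA and ANS
LIGAND_CONCENTRATIONS_UM = (0.3, 0.5, 1.0, 3.0, 5.0, 10.0, 30.0, 50.0)
#: usable extract titration (ug/mL) for quantitative TSA
EXTRACT_TSA_CONCENTRATIONS_UGML = (5.0, 10.0, 30.0, 50.0, 100.0)
#: extract titration (mg/mL) for ANS quenching
EXTRACT_ANS_CONCENTRATIONS_MGML = (0.003, 0.005, 0.01, 0.03, 0.05, 0.1, 0.3, 1.0)
#: ten-decade dose-response design, 1e-11 .. 1e-6 M half-decade spaced
DECADE_CONCENTRATIONS_M = tuple(
    float(f"{c:.3e}") for c in np.logspace(-11, -6, 10)
)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean, dtype=float)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


# ---------------------------------------------------------------------------
# screen


@dataclass
class ScreenSimConfig:
    """Conditions for a synthetic primary screen."""

    n_library_samples: int = 560
    hit_folds: tuple[float, ...] = tuple(
        float(f"{f:.4f}") for f in np.linspace(1.3, 2.1, 31)
    )
    n_cytotoxic: int = 0
    renilla_mu: float = 10000.0
    renilla_cv: float = 0.08
    baseline_ratio: float = 1.0
    pos_ctrl_fold: float = 56.0
    pos_ctrl_cv: float = 0.13
    ratio_cv: float = 0.02
    tox_suppression: float = 0.3  # cytotoxic Renilla multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hit_folds) + self.n_cytotoxic > self.n_library_samples:
            raise ValueError("more planted hits + cytotoxic wells than samples")
        for name in ("renilla_cv", "pos_ctrl_cv", "ratio_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[list[ScreeningPlate], pd.DataFrame]:
    """Generate the assay plates of a primary screen plus a truth table.

    Samples fill ceil(n/80) 96-well plates row-major; columns 1/12 carry
    negative/positive controls.  The truth table lists each sample's planted
    fold and cytotoxicity.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_library_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    folds = np.ones(n)
    cytotoxic = np.zeros(n, dtype=bool)
    # plant activators first, cytotoxic wells after them, scattered by shuffle
    order = rng.permutation(n)
    hit_idx = order[: len(config.hit_folds)]
    folds[hit_idx] = config.hit_folds
    tox_idx = order[len(config.hit_folds): len(config.hit_folds) + config.n_cytotoxic]
    cytotoxic[tox_idx] = True

    positions = sample_positions(96)
    per_plate = len(positions)
    n_plates = math.ceil(n / per_plate) if n else 0
    plates: list[ScreeningPlate] = []
    rows = []
    for p in range(n_plates):
        plate = ScreeningPlate(f"P{p + 1:02d}", 96)
        chunk = range(p * per_plate, min((p + 1) * per_plate, n))
        layout = default_screen_layout(96)
        for addr_s, (role, _) in layout.items():
            if role in (Role.negative_control, Role.positive_control):
                fold = config.pos_ctrl_fold if role is Role.positive_control else 1.0
                cv = config.pos_ctrl_cv if role is Role.positive_control else config.ratio_cv
                renilla = float(_lognormal(rng, config.renilla_mu, config.renilla_cv, ()))
                ratio = config.baseline_ratio * fold * (1.0 + rng.normal(0.0, cv))
                plate.add(
                    WellRecord(
                        address=WellAddress.parse(addr_s),
                        role=role,
                        firefly=max(ratio, 0.0) * renilla,
                        renilla=renilla,
                    )
                )
        for j, i in enumerate(chunk):
            renilla = float(_lognormal(rng, config.renilla_mu, config.renilla_cv, ()))
            if cytotoxic[i]:
                renilla *= config.tox_suppression
            ratio = config.baseline_ratio * folds[i] * (
                1.0 + rng.normal(0.0, config.ratio_cv)
            )
            plate.add(
                WellRecord(
                    address=WellAddress.parse(positions[j]),
                    role=Role.sample,
                    sample_id=sample_ids[i],
                    firefly=max(ratio, 0.0) * renilla,
                    renilla=renilla,
                )
            )
            rows.append(
                {
                    "sample_id": sample_ids[i],
                    "plate_id": plate.plate_id,
                    "well": positions[j],
                    "fold": folds[i],
                    "is_activator": folds[i] > 1.0,
                    "is_cytotoxic": bool(cytotoxic[i]),
                }
            )
        plates.append(plate)
    truth = pd.DataFrame(
        rows,
        columns=["sample_id", "plate_id", "well", "fold", "is_activator", "is_cytotoxic"],
    )
    return plates, truth


def simulate_confirmation(
    candidate_folds: dict[str, float],
    config: ScreenSimConfig,
    n_replicates: int = 3,
) -> list[ScreeningPlate]:
    """Replicate plates carrying the given candidates at the given true folds.

    Used for the confirmatory stage: candidates that did not reproduce are
    passed with fold 1.  All candidates share each plate (<= 80 per plate).
    """
    ids = sorted(candidate_folds)
    if len(ids) > len(sample_positions(96)):
        raise ValueError("confirmation plates carry at most 80 candidates")
    rng = np.random.default_rng(config.seed + 1)
    plates = []
    for r in range(n_replicates):
        plate = ScreeningPlate(f"C{r + 1}", 96)
        layout = default_screen_layout(96)
        for addr_s, (role, _) in layout.items():
            if role in (Role.negative_control, Role.positive_control):
                fold = config.pos_ctrl_fold if role is Role.positive_control else 1.0
                cv = config.pos_ctrl_cv if role is Role.positive_control else config.ratio_cv
                renilla = float(_lognormal(rng, config.renilla_mu, config.renilla_cv, ()))
                ratio = config.baseline_ratio * fold * (1.0 + rng.normal(0.0, cv))
                plate.add(
                    WellRecord(
                        address=WellAddress.parse(addr_s),
                        role=role,
                        firefly=max(ratio, 0.0) * renilla,
                        renilla=renilla,
                    )
                )
        for j, sid in enumerate(ids):
            renilla = float(_lognormal(rng, config.renilla_mu, config.renilla_cv, ()))
            ratio = config.baseline_ratio * candidate_folds[sid] * (
                1.0 + rng.normal(0.0, config.ratio_cv)
            )
            plate.add(
                WellRecord(
                    address=WellAddress.parse(sample_positions(96)[j]),
                    role=Role.sample,
                    sample_id=sid,
                    firefly=max(ratio, 0.0) * renilla,
                    renilla=renilla,
                )
            )
        plates.append(plate)
    return plates


# ---------------------------------------------------------------------------
# curve generators


@dataclass
class HillSimConfig:
    """Planted Hill-series truth for dose-response or quench generators."""

    k: float
    n: float = 1.0
    start: float = 0.0
    end: float = 1.0
    concentrations: tuple[float, ...] = DECADE_CONCENTRATIONS_M
    conc_unit: str = "M"
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.n <= 0:
            raise ValueError("k and n must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class MeltSimConfig:
    """Planted Boltzmann melt-curve truth."""

    tm: float = 48.0
    width: float = 1.5
    baseline: float = 1000.0
    amplitude: float = 10000.0
    aggregation_slope: float = 0.0  # signal loss per degC past the transition
    aggregation_onset: float = 8.0  # degC past Tm where decay starts
    noise_sd: float = 0.0  # fraction of amplitude
    t_min: float = 9.0
    t_max: float = 89.0
    t_step: float = 1.0
    replicates: int = 1
    no_transition: bool = False
    condition_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.t_step <= 0:
            raise ValueError("width and t_step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_dose_response(config: HillSimConfig) -> tuple[pd.DataFrame, dict]:
    """Hill-model responses with Gaussian noise on the planted design.

    Returns a long table (``concentration, conc_unit, response, replicate``)
    and the truth dict.
    """
    from .dose_response import hill1

    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.replicates):
        for c in config.concentrations:
            y = hill1(c, config.start, config.end, config.k, config.n)
            if config.noise_sd > 0:
                y += rng.normal(0.0, config.noise_sd)
            rows.append(
                {
                    "concentration": c,
                    "conc_unit": config.conc_unit,
                    "response": y,
                    "replicate": rep + 1,
                }
            )
    truth = {
        "k": config.k,
        "n": config.n,
        "start": config.start,
        "end": config.end,
        "conc_unit": config.conc_unit,
    }
    return pd.DataFrame(rows), truth


def simulate_melt_curve(config: MeltSimConfig) -> tuple[list[MeltCurve], dict]:
    """Boltzmann melt curves (with optional aggregation decay) plus truth.

    ``no_transition=True`` emits amplitude-0 traces — the behavior of samples
    that destabilize the protein or never produce a melting transition.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.t_min, config.t_max + 0.5 * config.t_step, config.t_step)
    curves = []
    for rep in range(config.replicates):
        if config.no_transition:
            f = np.full_like(t, config.baseline)
        else:
            f = config.baseline + config.amplitude / (
                1.0 + np.exp((config.tm - t) / config.width)
            )
            if config.aggregation_slope > 0:
                onset = config.tm + config.aggregation_onset
                f = f - config.aggregation_slope * np.clip(t - onset, 0.0, None)
        if config.noise_sd > 0:
            f = f + rng.normal(0.0, config.noise_sd * config.amplitude, t.shape)
        curves.append(
            MeltCurve(
                t.copy(), f, condition_id=config.condition_id, replicate=rep + 1
            )
        )
    truth = {
        "tm": None if config.no_transition else config.tm,
        "width": config.width,
        "amplitude": 0.0 if config.no_transition else config.amplitude,
    }
    return curves, truth


def simulate_tsa_titration(
    kd: float,
    plateau: float,
    concentrations: Sequence[float] = LIGAND_CONCENTRATIONS_UM,
    conc_unit: str = "uM",
    hill_n: float = 1.0,
    tm_apo: float = 48.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    melt: MeltSimConfig | None = None,
) -> tuple[dict[float, list[MeltCurve]], list[MeltCurve], dict]:
    """Quantitative-TSA inputs: melt curves per ligand concentration + apo.

    The planted Tm at concentration c follows
    ``tm_apo + plateau * c^n / (kd^n + c^n)``.  Returns (per-concentration
    curves, apo curves, truth).
    """
    from .dose_response import hill1

    base = melt or MeltSimConfig()
    rng = np.random.default_rng(seed)
    series: dict[float, list[MeltCurve]] = {}
    for i, c in enumerate(concentrations):
        tm_c = tm_apo + hill1(c, 0.0, plateau, kd, hill_n)
        cfg = MeltSimConfig(
            tm=tm_c,
            width=base.width,
            baseline=base.baseline,
            amplitude=base.amplitude,
            aggregation_slope=base.aggregation_slope,
            noise_sd=noise_sd,
            t_min=base.t_min,
            t_max=base.t_max,
            t_step=base.t_step,
            replicates=replicates,
            condition_id=f"c{i}",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series[float(c)], _ = simulate_melt_curve(cfg)
    apo_cfg = MeltSimConfig(
        tm=tm_apo,
        width=base.width,
        baseline=base.baseline,
        amplitude=base.amplitude,
        aggregation_slope=base.aggregation_slope,
        noise_sd=noise_sd,
        t_min=base.t_min,
        t_max=base.t_max,
        t_step=base.t_step,
        replicates=replicates,
        condition_id="apo",
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    apo, _ = simulate_melt_curve(apo_cfg)
    truth = {"kd": kd, "plateau": plateau, "n": hill_n, "tm_apo": tm_apo,
             "conc_unit": conc_unit}
    return series, apo, truth


def simulate_quench_series(
    kd: float,
    concentrations: Sequence[float] = LIGAND_CONCENTRATIONS_UM,
    conc_unit: str = "uM",
    hill_n: float = 1.0,
    quench_amplitude: float = 0.8,
    band_center_nm: float = 480.0,
    band_width_nm: float = 40.0,
    peak_intensity: float = 50000.0,
    baseline_intensity: float = 500.0,
    noise_sd: float = 0.0,  # fraction of the vehicle peak
    replicates: int = 3,
    seed: int = 0,
    vehicle_id: str = "vehicle",
) -> tuple[list[EmissionSpectrum], dict]:
    """ANS emission spectra per concentration, vehicle included, plus truth.

    Each spectrum is a Gaussian band centered near 480 nm whose height is the
    vehicle height scaled by a decreasing Hill factor
    ``1 - quench_amplitude * c^n / (kd^n + c^n)``; ``quench_amplitude=0``
    emulates a non-displacing ligand.  ``replicates`` independent spectra are
    emitted per condition (quench curves are reported as triplicate means).
    """
    if not 0.0 <= quench_amplitude <= 1.0:
        raise ValueError("quench_amplitude must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    from .dose_response import hill1

    rng = np.random.default_rng(seed)
    wavelengths = np.arange(400.0, 601.0, 2.0)
    band = np.exp(-0.5 * ((wavelengths - band_center_nm) / band_width_nm) ** 2)

    def make(cid: str, conc: float, scale: float) -> EmissionSpectrum:
        intensities = baseline_intensity + peak_intensity * scale * band
        if noise_sd > 0:
            intensities = intensities + rng.normal(
                0.0, noise_sd * peak_intensity, wavelengths.shape
            )
        return EmissionSpectrum(
            wavelengths.copy(),
            np.clip(intensities, 0.0, None),
            condition_id=cid,
            concentration=conc,
            conc_unit=conc_unit,
        )

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spectra = [make(vehicle_id, 0.0, 1.0) for _ in range(replicates)]
    for i, c in enumerate(concentrations):
        scale = 1.0 - hill1(c, 0.0, quench_amplitude, kd, hill_n)
        for _ in range(replicates):
            spectra.append(make(f"c{i}", float(c), scale))
    truth = {
        "kd": kd,
        "n": hill_n,
        "quench_amplitude": quench_amplitude,
        "conc_unit": conc_unit,
    }
    return spectra, truth


# ---------------------------------------------------------------------------
# whole-campaign convenience


def simulate_campaign(
    seed: int = 0,
    screen: ScreenSimConfig | None = None,
    n_reproducible: int = 10,
    n_stabilizers: int = 2,
    n_no_transition: int = 2,
    n_binders: int = 1,
    tm_apo: float = 48.0,
    stabilizer_shifts: tuple[float, ...] = (3.5, 2.5),
    binder_kd_mgml: float = 0.022,
    melt_noise_sd: float = 0.02,
    quench_noise_sd: float = 0.03,
) -> dict:
    """Generate a full four-stage campaign with planted truth.

    Defaults plant the canonical funnel: 31 activators in a 560-sample
    screen, 10 of them reproducible on confirmation, 2 of those stabilizing
    the receptor (shifts 3.5 and 2.5 degC), 2 with no melting transition, the
    rest unshifted, and 1 stabilizer displacing the ANS probe with a
    determinable Kd.  Returns a dict with keys ``screen_plates``,
    ``confirm_plates``, ``tsa``, ``ans``, and ``truth``.
    """
    cfg = screen or ScreenSimConfig(seed=seed)
    if n_reproducible < n_stabilizers + n_no_transition:
        raise ValueError("more special TSA behaviors than reproducible hits")
    if n_binders > n_stabilizers:
        raise ValueError("binders must be a subset of stabilizers")
    plates, truth = simulate_screen(cfg)
    activators = truth[truth.is_activator].sort_values("sample_id")
    candidate_ids = activators.sample_id.tolist()
    candidate_folds = dict(zip(activators.sample_id, activators.fold))

    rng = np.random.default_rng(seed + 10_000)
    reproducible = sorted(
        rng.choice(candidate_ids, size=min(n_reproducible, len(candidate_ids)),
                   replace=False).tolist()
    )
    confirm_folds = {
        sid: candidate_folds[sid] if sid in reproducible else 1.0
        for sid in candidate_ids
    }
    confirm_plates = simulate_confirmation(confirm_folds, cfg, 3)

    stabilizers = reproducible[:n_stabilizers]
    no_transition = reproducible[n_stabilizers: n_stabilizers + n_no_transition]
    binders = stabilizers[:n_binders]
    tsa: dict[str, dict[str, list[MeltCurve]]] = {}
    ans: dict[str, tuple[list[EmissionSpectrum], str]] = {}
    for i, sid in enumerate(reproducible):
        apo, _ = simulate_melt_curve(
            MeltSimConfig(
                tm=tm_apo, noise_sd=melt_noise_sd, replicates=3,
                condition_id=f"{sid}-apo", seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        if sid in stabilizers:
            shift = stabilizer_shifts[stabilizers.index(sid) % len(stabilizer_shifts)]
            holo_cfg = MeltSimConfig(
                tm=tm_apo + shift, noise_sd=melt_noise_sd, replicates=3,
                condition_id=f"{sid}-holo", seed=int(rng.integers(0, 2**31 - 1)),
            )
        elif sid in no_transition:
            holo_cfg = MeltSimConfig(
                no_transition=True, noise_sd=melt_noise_sd, replicates=3,
                condition_id=f"{sid}-holo", seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            holo_cfg = MeltSimConfig(
                tm=tm_apo, noise_sd=melt_noise_sd, replicates=3,
                condition_id=f"{sid}-holo", seed=int(rng.integers(0, 2**31 - 1)),
            )
        holo, _ = simulate_melt_curve(holo_cfg)
        tsa[sid] = {"apo": apo, "holo": holo}
        spectra, _ = simulate_quench_series(
            kd=binder_kd_mgml,
            concentrations=EXTRACT_ANS_CONCENTRATIONS_MGML,
            conc_unit="mg/mL",
            quench_amplitude=0.8 if sid in binders else 0.0,
            noise_sd=quench_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ans[sid] = (spectra, "vehicle")
    return {
        "screen_plates": plates,
        "confirm_plates": confirm_plates,
        "tsa": tsa,
        "ans": ans,
        "truth": {
            "screen": truth,
            "activators": candidate_ids,
            "reproducible": reproducible,
            "stabilizers": stabilizers,
            "no_transition": no_transition,
            "binders": binders,
            "binder_kd_mgml": binder_kd_mgml,
        },
    }
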