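"""Dual-reporter screen analytics: plate QC, cytotoxicity, hit calling.

The primary screen reads two luciferases per well.  The firefly channel
reports receptor transactivation; the constitutive Renilla channel reports
transfection efficiency and, when suppressed, cytotoxicity.  All statistics
run on the per-well firefly/Renilla ratio:

* plate QC — Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n| on the control
  ratios (positive controls as signal, negative as background), plus
  signal-to-background mu_p/mu_n and per-group CV;
* cytotoxicity — sample wells whose Renilla read falls strictly below
  mean(control Renilla) - 5 SD are flagged and excluded from hit calling;
* hit calling — a non-cytotoxic sample is a hit when its ratio is at least
  mu_n + 7 sigma_n, thresholds always from the same plate;
* confirmation — a candidate is confirmed when it passes the hit rule on at
  least 2 of 3 replicate plates, each with its own thresholds.

The multipliers (7, 5), boundary conventions and which controls anchor the
cytotoxicity cutoff are configurable; defaults follow the conventions above.
SDs are sample standard deviations (n-1).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .plate import Role, ScreeningPlate, WellRecord

__all__ = [
    "QCStats",
    "HitCall",
    "CytotoxicityFlag",
    "plate_qc",
    "percent_activation",
    "flag_cytotoxicity",
    "call_hits",
    "confirm_hits",
    "activation_fold",
]


@dataclass
class QCStats:
    """Per-plate control summaries and assay-window statistics."""

    plate_id: str
    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    z_prime: float | None  # None when mu_pos == mu_neg (undefined window)
    signal_to_background: float | None
    cv_pos: float | None
    cv_neg: float | None
    n_pos: int
    n_neg: int

    def passes_gate(self, zprime_min: float = 0.5) -> bool:
        return self.z_prime is not None and self.z_prime >= zprime_min


@dataclass
class CytotoxicityFlag:
    """A sample well whose Renilla read fell below the cytotoxicity cutoff."""

    address: str
    sample_id: str | None
    renilla: float
    cutoff: float


@dataclass
class HitCall:
    sample_id: str | None
    plate_id: str
    address: str
    ratio: float
    percent_activation: float | None
    threshold: float
    is_hit: bool
    is_cytotoxic: bool
    low_confidence: bool = False  # plate failed the Z' reliability gate


def _control_ratios(plate: ScreeningPlate, role: Role) -> list[float]:
    vals = [w.ratio for w in plate.by_role(role) if w.usable]
    return [v for v in vals if v is not None]


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    mu = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mu, sd


def plate_qc(plate: ScreeningPlate) -> QCStats:
    """Control-based plate statistics; needs >=2 usable wells per control group."""
    pos = _control_ratios(plate, Role.positive_control)
    neg = _control_ratios(plate, Role.negative_control)
    for name, grp in (("positive", pos), ("negative", neg)):
        if len(grp) < 2:
            raise ValueError(
                f"plate {plate.plate_id}: need >=2 usable {name} controls, got {len(grp)}"
            )
    mu_p, sd_p = _mean_sd(pos)
    mu_n, sd_n = _mean_sd(neg)
    if mu_p == mu_n:
        z_prime = None
    else:
        z_prime = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return QCStats(
        plate_id=plate.plate_id,
        mu_pos=mu_p,
        sigma_pos=sd_p,
        mu_neg=mu_n,
        sigma_neg=sd_n,
        z_prime=z_prime,
        signal_to_background=mu_p / mu_n if mu_n != 0 else None,
        cv_pos=sd_p / mu_p if mu_p != 0 else None,
        cv_neg=sd_n / mu_n if mu_n != 0 else None,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def percent_activation(
    plate: ScreeningPlate, qc: QCStats | None = None
) -> dict[str, float]:
    """Control-anchored scale: negative-control mean = 0%, positive = 100%.

    Returns ``{address: percent}`` for every usable sample well.
    """
    qc = qc or plate_qc(plate)
    if qc.mu_pos == qc.mu_neg:
        raise ValueError("degenerate anchors: positive and negative means equal")
    span = qc.mu_pos - qc.mu_neg
    return {
        str(w.address): 100.0 * (w.ratio - qc.mu_neg) / span
        for w in plate.samples()
        if w.usable
    }


def flag_cytotoxicity(
    plate: ScreeningPlate,
    tox_k: float = 5.0,
    tox_controls: Literal["all", "neg", "pos"] = "all",
) -> list[CytotoxicityFlag]:
    """Flag sample wells with Renilla strictly below mean - tox_k * SD of controls.

    The cutoff is anchored on the Renilla reads of the control wells (both
    control columns by default, since both carry vehicle-level DMSO).
    """
    roles = {
        "all": (Role.negative_control, Role.positive_control),
        "neg": (Role.negative_control,),
        "pos": (Role.positive_control,),
    }[tox_controls]
    ctrl = [
        w.renilla
        for w in plate.by_role(*roles)
        if w.renilla is not None and w.renilla > 0
    ]
    if len(ctrl) < 2:
        raise ValueError(
            f"plate {plate.plate_id}: need >=2 control wells with Renilla reads"
        )
    mu, sd = _mean_sd(ctrl)
    cutoff = mu - tox_k * sd
    return [
        CytotoxicityFlag(str(w.address), w.sample_id, w.renilla, cutoff)
        for w in plate.samples()
        if w.renilla is not None and w.renilla < cutoff
    ]


def call_hits(
    plate: ScreeningPlate,
    hit_k: float = 7.0,
    tox_k: float = 5.0,
    tox_controls: Literal["all", "neg", "pos"] = "all",
    zprime_min: float = 0.5,
) -> list[HitCall]:
    """Per-plate hit calls: ratio >= mu_neg + hit_k * sigma_neg, cytotoxic excluded.

    Cytotoxic wells are reported with ``is_hit=False, is_cytotoxic=True``; hits
    from plates failing the Z' gate are kept but marked low-confidence.
    """
    qc = plate_qc(plate)
    toxic = {f.address for f in flag_cytotoxicity(plate, tox_k, tox_controls)}
    threshold = qc.mu_neg + hit_k * qc.sigma_neg
    low_conf = not qc.passes_gate(zprime_min)
    try:
        pct = percent_activation(plate, qc)
    except ValueError:
        pct = {}
    calls = []
    for w in plate.samples():
        if not w.usable:
            continue
        addr = str(w.address)
        cytotoxic = addr in toxic
        calls.append(
            HitCall(
                sample_id=w.sample_id,
                plate_id=plate.plate_id,
                address=addr,
                ratio=w.ratio,
                percent_activation=pct.get(addr),
                threshold=threshold,
                is_hit=bool((not cytotoxic) and w.ratio >= threshold),
                is_cytotoxic=cytotoxic,
                low_confidence=low_conf,
            )
        )
    return calls


def confirm_hits(
    replicate_plates: Sequence[ScreeningPlate],
    quorum: int = 2,
    hit_k: float = 7.0,
    tox_k: float = 5.0,
    tox_controls: Literal["all", "neg", "pos"] = "all",
) -> list[str]:
    """Candidates passing the per-plate hit rule on >= ``quorum`` replicates.

    Each replicate computes its own negative-control threshold.  Every
    candidate (sample_id on the first plate) must be present on all replicates.
    """
    if not replicate_plates:
        raise ValueError("no replicate plates given")
    per_plate_hits: list[dict[str, bool]] = []
    ids_per_plate: list[set[str]] = []
    for plate in replicate_plates:
        calls = call_hits(plate, hit_k=hit_k, tox_k=tox_k, tox_controls=tox_controls)
        hits = {}
        for c in calls:
            if c.sample_id is not None:
                hits[c.sample_id] = c.is_hit
        per_plate_hits.append(hits)
        ids_per_plate.append(set(hits))
    candidates = sorted(ids_per_plate[0])
    for plate, ids in zip(replicate_plates, ids_per_plate):
        missing = set(candidates) - ids
        if missing:
            raise ValueError(
                f"candidates missing from replicate plate {plate.plate_id}: "
                f"{sorted(missing)}"
            )
    return [
        sid
        for sid in candidates
        if sum(hits[sid] for hits in per_plate_hits) >= quorum
    ]


def activation_fold(
    plate: ScreeningPlate | None = None,
    treated: Iterable[float] | None = None,
    vehicle: Iterable[float] | None = None,
) -> float:
    """Fold activation: mean treated ratio over mean vehicle (negative) ratio.

    Either pass a plate (positive controls vs negative controls) or explicit
    treated/vehicle ratio collections.
    """
    if plate is not None:
        treated = _control_ratios(plate, Role.positive_control)
        vehicle = _control_ratios(plate, Role.negative_control)
    if treated is None or vehicle is None:
        raise ValueError("need a plate or treated and vehicle ratio lists")
    mu_t = statistics.fmean(list(treated))
    mu_v = statistics.fmean(list(vehicle))
    if mu_v <= 0:
        raise ValueError(f"vehicle mean ratio must be positive, got {mu_v}")
    return mu_t / mu_v
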