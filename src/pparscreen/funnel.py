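"""Four-stage screening funnel: primary screen -> confirmation -> TSA -> ANS.

Each stage is a gate with a configurable threshold:

1. primary screen — per-plate hit rule (ratio >= mu_neg + hit_k * sigma_neg),
   cytotoxic wells (Renilla < mean - tox_k * SD of controls) excluded;
2. confirmation — pass the hit rule on >= confirm_quorum of the replicate
   plates (thresholds recomputed per plate);
3. qualitative TSA — Tm shift classified stabilizer or weak (>= tm_weak degC);
4. ANS quenching — probe displacement with a determinable Kd_app
   (quench amplitude >= quench_floor).

Candidate counts are non-increasing across stages; a final-verdict binder has
passed every gate.  Later-stage inputs are optional — candidates that reached
an absent stage are reported pending.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

from .ans import EmissionSpectrum, build_quench_series, fit_ans_kd
from .melt import MeltCurve, delta_tm, extract_tm
from .plate import ScreeningPlate
from .transactivation import call_hits, confirm_hits, plate_qc

__all__ = ["FunnelConfig", "CandidateRecord", "FunnelReport", "run_funnel", "render_report"]

logger = logging.getLogger("pparscreen.funnel")

STAGES = ("screen", "confirmation", "tsa", "ans")


@dataclass
class FunnelConfig:
    """All funnel thresholds in one auditable place."""

    hit_k: float = 7.0
    tox_k: float = 5.0
    zprime_min: float = 0.5
    confirm_quorum: int = 2
    tm_weak: float = 2.0
    tm_strong: float = 5.0
    quench_floor: float = 0.1
    force_ans: bool = False  # route TSA failures to ANS anyway (exploration)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "FunnelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class CandidateRecord:
    """Stage-by-stage dossier for one sample."""

    sample_id: str
    plate_id: str | None = None
    ratio: float | None = None
    percent_activation: float | None = None
    hit: bool = False
    cytotoxic: bool = False
    low_confidence: bool = False
    confirmation_votes: int | None = None
    confirmed: bool | None = None
    delta_tm: float | None = None
    delta_tm_sd: float | None = None
    tm_classification: str | None = None
    stabilizer: bool | None = None
    ans_displaced: bool | None = None
    kd_app: float | None = None
    kd_app_se: float | None = None
    kd_unit: str | None = None
    tsa_kd_app: float | None = None
    tsa_kd_app_se: float | None = None
    tsa_kd_unit: str | None = None
    verdict: str = "not_hit"


@dataclass
class FunnelReport:
    """Campaign-level result: stage counts, per-candidate dossiers, plate QC."""

    stage_counts: dict[str, int]
    candidates: list[CandidateRecord]
    plate_qc: list[dict[str, Any]]
    config: dict[str, Any]

    def to_json(self, indent: int | None = 2) -> str:
        def default(o):
            if hasattr(o, "item"):  # numpy scalars
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(
            {
                "stage_counts": self.stage_counts,
                "candidates": [dataclasses.asdict(c) for c in self.candidates],
                "plate_qc": self.plate_qc,
                "config": self.config,
            },
            indent=indent,
            sort_keys=True,
            default=default,
        )

    @classmethod
    def from_json(cls, text: str) -> "FunnelReport":
        data = json.loads(text)
        return cls(
            stage_counts=data["stage_counts"],
            candidates=[CandidateRecord(**c) for c in data["candidates"]],
            plate_qc=data["plate_qc"],
            config=data["config"],
        )


def run_funnel(
    config: FunnelConfig,
    screen_plates: Sequence[ScreeningPlate],
    confirm_plates: Sequence[ScreeningPlate] | None = None,
    tsa_curves: Mapping[str, Mapping[str, Sequence[MeltCurve]]] | None = None,
    ans_spectra: Mapping[str, tuple[Sequence[EmissionSpectrum], str]] | None = None,
) -> FunnelReport:
    """Apply the stage gates in order and emit a :class:`FunnelReport`.

    ``tsa_curves`` maps candidate id -> {"apo": curves, "holo": curves};
    ``ans_spectra`` maps candidate id -> (spectra, vehicle_condition_id).
    Stages without inputs leave the surviving candidates pending.
    """
    qc_rows = []
    records: dict[str, CandidateRecord] = {}

    # stage 1 — primary screen
    for plate in screen_plates:
        qc = plate_qc(plate)
        qc_rows.append(
            {
                "plate_id": qc.plate_id,
                "z_prime": qc.z_prime,
                "signal_to_background": qc.signal_to_background,
                "mu_neg": qc.mu_neg,
                "sigma_neg": qc.sigma_neg,
                "mu_pos": qc.mu_pos,
                "sigma_pos": qc.sigma_pos,
                "passes_gate": qc.passes_gate(config.zprime_min),
            }
        )
        for call in call_hits(
            plate, hit_k=config.hit_k, tox_k=config.tox_k,
            zprime_min=config.zprime_min,
        ):
            sid = call.sample_id or f"{call.plate_id}:{call.address}"
            records[sid] = CandidateRecord(
                sample_id=sid,
                plate_id=call.plate_id,
                ratio=call.ratio,
                percent_activation=call.percent_activation,
                hit=call.is_hit,
                cytotoxic=call.is_cytotoxic,
                low_confidence=call.low_confidence,
                verdict="hit_candidate" if call.is_hit else (
                    "cytotoxic" if call.is_cytotoxic else "not_hit"
                ),
            )
            logger.info(
                "screen %s: ratio=%.3f threshold=%.3f hit=%s cytotoxic=%s",
                sid, call.ratio, call.threshold, call.is_hit, call.is_cytotoxic,
            )
    hits = [r for r in records.values() if r.hit]

    # stage 2 — confirmation (>= quorum of replicate plates)
    confirmed_ids: list[str] = []
    if confirm_plates is not None and hits:
        confirmed_ids = confirm_hits(
            confirm_plates,
            quorum=config.confirm_quorum,
            hit_k=config.hit_k,
            tox_k=config.tox_k,
        )
        per_plate = [
            {c.sample_id: c.is_hit for c in call_hits(p, hit_k=config.hit_k, tox_k=config.tox_k)}
            for p in confirm_plates
        ]
        for r in hits:
            votes = sum(h.get(r.sample_id, False) for h in per_plate)
            r.confirmation_votes = votes
            r.confirmed = r.sample_id in confirmed_ids
            r.verdict = "confirmed" if r.confirmed else "not_confirmed"
            logger.info("confirm %s: votes=%d confirmed=%s", r.sample_id, votes, r.confirmed)
        confirmed = [r for r in hits if r.confirmed]
    else:
        for r in hits:
            r.verdict = "pending-confirmation"
        confirmed = []

    # stage 3 — qualitative TSA
    stabilized: list[CandidateRecord] = []
    if tsa_curves is not None and confirmed:
        for r in confirmed:
            data = tsa_curves.get(r.sample_id)
            if data is None:
                raise ValueError(f"TSA input missing for candidate {r.sample_id}")
            holo = [extract_tm(c) for c in data["holo"]]
            apo = [extract_tm(c) for c in data["apo"]]
            dtm = delta_tm(holo, apo, t_weak=config.tm_weak, t_strong=config.tm_strong)
            r.delta_tm = dtm.value
            r.delta_tm_sd = dtm.sd
            r.tm_classification = dtm.classification
            r.stabilizer = dtm.classification in ("stabilizer", "weak")
            r.verdict = "stabilizer" if r.stabilizer else "no_stabilization"
            logger.info(
                "tsa %s: dTm=%s class=%s", r.sample_id, dtm.value, dtm.classification
            )
            if r.stabilizer or config.force_ans:
                stabilized.append(r)
    elif confirmed:
        for r in confirmed:
            r.verdict = "pending-TSA"

    # stage 4 — ANS quenching
    binders: list[CandidateRecord] = []
    if ans_spectra is not None and stabilized:
        for r in stabilized:
            data = ans_spectra.get(r.sample_id)
            if data is None:
                raise ValueError(f"ANS input missing for candidate {r.sample_id}")
            spectra, vehicle_id = data
            series = build_quench_series(spectra, vehicle_id)
            result = fit_ans_kd(series, quench_floor=config.quench_floor)
            r.ans_displaced = result.displaced
            if result.displaced and result.fit is not None:
                r.kd_app = result.fit.k
                r.kd_app_se = result.fit.k_se
                r.kd_unit = result.fit.conc_unit
                r.verdict = "binder"
                binders.append(r)
            else:
                r.verdict = "no_displacement"
            logger.info(
                "ans %s: displaced=%s kd=%s", r.sample_id, result.displaced, r.kd_app
            )
    elif stabilized:
        for r in stabilized:
            r.verdict = "pending-ANS"

    counts = {
        "screen": len(hits),
        "confirmation": len(confirmed) if confirm_plates is not None else None,
        "tsa": len(stabilized) if tsa_curves is not None else None,
        "ans": len(binders) if ans_spectra is not None else None,
    }
    return FunnelReport(
        stage_counts=counts,
        candidates=sorted(records.values(), key=lambda r: r.sample_id),
        plate_qc=qc_rows,
        config=config.to_dict(),
    )


def render_report(report: FunnelReport, fmt: str = "json") -> str:
    """Serialize a report: canonical JSON, or a short human-readable summary."""
    if fmt == "json":
        return report.to_json()
    if fmt == "text":
        lines = ["stage counts:"]
        for stage in STAGES:
            v = report.stage_counts.get(stage)
            lines.append(f"  {stage:<13}{'pending' if v is None else v}")
        lines.append("")
        lines.append("candidates past the primary screen:")
        for c in report.candidates:
            if not c.hit:
                continue
            bits = [f"  {c.sample_id}: verdict={c.verdict}"]
            if c.delta_tm is not None:
                bits.append(f"dTm={c.delta_tm:.1f}C")
            if c.kd_app is not None:
                bits.append(f"Kd_app={c.kd_app:.3g} {c.kd_unit or ''}".rstrip())
            lines.append(" ".join(bits))
        return "\n".join(lines)
    raise ValueError(f"unknown report format {fmt!r}")
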