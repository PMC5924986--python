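# Methods

This note documents the models, rules, numerical choices and limitations of
the pipeline, in the order the funnel runs.

## Dual-reporter normalization and plate QC

Each well's firefly luminescence (receptor-driven reporter) is divided by its
Renilla luminescence (constitutive transfection control); all downstream
statistics operate on this ratio. Wells with Renilla = 0 are retained but
excluded from every statistic — they are *unusable*, which is distinct from
*cytotoxic*.

Plate quality uses the control columns only: Z′ = 1 − 3(σₚ + σₙ)/|μₚ − μₙ|,
signal-to-background μₚ/μₙ, and per-group CV. SDs are sample standard
deviations (n − 1 denominator) throughout. Z′ is undefined (reported as such,
not fabricated) when the control means coincide. The reliability gate defaults
to Z′ ≥ 0.5; hits from failing plates are *kept but marked low-confidence*
rather than discarded — the alternative (dropping them) destroys information
a screener may want for triage, and the gate threshold is configurable.

## Cytotoxicity rule

A sample well is cytotoxic when its Renilla read is strictly below
mean − 5·SD of the control wells' Renilla. The anchor set defaults to *all*
control wells (negative and positive), since both carry vehicle-level DMSO
and the positive-control agonist is itself non-cytotoxic at screening
concentration; `tox_controls` can restrict it to either group. Boundary
conventions: the cytotoxicity rule is strict (<), the hit rule inclusive (≥).
Positive-control wells are never themselves flagged — they help define the
cutoff.

## Hit calling and confirmation

"Ratio 7 times above the SD of the negative controls" is implemented as
r ≥ μₙ + 7σₙ, i.e. anchored at the negative-control mean: the unanchored
reading (r ≥ 7σₙ) is dimensionally inconsistent for ratios normalized near 1.
The multiplier is the `hit_k` config knob. Thresholds are always computed
from the *same plate* as the sample, including on confirmation plates, where
each of the three replicates recomputes its own threshold; a candidate is
confirmed by a ≥ 2-of-3 quorum. Hit calling is applied to raw ratios, not to
percent-activation values — the two are monotone-equivalent within a plate.
Control-well outliers are not auto-removed (no robust trimming by default).

## Dose-response fitting

All binding-type fits share one Hill ("Hill1") engine:

    y(x) = START + (END − START) · xⁿ / (kⁿ + xⁿ)

parameterized internally as (START, END, log₁₀k, log n) so k and n stay
positive, minimized by trust-region least squares from a small multi-start
grid: k initialized at the geometric mean of the design and at the half-range
response crossing, n at {0.5, 1, 2}. Standard errors are asymptotic
(Jacobian-based, delta method for k and n); R² = 1 − SSres/SStot on the
fitted scale. Zero-concentration (vehicle) rows are legal anchors for START
but excluded from the ≥ 2-decade span requirement. END is fitted freely, not
constrained to a positive-control plateau. Flat responses raise a
no-transition error rather than returning a degenerate fit.

Parameter recovery at the standard 10-point decade design (10⁻¹¹–10⁻⁶ M):
median relative EC50 error is below 2% / 10% / 25% at response noise
σ = 0 / 0.02 / 0.05 (checked over 200 simulations per level in the test
suite).

## Melt-curve analysis (TSA / DSF)

Protein-unfolding traces are analyzed in four steps:

1. **Truncation** at the global fluorescence maximum, discarding the
   post-transition aggregation decay (curves whose maximum sits at the first
   point degenerate to a no-transition status).
2. **Boltzmann fit** F(T) = F_pre + (F_post − F_pre)/(1 + exp((Tm − T)/a)),
   initialized at the maximum of a Savitzky–Golay-smoothed dF/dT.
3. **Quality gates** for status `ok`: positive amplitude, R² ≥ 0.95, Tm at
   least 2 °C inside the truncated window, amplitude ≥ 3× the median
   absolute pre-transition residual, and agreement within 0.5 °C with the
   independent derivative-maximum estimate (`tm_by_derivative`). Anything
   else is `no_transition` — a status, never an exception, because flat and
   destabilized curves are expected outcomes for real extracts.
4. **ΔTm** = Tm(holo) − Tm(apo). Replicates are fitted per curve and
   aggregated as mean ± SD across replicates; ΔTm SDs combine in quadrature.
   Classification tiers default to ≥ 5 °C *stabilizer*, ≥ 2 °C *weak*, else
   *none* (ND when either side lacks a transition). These defaults separate
   strong specific agonists (shifts of 7–14 °C) from weak/low-specificity
   binders (2.5–3.5 °C), and are fully configurable.

Under 2% amplitude noise the fitted Tm has bias < 0.1 °C and SD < 0.3 °C
(100-replicate check in the suite), consistent with replicate spreads of
±0.1–1 °C typical of triplicate DSF.

**Quantitative TSA**: ΔTm (not absolute Tm) is fitted against ligand
concentration with the increasing Hill model and START pinned at 0, avoiding
the apo Tm as a free anchor. The Hill coefficient is fixed at 1 by default
(single-site binding): the short titrations used here — 8 ligand or 5
extract concentrations, truncated a few-fold above the Kd — cannot identify
a free n, and floating it roughly doubles the Kd estimator SD (measured
10.5% → 5.3% on the extract design). `fix_n=None` restores a floated
coefficient.

## ANS quenching

The emission maximum of each spectrum is located after a 5-point moving-median
smoothing pass (robust to single-pixel spikes); ties between equal smoothed
maxima break by raw intensity, then by lower wavelength. A peak further than
15 nm from the expected 480 nm band triggers a warning. Intensities are
normalized to the vehicle spectrum (f_norm = 1 by construction); the fitted
k is invariant to this rescaling. Quench series are analyzed as triplicate
means per concentration. The decreasing Hill fit floats START (≈ 1) and the
Hill coefficient (initialized at 1); when the fitted quench amplitude
START − END is below the `quench_floor` (default 0.1), or the series is flat,
the verdict is *no displacement* — the Kd of such a ligand is not
determinable by this assay. No inner-filter/absorbance correction is applied;
high-absorbance concentrations should instead be dropped from the design (the
extract titration for quantitative TSA defaults to 5–100 µg/mL for this
reason).

## Synthetic-data generators

The generators emulate the screening campaign this pipeline was designed
around, with every parameter overridable:

* **Screen**: 560 samples on 7 96-well plates (80 sample wells each; column 1
  negative controls, column 12 positive controls). Renilla is lognormal
  (CV 0.08) — multiplicative transfection biology; the ratio gets Gaussian
  noise on the fold scale (CV 0.02 for samples/negatives, 0.13 for positive
  controls, whose plate-to-plate variability is a known feature of cell-based
  screens). Planted activator folds span 1.3–2.1; the positive-control fold
  defaults to 56 (confirmatory-screen conditions; 199 under fully optimized
  conditions is available via config). These noise levels were chosen once so
  that screen-quality Z′ values (≈ 0.5–0.65) arise naturally and the planted
  folds sit several σ above the 7σ threshold; no noise magnitudes are claimed
  for any real instrument. Cytotoxic wells draw Renilla suppressed to 0.3× —
  far below the 5·SD cutoff.
* **Melt curves**: Boltzmann rise on the 9–89 °C, 1 °C grid (81 points
  inclusive), optional linear aggregation decay past the transition, Gaussian
  noise as a fraction of amplitude, and a no-transition mode emitting flat
  traces.
* **Dose-response / quench series**: Hill curves on the standard designs
  (10-decade molar grid; 0.3–50 µM ligand; 5–100 µg/mL extract for TSA;
  0.003–1 mg/mL extract for ANS) plus Gaussian noise; quench series are
  emitted as Gaussian 480 nm emission bands scaled by the quench factor,
  3 replicates per condition.

All generators are pure functions of (config, seed). What passing tests show:
the analysis recovers planted truth under idealized Gaussian/lognormal noise
on exact Hill/Boltzmann shapes. What they do not show: robustness to spatial
plate effects (edge evaporation, dispenser gradients), non-Gaussian outliers,
compound fluorescence interfering with dye signal, or deviations of real
binding from single-site Hill behavior — real campaigns should inspect QC
and residuals, not assume them.

## Funnel orchestration

Stage gates run strictly in order (hit rule → quorum confirmation → ΔTm
classification ∈ {stabilizer, weak} → displacement with determinable Kd),
each threshold in one `FunnelConfig`; `force_ans` routes TSA failures to ANS
for exploration. Candidate counts are non-increasing across stages, a final
*binder* verdict implies passing every gate, and reports serialize to JSON
with byte-identical reruns for fixed inputs.

## Acceptance-scale experiment sizes

The recovery experiments in `scripts/acceptance.py` use the assays' own
designs — 30-point dose-response (10 concentrations × 3), 6 melt curves of
81 points per ΔTm, 8–9-point titrations with triplicate curves or spectra —
which run in about a second in total; the remaining suite properties use 100–
200 simulation repeats where a distributional claim is made.
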