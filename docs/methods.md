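# Methods

## The dosing model

`colidose` implements the loading- and maintenance-dose algorithm for
intravenous colistimethate in critically ill adults. The pharmacological
premise: colistimethate (the administered prodrug) is predominantly renally
cleared, while formed colistin is cleared mostly non-renally, so the
maintenance dose needed to hold a target average steady-state colistin
concentration (Css,avg) depends strongly on renal function, and patients on
renal replacement therapy (RRT) lose additional drug to the dialysis
circuit.

**Loading dose.** `CBA (mg) = Css,avg × 2.0 × IBW (kg)`, ideal body weight
by the Devine formula (50 kg male / 45.5 kg female at 60 inches, +2.3 kg per
inch above). IBW, not actual weight, is used in all cases. The first regular
daily dose follows 12 hours after the loading dose.

**Maintenance baseline.** `Css,avg × f(CrCl)` with CrCl from the canonical
Cockcroft–Gault equation on actual body weight (the clinician's single
weight input), in mg/dL creatinine units (a µmol/L input is divided by
88.4). `f` — mg CBA/day per 1 mg/L of target — is configuration data, not
code: a YAML/JSON table of CrCl bands, schema-validated at load time
(strictly increasing bounds, non-decreasing doses, full coverage of
[0, ∞)). The bundled default `nation2017.yaml` transcribes the 2017
population-pharmacokinetic dosing guidance (130 mg/day per 1 mg/L at CrCl 0,
rising to 360 mg/day at CrCl ≥ 90). An optional interpolation mode treats
the table rows as knots of a piecewise-linear function instead of steps;
the default table uses steps, matching how the guidance is printed.

**RRT supplement.** A single rule — 10% of the baseline daily dose per hour
of dialysis — reproduces every published operating point: 20% after a 2-h
and 50% after a 5-h intermittent hemodialysis (IHD) session, and 10%/h for
SLED and CRRT. IHD supplements apply only on dialysis days and are given
after the session; on non-dialysis days the baseline alone applies. IHD
sessions outside the studied 2–5 h range still use the 10%/h rule but carry
an extrapolation warning, since the published points only bracket that
range.

**Cap and schedule.** The cap of 300 mg CBA/day (≡ 9.0 million IU) is
applied to the post-supplement daily total and, separately, to the loading
dose — not to the baseline before supplementation. The uncapped value is
retained in every recommendation for transparency, and capping always
attaches the "Immediate Attention" warning. The administered total is split
12-hourly (capped total / 2).

## Units and rounding

All engine arithmetic runs in mg CBA at full double precision; the
1 MIU = 33.3 mg CBA = 80 mg CMS equivalence is pinned as exact constants so
conversions round-trip to better than 1e-9 relative error. Rounding is
purely a display concern: mg values are rounded to the nearest whole
milligram (halves up, the clinical convention) and only then converted to
million IU, shown to one decimal so that the 300 mg ceiling renders as
exactly 9.0 MIU. lb→kg (0.45359237) and in→cm (2.54) use the international
definitions.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| target Css,avg | 2.0 mg/L | grid 0.5–4.0 by 0.5; 2.0 suits colistin MIC ≤ 2 mg/L |
| max_daily_cba | 300 mg CBA | safety ceiling on loading and daily totals |
| supplement rate | 0.10 /h | fraction of baseline added per dialysis hour |
| age band | 18–120 y | input plausibility check (adult dosing only); configurable |

Degenerate inputs are handled deterministically: ages ≥ 140 would make the
Cockcroft–Gault numerator non-positive, so the estimate is clamped to
0 mL/min with a warning rather than an exception; heights below 60 inches
would extrapolate the Devine line downward, so IBW is floored at the
sex-specific base constant. CrCl itself is not capped — the band table's
open top band handles high clearances.

## Validation design and the synthetic generator

The engine is checked against `validation.oracle_dose`, an independently
written straight-line pass over the same equations (own IBW, CrCl, band
lookup, supplement and cap arithmetic, no shared code, no intermediate
rounding). `run_validation` compares the two on a patient panel at a
tolerance of 0.5 mg CBA — the rounding-level agreement the original
calculator's manual validation demonstrated — and the oracle is injectable
so the harness's own sensitivity is testable.

`generate_panel` draws synthetic adults uniformly from plausible ranges
(age 18–90 y, height 55–78 in, weight 40–150 kg, serum creatinine
0.4–8 mg/dL), targets from the Css grid, and RRT per design; the default
8-patient panel fixes 2 patients on each of IHD, SLED, CRRT and none,
mirroring the original validation design. IHD sessions use the published
2 h / 5 h lengths, SLED 6–12 h, CRRT 24 h. Sampling is uniform and
uncorrelated: the generator exercises the algorithm over its input domain
but does not model real covariate structure (renal function, weight and age
co-vary in real ICU populations), so passing validation demonstrates
arithmetic fidelity to the equations, not clinical performance. Panels are
bit-identical for a fixed seed. The test suite and the validation CLI use
panels of 8 and 1000 patients — sizes at which the whole suite runs in
seconds.

## Design choices

* The equivalence constants are pinned at the printed 33.3 and 80 even
  though both are physically approximate: reproducibility of the published
  arithmetic is the goal, not assay-grade precision.
* Cockcroft–Gault uses actual body weight because the calculator exposes a
  single weight field; no CKD-EPI/MDRD substitute is offered, as the dose
  bands were derived against Cockcroft–Gault.
* The maintenance table lives in a config file rather than code so that the
  engine, the oracle and every test are independent of any particular
  coefficient set; alternative tables can be supplied with `--model`.
* History is a plain local JSON-lines file: transparent, greppable, and
  permanently deletable — the privacy contract is local-only storage with
  unrecoverable purge, and the docs advise pseudonymous identifiers. No
  module performs network I/O.

## Known limitations

* The default maintenance table is a step function of CrCl; a patient
  crossing a band boundary sees a discrete dose change.
* No therapeutic drug monitoring feedback, exposure simulation, pediatric
  dosing, inhalational dosing, or polymyxin B support.
* The plausibility checks catch structural errors (non-positive values,
  implausible ages), not clinical ones; the tool does not replace clinical
  judgement.
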