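# colidose

Intravenous colistimethate dosing calculator for critically ill adults — a
Python library and command-line tool.

Colistin (polymyxin E) is a last-line antibiotic for multidrug-resistant
gram-negative infections, administered intravenously as the inactive prodrug
colistimethate (CMS). Dosing it is notoriously error-prone: the prodrug is
renally cleared while formed colistin is not, the therapeutic window is
narrow (nephrotoxicity is the dose-limiting toxicity), and the dose is
labelled in two incompatible conventions — milligrams of colistin base
activity (mg CBA) in North America and million international units (MIU)
elsewhere, related by

```
1 million IU = 33.3 mg CBA = 80 mg CMS
```

`colidose` computes loading and maintenance regimens that target an average
steady-state plasma colistin concentration C<sub>ss,avg</sub> (selectable
0.5–4.0 mg/L in 0.5 steps, default 2.0 mg/L, suitable for pathogens with
colistin MIC ≤ 2 mg/L):

* **Loading dose (all patients):**
  `CBA (mg) = Css,avg (mg/L) × 2.0 × IBW (kg)`,
  with ideal body weight from the Devine formula
  `IBW = 50 kg (45.5 kg for females) + 2.3 × (height in inches − 60)`.
  The first regular daily dose follows 12 h later.
* **Maintenance daily dose:** `Css,avg × f(CrCl)`, where CrCl is the
  Cockcroft–Gault creatinine clearance
  `(140 − age) × weight / (72 × SCr)` (× 0.85 for females) and `f` is a
  CrCl-banded table of mg CBA/day per 1 mg/L of target, loaded from a
  YAML/JSON model config (the bundled default is the published 2017
  population-PK dosing guidance). Administration is 12-hourly.
* **Renal replacement therapy supplement:** 10% of the baseline daily dose
  per hour of dialysis — 20% after a 2-h and 50% after a 5-h intermittent
  hemodialysis session (on dialysis days only), and 10%/h during SLED or
  CRRT.
* **Safety cap:** any loading or total daily dose above **300 mg CBA
  (9.0 million IU)** is capped, with an "Immediate Attention" warning; the
  uncapped value is retained in the record.

Every reported dose is printed in both mg CBA and million IU. Calculation
history is stored only in a local JSON-lines file (use a pseudonymous
patient identifier), and can be purged permanently.

## Worked example

A 70-inch male targeting C<sub>ss,avg</sub> 2 mg/L
(IBW = 50 + 2.3 × 10 = 73 kg, so the loading dose is 2 × 2.0 × 73 = 292 mg):

```
$ colidose loading --sex male --height 70in --css 2
Loading dose: 292 mg CBA (8.8 million IU)
Note: Administer the first regular daily dose 12 hours after the loading dose
```

A 40-year-old, 72-kg male with serum creatinine 1.0 mg/dL on 24-hour CRRT
(Cockcroft–Gault CrCl = (140−40)×72/(72×1.0) = 100 mL/min):

```
$ colidose daily --sex male --age 40 --weight 72kg --scr 1.0 --rrt crrt --hours 24
Creatinine clearance (Cockcroft-Gault): 100.0 mL/min
Baseline daily dose: 720 mg CBA (21.6 million IU)
RRT supplement: 1728 mg CBA (51.9 million IU)
Total daily dose: 300 mg CBA (9.0 million IU)
Administer 150 mg CBA per 12 h (4.5 million IU per 12 h)
Immediate Attention: calculated dose 2448 mg CBA (73.5 million IU) exceeds the maximum recommended 300 mg CBA (9.0 million IU) and has been capped due to safety considerations
Note: During CRRT, add 10% per 1 hour of CRRT to the baseline daily dose
```

The baseline (2 × 360 mg at CrCl ≥ 90) plus the 240% CRRT supplement far
exceeds the ceiling, so the administered total is capped at 300 mg CBA/day,
split as 150 mg per 12 h, and the warning is raised.

Add `--save --patient-id bed-7` to store a calculation, then:

```sh
colidose history               # tabular listing, newest first
colidose history --purge --yes # permanent deletion
```

The engine is validated against an independently coded manual-calculation
oracle on synthetic patient panels:

```
$ colidose validate --seed 1 --n 1000 | tail -1
PASS: 1000 patients, max |engine - oracle| = 0 mg CBA (tolerance 0.5 mg)
```

## History-record schema

One JSON object per line:
`{"record_id": int, "patient_id": str, "timestamp": ISO-8601 UTC,
"inputs": {...}, "recommendation": {...}, "app_version": str}`,
where `recommendation` is the full dose snapshot (uncapped, capped,
supplement, per-12-h amounts in mg CBA, warnings, notes, rendered text).

**This software is a dosing aid for research and education; it does not
replace clinical judgement or therapeutic drug monitoring.**
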