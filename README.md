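# cryocea

A Markov cohort cost-effectiveness model comparing **ultrasound-guided
breast cryoablation (BCA)** with **breast-conserving surgery (BCS)** for
unifocal, small (≤ 1.5 cm), node-negative, low-risk breast cancer, from a US
payer's perspective.  It re-implements a published TreeAge-style decision
analysis as a tested, reusable Python library: the base-case comparison, a
seeded probabilistic sensitivity analysis (PSA), and deterministic
sensitivity analyses (one-way sweeps, two-way preference maps, tornado
diagrams, break-even thresholds).  It is written for health-economics and
interventional-radiology researchers who want to reproduce, perturb or
extend the published comparison.

## The model

Four health states — disease-free (DF), local recurrence, distant
recurrence, dead — evolved over five one-year cycles.  The DF row of the
annual transition matrix is `[1−pL−pD−pM, pL, pD, pM]`; recurrence states
self-persist; death is absorbing.  Each arm pays its procedure cost plus
expected complication cost at cycle 0; DF accrues the routine annual care
cost; recurrence states accrue costs per a calibrated structural reading
(see `docs/methods.md`).  Outcomes:

- QALYs: `Σ_k (1+r)^(−k) Σ_s occ[k,s]·u(s,k)` with `r = 3%/yr`,
  first-year DF utility reduced by the treatment disutility and expected
  complication disutility;
- net monetary benefit `NMB = λ·QALY − cost` at willingness-to-pay
  `λ = $100,000/QALY` (subgroup: $50,000);
- ICER `ΔC/ΔE` when the increments share a sign, with explicit
  dominance/tie flags otherwise.

Probabilities are Beta distributed, costs Gamma (moment-matched from mean
and SD), utilities truncated Normal; the PSA draws shared economic
parameters once per iteration for both arms.

## Worked example

```sh
python examples/base_case.py
```

```text
scenario: low_risk (WTP $100,000/QALY)
  cryoablation: cost $   177,520   QALYs 3.517
  surgery:      cost $   191,988   QALYs 3.469
  incremental (BCA-BCS): $-14,469, +0.048 QALY
  ICER flag: dominant;  preferred: bca
  NMB: BCA $174,160 vs BCS $154,931
```

Cryoablation costs $14,469 less per patient and yields 0.048 more QALYs
over five years, so it *dominates* surgery — preferred at any
willingness-to-pay.  The other examples cover the PSA (`psa_run.py`:
cryoablation wins ≈ 98% of low-risk iterations and 100% of 1–20 mm
iterations), threshold analysis (`threshold_analysis.py`: surgery becomes
preferred if the cryoablation procedure exceeds $21,730, its extra annual
surveillance cost exceeds $4,094, or its annual mortality exceeds 3.6%),
two-way boundaries and tornado diagrams (`two_way_and_tornado.py`), and
scenario/report serialization (`scenario_io.py`).

A scenario is an ordinary YAML/JSON document (emit the published ones with
`cryocea.emit_paper_scenarios(out_dir)`, each parameter annotated in a
provenance manifest); `cryocea.generate_synthetic_scenario(seed)` produces
random valid scenarios for property testing.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the reproduction targets from scratch — both base cases, a
10,000-iteration seeded PSA per scenario, the one-way break-even searches
(mortality, local and distant recurrence, procedure cost with an analytic
closed-form cross-check, follow-up cost) and the two-way mortality and
local-recurrence preference boundaries — and writes one JSON object with a
value per target (≈ 20 s on one CPU).

## Layout

- `src/cryocea/params.py` — distributions, parameters, scenario I/O
- `src/cryocea/engine.py` — the discounted cohort engine
- `src/cryocea/metrics.py` — NMB / ICER / dominance
- `src/cryocea/psa.py`, `src/cryocea/dsa.py` — sensitivity analyses
- `src/cryocea/fixtures.py` — published scenarios + synthetic generator
- `src/cryocea/calibration.py` — 72-variant structural calibration
- `src/cryocea/reporting.py` — reports, traces, run manifests
- `docs/methods.md` — model, assumptions, calibration table, limitations
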