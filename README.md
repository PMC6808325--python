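# dialysis-cea

Cost-utility analysis of the two main dialysis modalities for end-stage
renal disease — in-centre hemodialysis (HD) and continuous ambulatory
peritoneal dialysis (CAPD) — from a public-payer perspective, built as a
tested, reusable Python pipeline.  The default inputs transcribe a
published Ministry-of-Health cost-utility analysis of dialysis provision in
Malaysia (annual per-patient costs in 2017 ringgit, EQ-5D-3L utilities, and
registry-derived annual transition rates), so the package reproduces that
analysis end to end and can be re-run with any other parameter file.

It is aimed at health-economics and HTA analysts who need the standard
machinery of a modality-mix decision model without rebuilding it in a
spreadsheet or a proprietary tool:

- **Survival estimation** from registry-style patient records:
  Kaplan-Meier product-limit curves with Greenwood standard errors
  (intention-to-treat by first modality), restricted-mean survival
  ("life years"), and annual event rates from mid-year populations, with
  the conversion `p = 1 − exp(−r·t)` to per-cycle probabilities.
- **A 3-state Markov cohort model** (HD, CAPD, Death; death absorbing) over
  a 5-year horizon of annual cycles, with half-cycle correction and 3%
  annual discounting, accumulating cost, life years and QALYs per member of
  the incident cohort.
- **Cost-effectiveness metrics**: QALYs from LY × utility, cost per LY and
  per QALY, HD:CAPD cost ratios, net monetary benefit (NMB), and an ICER
  ladder with strict and extended dominance and GDP-based
  willingness-to-pay classification (RM40,000 / RM120,000 per QALY).
- **Sensitivity analysis**: one-way tornado analysis of incremental NMB
  over every published parameter range, and probabilistic sensitivity
  analysis (1,000 second-order Monte Carlo iterations; gamma costs, beta
  utilities and rates) summarized as cost-effectiveness acceptability
  curves (CEAC).
- **A synthetic registry generator** producing patient-level records with
  the assumed statistical structure (competing exponential death/switch/
  censoring hazards, 2011–2015 enrolment, administrative censoring at the
  end of 2016), so the whole pipeline is testable although the original
  registry extract is not public.

## The model

Patients start on HD or CAPD according to a provision strategy's initial
mix and move between states once per annual cycle with probabilities
obtained from annual rates $r$ via $p = 1 - e^{-rt}$.  With occupancy row
vector $\pi_k = \pi_{k-1} P$ and per-year payoffs $h$ (1 for LY, the EQ-5D
utility $u_s$ for QALYs, the annual treatment cost $c_s$ for costs), cycle
$k$ contributes

$$\tfrac{1}{2}(\pi_{k-1} + \pi_k)\,h \;/\; (1+d)^k,$$

the half-cycle (trapezoidal) correction with end-of-cycle discounting at
$d = 3\%$.  Compared strategies differ only in the initial mix: the base
case is 60:40 HD:CAPD; scenarios 1–3 are 55:45, 50:50 and 70:30.  Strategy
comparison uses incremental NMB ($\Delta E \cdot \lambda - \Delta C$) and
the ICER frontier.

## Worked example

```python
from dialysis_cea import default_parameters, run_scenario
from dialysis_cea.cea import modality_summary, cost_ratio

params = default_parameters()

hd = modality_summary("HD", 4.15, 0.854, params.costs["HD"].annual_cost)
capd = modality_summary("CAPD", 3.70, 0.905, params.costs["CAPD"].annual_cost)
print(hd.qaly, capd.qaly)                    # 3.544 3.348
print(hd.cost_per_qaly, capd.cost_per_qaly)  # 46595.0 41527.0
print(cost_ratio(hd, capd))                  # (1.06, 1.12)

_, res = run_scenario(params, "scenario2")
print(round(res.total_ly, 3), round(res.disc_cost))   # 3.689 132206
```

A patient with 4.15 mean life years on HD at utility 0.854 accrues 3.544
QALYs, at RM46,595 per QALY against RM41,527 on CAPD — HD costs 1.06× per
life year and 1.12× per QALY.  The Markov run shows a member of the 50:50
incident cohort accrues 3.689 life years over 5 years at a discounted cost
of RM132,206; comparing strategies, the 50:50 mix has slightly lower cost
and slightly higher QALYs than current practice (60:40), so expanding CAPD
is the preferred strategy at conventional thresholds.

The same stages are exposed as a CLI:

```bash
dialysis-cea simulate-registry --n 5000 --seed 1 --out registry.csv
dialysis-cea estimate-survival --registry registry.csv --rates-out rates.csv
dialysis-cea run-model --scenario scenario2
dialysis-cea cea
dialysis-cea tornado --out tornado.csv
dialysis-cea psa --iterations 1000 --seed 1 --ceac-out ceac.csv
```

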