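# wmcea

A Markov cohort cost-effectiveness model of **ibrutinib versus the
current therapeutic pathway (CTP) in relapsed/refractory Waldenström
macroglobulinemia**, from the Italian National Health Service
perspective. It is written for health-economics analysts who want a
reproducible, fully testable re-implementation of a published
cost-effectiveness analysis whose inputs are only partially public:
the printed input tables (treatment mix, drug prices, DRG and
outpatient tariffs) ship with the package, and the unpublished inputs
are reconstructed by a calibration module so that the model reproduces
the published result tables.

## The model in brief

Five health states — initial treatment, first and second subsequent
treatment, best supportive care (BSC), death — traversed in 4-week
cycles (13/year) over a 15-year horizon. Progression-free survival on
ibrutinib follows a Weibull curve S(t) = exp(−(t/λ)^k); the comparator
arm is derived under proportional hazards with HR = 0.25 (95% CI
0.11–0.57), S_CTP = S_ibr^(1/HR). Progressors split 70/30 between the
next treatment line and BSC. Costs are activity-based (ex-factory
drug prices with whole-vial rounding, €371/day IV administration
tariff, DRG tariffs for severe adverse events, monitoring bundles) and
both streams discount at 3%/year. The headline statistic is the
incremental cost-effectiveness ratio

    ICER = (C_ibr − C_CTP) / (E_ibr − E_CTP)   [€ per life-year gained]

with deterministic (one-way scenario) and probabilistic (joint
sampling, CEAC) sensitivity analyses. See `docs/methods.md` for the
full model description and the calibration design.

## Worked example

```python
from wmcea import load_default_parameters, run_base_case
from wmcea.cea import render_report

params = load_default_parameters()   # printed tables + calibrated bundle
result = run_base_case(params)
print(render_report(result, "text"))
```

prints

```
Variable                             Ibrutinib           CTP     Increment
Life Years (discounted)                   6.80          3.79          3.02
Drug cost                              200,575        33,835       166,740
Administration cost                          0         6,098        -6,098
Serious Adverse Events costs            13,423        21,978        -8,555
Total post-progression costs            19,141        13,017         6,125
Total Costs                            233,139        74,928       158,212
ICER EUR/LYG (ibrutinib vs CTP)         52,455
Note: ICER computed from unrounded increments.
```

Read: over 15 years, ibrutinib yields 3.02 extra (discounted)
life-years at €158,212 extra cost — about €52,500 per life-year
gained, below the €60,000/LYG willingness-to-pay threshold. Higher
drug acquisition cost is partly offset by avoided IV administration
and adverse-event management. The same pipeline is scriptable from the
shell (`wmcea run`, `wmcea dsa`, `wmcea psa`, `wmcea calibrate`).

The numbered drivers under `analysis/` run the full study:
`01_calibrate.py` (refits the unpublished inputs to the published
aggregates and reports residuals — worst 0.46%), `02_base_case.py`
(table above), `03_dsa.py` (one-way scenario table; ICERs range from
€39,155 at ibrutinib −20% price to €65,755 at +20%), `04_psa.py`
(2,000-draw PSA; cost-effective at €60,000/LYG in ~72% of draws under
the package's default sampling distributions). Tables land in
`results/`.

## Layout

    src/wmcea/        model_params, survival, engine, costing, cea,
                      sensitivity, calibration, cli; shipped input
                      bundle under data/
    analysis/         numbered study drivers (results land in results/)
    tests/            pytest suite incl. acceptance-level checks
    docs/methods.md   model, calibration and design notes
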