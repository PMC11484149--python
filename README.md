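# adcea

A cohort cost-effectiveness model for systemic therapy (abrocitinib 100 mg +
topical therapy) versus standard of care (topical therapy alone) in adults
with moderate-to-severe atopic dermatitis, from Japanese **societal** and
**payer** perspectives.

## Who this is for

Health-economics analysts and modellers who need a transparent, tested,
scriptable implementation of a decision-tree + Markov hybrid model for a
chronic, non-fatal disease with response-based treatment continuation:
deterministic ICERs, one-way sensitivity analysis (tornado), probabilistic
sensitivity analysis (PSA), and cost-effectiveness acceptability curves
(CEAC), all reproducible from a single YAML parameter file.

## The model

**Initial phase (decision tree, weeks 0–52).** Everyone starts on the
assigned treatment. Response (EASI-75 with a ≥4-point DLQI improvement) is
assessed at week 16: responders continue, non-responders switch to standard
of care and subsequent treatment. Responders on active treatment face a
16–52-week all-cause discontinuation probability, and at week 52 a
sustained-response assessment; sustainers enter maintenance.

**Maintenance phase (Markov, 6-month cycles, lifetime horizon).** Three
states — *in response* (on maintenance treatment), *non-response* (standard
of care + subsequent treatment), *dead*. Exits from response combine linear
response waning (down to a long-term response rate at a fixed horizon) with
a constant annual discontinuation probability as independent competing
risks. Background mortality comes from an age-indexed life table and is
identical in both arms ("no treatment effect on mortality"); life-years are
reported undiscounted while QALYs and costs are discounted at 2%/year with
half-cycle correction.

**Valuation.** Utilities depend on arm and responder status. Costs cover
drug acquisition (including monthly subsequent-treatment spend for
non-response time), adverse-event management, hospitalization/primary-care
resource use, and laboratory monitoring (year-1 vs year-2+ schedules).
The societal perspective adds productivity loss by the human-capital
approach (employment rate × hours × wage × share of hours lost, to
retirement at 65). The headline statistic is the incremental
cost-effectiveness ratio,

    ICER = (C_tx − C_soc) / (E_tx − E_soc)   [JPY per QALY],

judged against a willingness-to-pay threshold λ = ¥5,000,000/QALY; the CEAC
reports Pr(λ·ΔE − ΔC > 0) over PSA draws.

No patient-level data are used anywhere: the packaged base case is the
published aggregate input set, and a synthetic Gompertz–Makeham life table
(life expectancy 46.6 y at age 38, 84.0 y at birth) stands in for national
mortality statistics so everything runs offline.

## Worked example

```python
from adcea import (load_basecase, make_synthetic_life_table,
                   calibrate_start_age, run_cea)

p = load_basecase()
lt = make_synthetic_life_table()
# pin the cohort start age so undiscounted life expectancy matches 46.05 y
p.settings.start_age = calibrate_start_age(p, lt, 46.05)

for persp in ("societal", "payer"):
    r = run_cea(p, lt, persp)
    print(persp, f"dQALY={r.inc_qaly:.3f}",
          f"dCost={r.inc_cost:,.0f}", f"ICER={r.icer:,.0f}")
```

prints

```
societal dQALY=0.768 dCost=2,316,567 ICER=3,016,141
payer dQALY=0.768 dCost=4,463,638 ICER=5,811,601
```

i.e. treatment gains 0.77 QALYs per patient; from the societal perspective
(which credits reduced productivity loss against the drug cost) the ICER is
about ¥3.0M/QALY — cost-effective at the ¥5M threshold — while from the
payer perspective it is about ¥5.8M/QALY.

The same run from the shell, with CSV outputs and a run manifest:

```bash
adcea run --calibrate-le 46.05 --perspective societal --out results/
adcea owsa --mode fixed_fraction --top 10 --out results/   # tornado.csv
adcea psa --iterations 1000 --seed 1 --out results/        # ce_plane.csv
adcea ceac --iterations 1000 --seed 1 --out results/       # ceac.csv
adcea synth lifetable --out lifetable.csv
```

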