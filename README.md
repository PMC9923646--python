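# eecc-costing

Ingredients-based, incremental costing of critical-care services for
low-resource hospital settings, with deterministic scenario bounds and a
gamma Monte Carlo probabilistic sensitivity analysis (PSA).

The package answers a budgeting question health planners in low- and
middle-income countries face: what does it cost, per patient-day and per
admission, to provide **Essential Emergency and Critical Care (EECC)** — the
low-cost package of identifying critical illness and giving essential organ
support — and **Advanced Critical Care (ACC)** — EECC plus the
resource-intensive organ support of an ICU? Costs are estimated for two East
African country contexts (Tanzania-like and Kenya-like), stratified by
illness severity (moderate / severe / critical, with COVID-19 as the tracer
condition), and built bottom-up from an itemized resource list: the
*incremental* cost of critical care over and above the hotel, definitive and
other care a hospital already provides.

## The model

For each resource line *i* (an ingredient with per-patient-day quantity
*q_i,s* at severity *s* and unit price *p_i*), the cost per patient-day is

```
cost_s = Σ_i  q_i,s · v(p_i)
```

where the valuation `v(·)` converts to USD at fixed exchange rates
(1 USD = 2300 TZS = 115 KES), adds a 17.4% transport/insurance uplift to
goods priced without shipping, annualizes capital purchases over their
useful life *L* at discount rate *r* = 3% via the annuity factor

```
AF(r, L) = (1 − (1+r)^−L) / r        (equivalent annual cost = price / AF)
```

and values staff minutes from annual public-sector salaries. Oxygen — the
dominant cost for severe and critical respiratory illness — is costed
through an explicit supply model (annualized concentrators/cylinders +
recurrent running costs + refills, divided by litres delivered per year)
and a flow-rate profile per severity (e.g. 5 L/min × 24 h for severe
patients). Moderate patients are not critically ill and consume only
identification-stream resources (vital-signs monitoring); ACC line sets are
supersets of EECC line sets.

Uncertainty is handled in two stages. Scenario analysis moves oxygen (and,
for ACC, pharmaceutical) daily costs by ±25% and re-values staffing with
the cheapest adequate cadre (low) or the highest nurse grade plus a
consultant doctor (high), giving per-category (low, reference, high)
bounds. The PSA reads each category's bounds as central-95% limits of a
gamma distribution fitted by moments (mean = reference,
sd = (high − low)/3.92), samples categories independently
(n = 1000 draws), and reports the mean and empirical 2.5/97.5 percentiles
of the summed total.

## Worked example

The packaged category-level reference model reproduces the calibrated
breakdown tables for both countries:

```python
>>> import eecc_costing as ec
>>> model = ec.reference_fixture()
>>> b = model.breakdown(ec.Country.TZ, ec.CareLevel.EECC, ec.Severity.SEVERE)
>>> round(b.total_usd_per_day, 2)
10.83
>>> ec.category_share(b, ec.CostCategory.OXYGEN)
44.0
>>> bounds = ec.build_bounds(b, model.scenario_spec(
...     ec.Country.TZ, ec.CareLevel.EECC, ec.Severity.SEVERE))
>>> (round(bounds.total_low, 2), round(bounds.total_high, 2))
(8.74, 22.12)
>>> psa = ec.run_psa(bounds, ec.CostingContext(seed=1))
>>> f"{psa.mean_usd:.2f} ({psa.ci_low_usd:.2f}-{psa.ci_high_usd:.2f})"
'10.73 (7.34-17.73)'
```

A severe patient-day of essential care in the Tanzania context costs
10.83 USD (oxygen is 44% of it); the staffing/oxygen scenario grid spans
8.74–22.12 USD, and the gamma PSA summarises that uncertainty as
10.73 (7.34–17.73) USD. The severity-mix headline — weighting severe and
critical per-day costs 74%/26% — rounds to 17 USD (Tanzania) and 21 USD
(Kenya):

```python
>>> tz = ec.weighted_daily_cost(10.83, 32.84)
>>> ec.headline(tz)
17.0
```

The same numbers are available from the shell:

```sh
eecc cost --out tables/          # breakdown tables (CSV + aligned text)
eecc scenarios --country TZ      # low/reference/high totals per cell
eecc psa --seed 1                # Monte Carlo means and intervals
eecc generate --seed 1 --out m/  # synthetic item-level model (CSV)
eecc fixture --out ref/          # emit the reference model as CSV
```

Every run writes `run_manifest.json` (config hash, seed, version) so
outputs can be reproduced bit for bit.

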