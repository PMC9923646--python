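# Methods

## Scope and approach

The package implements a normative, incremental, ingredients-based costing
of critical-care provision: it prices the resources that must be in place
to deliver a defined standard of care, over and above the hotel, definitive
and other care a hospital already provides, rather than observed
expenditure. Costs are built bottom-up as Σ (quantity × unit price) over an
itemized resource list, stratified by country context (TZ-like, KE-like),
illness severity (moderate, severe, critical) and care level (essential,
EECC; advanced, ACC). Two structural rules shape every model the package
accepts: moderate patients are not critically ill, so at the essential
level they consume identification-stream resources (vital-signs
monitoring) only; and the advanced package is defined as a superset of the
essential one, so ACC line sets always contain the EECC lines plus
ACC-only extras. Cost-effectiveness analysis is out of scope.

## Valuation

| parameter | unit | default | role |
|---|---|---|---|
| `fx_rate_tzs_per_usd` | TZS/USD | 2300 | currency conversion |
| `fx_rate_kes_per_usd` | KES/USD | 115 | currency conversion |
| `discount_rate` | — | 0.03 | capital annualization |
| `transport_uplift` | — | 0.174 | shipping/insurance on flagged goods |
| `working_minutes_per_year` | min | 108 000 | salary → per-minute staff cost |
| `psa_draws` | draws | 1000 | Monte Carlo sample size |
| `ci_quantiles` | — | (0.025, 0.975) | reported interval |

Capital purchases are converted to an equivalent annual cost by dividing
the (uplifted) USD price by the annuity factor AF(r, L) = (1 − (1+r)^−L)/r,
computed as `-expm1(-L·log1p(r))/r` for numerical stability near r = 0,
where AF = L (straight-line depreciation). The per-day capital denominator
is 365 days with a per-line utilization fraction carried as data
(device-fraction quantities), rather than occupancy-adjusted bed-days;
occupancy enters only the oxygen supply model, through annual litres
delivered. The uplift applies only to goods explicitly flagged
`needs_uplift` (supply-department prices quoted without shipping), never to
salaries or hotel charges. `working_minutes_per_year` is a standard
public-sector assumption (225 working days × 8 h); category-level results
are insensitive to it because the reference model is calibrated at category
granularity.

Internal arithmetic is at full precision; reported values are rounded
half-up — 2 decimals in tables, whole USD for headline figures.

## Oxygen

Oxygen is costed through a transparent supply model rather than a flat
consumable price: USD/L = (Σ annualized capital + recurrent running costs +
annual refill spend) / annual litres delivered. Three presets are shipped —
concentrators with cylinder backup (the reference district-hospital
supply), cylinders only (same litres, higher refill spend, hence a higher
USD/L), and an ICU high-flow configuration. The reference preset is
calibrated so that a severe patient on 5 L/min for 24 h costs 4.74 USD/day
(≈ 0.000658 USD/L); the critical-severity profiles (≈ 20.7 L/min essential,
≈ 38.2 L/min advanced, both 24 h) are fixture parameters expressed relative
to that calibration, since flow rates are assumptions rather than measured
data. The same USD/L is used for both country contexts: no KE-specific
oxygen costing was available, a limitation inherited by every downstream
number. No pressure-swing-adsorption plants or liquid-oxygen supply chains
are modelled.

## Aggregation and reporting

Breakdowns report the eight cost categories (hotel, staffing, oxygen,
pharmaceuticals, non-pharmaceutical capital, non-pharmaceutical
recurrent/fluids, PPE, diagnostics — the last only populated in advanced
care). Percentage shares are displayed as integers at or above 1% and to
one decimal below 1%; the integer shares are apportioned by largest
remainder so that displayed shares sum to 100 within the sub-percent
rounding slack (≤ 0.5). The single-category accessor `category_share`
rounds independently and can therefore differ from the table column by one
unit in rare ties. Hotel costs are carried in every breakdown to match the
reference table convention, but strictly they are not incremental
critical-care costs; `total_excluding_hotel` exposes the stricter total.

## Scenario analysis

Oxygen (and, at the advanced level, pharmaceutical) category costs move by
an indicative ±25%. Staffing is re-valued: all staff minutes at the
cheapest cadre's salary for the low bound and at the most expensive
(highest nurse grade / consultant doctor) for the high bound when an
item-level model with a salary schedule is available. The packaged
category-level reference model has no item detail, so it ships explicit
per-cell staffing (low, high) overrides back-derived from its reference
total ranges by subtracting the fixed categories and the ±25% terms; one
cell (KE, advanced, severe) had an implied high endpoint below the
reference staffing cost and is clamped to the reference so every triple
satisfies low ≤ reference ≤ high. All other cells reproduce their range
endpoints exactly (e.g. TZ moderate essential care: 0.36–2.28 USD/day).

## Probabilistic sensitivity analysis

Each category's (low, high) bounds are read as central-95% limits of a
gamma distribution fitted by moments: mean = reference,
sd = (high − low)/3.92, shape = (mean/sd)², scale = sd²/mean. Degenerate
bounds (low = high) are point masses. Categories are sampled
independently — the simplest defensible reading; any correlation between
category costs (e.g. a price shock hitting oxygen and pharmaceuticals
together) would widen the true interval relative to the reported one.
Draw totals are summed per draw; the sample mean and empirical 2.5/97.5
percentiles are reported. Because the gamma is right-skewed, the Monte
Carlo mean sits slightly below the deterministic point estimate whenever
the high bound is far above the reference (e.g. 10.73 vs 10.83 for the
severe TZ essential cell) — a parameterization effect, not an error.
Reproducibility: each category's random stream is a numpy `SeedSequence`
of (root seed, CRC-32 of the category name), so results are bit-identical
for a given seed and adding a category never perturbs the draws of the
others.

## Admissions and the severity mix

Per-admission cost is per-day cost × average length of stay. LOS values
are data with deliberately transparent defaults back-divided from the
reference per-stay figures (moderate 3, severe 8, critical 8 TZ / 14 KE
days at the essential level; 8–14 days advanced); they are marked
reverse-engineered and fully overridable, since published LOS sources for
these contexts are inconsistent across countries. The headline cost of
critical illness care weights severe and critical per-day costs 74%/26%
(the assumed severity mix among the critically ill) and is reported in
whole USD.

## Synthetic data

`generate_model` draws item-level models for exercising the full valuation
pipeline: lognormal price noise around country-profile anchors (strictly
positive, right-skewed), salary anchors with the KE-like profile uniformly
above the TZ-like one, and line structure obeying the moderate-severity,
diagnostics and oxygen rules above. Noise factors clip the underlying
normal at ±2σ so the country salary ordering is strict for every seed. The
generator keeps independent bookkeeping of the daily cost it intends each
category to have, enabling parameter-recovery checks. What it does *not*
emulate: realistic drug names or dosages (labelled placeholders), price
correlations between items, within-country regional price variation, or
measured patient-level resource-use variation — quantities are fixed
per-severity averages, as in the underlying costing approach. Passing
tests therefore demonstrate pipeline correctness and structural-invariant
closure, not fidelity to any particular hospital's ledger.

The category-level reference model (`reference_fixture`) enters category
daily costs directly at their calibrated values for both countries, all
severities and both care levels; it exists because item-level reference
price lists are not available in machine-readable form, while
category-level outputs are. Two of its cells are known to be internally
inconsistent with their own per-stay or range figures at the cent level
(KE moderate essential; KE advanced severe high bound) and are documented
above and in the data files rather than silently adjusted.

## Problem sizes

Default test and reproduction runs use 1000 PSA draws (10 000 where a
sampling distribution is being checked against its analytic moments),
100 generated models for the structural-invariant sweep in the test suite
and 40 in the reproduction script, and 2 items per consumable category in
generated models. All complete in seconds on a single core.

## Known limitations

- Prices are current-2020; no inflation adjustment across years.
- The oxygen supply model is a transparent annualized-cost formula with
  scenario presets, not a full logistics/quantification tool.
- Independence of category draws in the PSA is an assumption (see above).
- The clinical content of the care packages (the care processes
  themselves) is taken as given and not modelled.
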