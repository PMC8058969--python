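# Methods

## Decision problem

The bundled scenario compares two strategies for chemorefractory metastatic
colorectal cancer from the Japanese health-care payer perspective, costs in
2019 US dollars (110.05 JPY/USD):

- **monotherapy** — TAS-102 (trifluridine/tipiracil) alone (reference);
- **combination** — TAS-102 plus bevacizumab (comparator).

Outcomes are discounted lifetime costs and quality-adjusted life-years
(QALYs), the incremental cost-effectiveness ratio (ICER), and probabilistic
acceptability at a willingness-to-pay threshold of $117,746/QALY (threefold
Japanese per-capita GDP).

## Model structure

A discrete-time Markov cohort model with an 8-week cycle and a 30-cycle
(~4.6-year) horizon. Five health states are reported: stable disease (SD),
treatment complication (TC), progression (PROG), progression with
complication (PC) and death. Internally the engine expands these to seven:

```
SD ──p_complication──> TC ──(1 cycle)──> SD_postC
SD / SD_postC ──p_progression──> PROG
PROG ──p_complication──> PC ──(1 cycle)──> PROG_postC
PROG / PROG_postC ──p_death──> DEATH (absorbing)
```

TC and PC are **one-cycle tunnel states**: occupancy equals fresh inflow, so
the once-only complication-management cost can be charged exactly once per
complication event, at the entry cycle. The post-complication twin states
(`SD_postC`, `PROG_postC`) carry the same utilities and transition
probabilities as their parents and are collapsed back onto SD/PROG for
reporting. Death is reached only from the progressed phase; the whole cohort
starts in SD.

Transition probabilities derive from median survival via the declining
exponential approximation (DEALE): rate = ln 2 / median, per-cycle
probability = 1 − exp(−rate × cycle length). `prob_rescale` converts
probabilities between cycle lengths on the same underlying rate.

## Values and conventions

Per-cycle QALY is utility × 8/52 (verified against the published per-cycle
values 0.11076923, 0.11230769, 0.09076923 to all printed digits). Per-cycle
cost is the sum of item unit costs times integer per-cycle multiplicities
(doses/visits per 8-week cycle); the complication item is excluded from the
cycle cost and charged once at tunnel entry.

Two conventions are configurable because the source analysis does not state
them:

- **membership counting** — `cycle_start` (occupancy at t = 0..n−1),
  `cycle_end` (t = 1..n), or `half_cycle` (average of consecutive
  occupancies, the half-cycle correction);
- **discounting** — `annualized` (1.035^(−t·8/52)) or `per_cycle`
  (1.035^(−t)).

The once-only complication cost is always discounted at its entry cycle,
independent of the counting convention.

## Calibration of the undocumented configuration

The published analysis reports parameter tables and base-case totals but not
its counting/discounting conventions or per-cycle item multiplicities.
`calibrate_conventions` recovers them deterministically in two stages:

1. **Conventions** (multiplicities do not affect QALYs): pick the
   (counting, discounting) pair minimizing the maximum relative deviation
   from the published per-arm and incremental QALYs. Winner: `half_cycle` +
   `annualized`, maximum QALY deviation 3.3%.
2. **Multiplicities**: cost is linear in the cycle cost and the complication
   cost (arm cost = W·cycle_cost + K·comp_cost with trace-derived discounted
   weights W, K), so a bounded integer grid (drug items in plausible dose
   counts, fees 0–4 per cycle) is searched exhaustively without rerunning
   the trace, by lexicographic minimax over the relative deviations of the
   four cost-side quantities (per-arm costs, incremental cost, ICER).

The bundled scenario ships with the calibrated configuration. Residual
deviations from the published totals:

| quantity | deviation |
|---|---|
| monotherapy QALY | −3.3% |
| combination QALY | −2.2% |
| incremental QALY | −0.7% |
| monotherapy cost | **−21.7%** |
| combination cost | −5.9% |
| incremental cost | +4.9% |
| ICER | +5.9% |

The monotherapy cost is **irreconcilable** with the rest of the publication:
under half-cycle counting the discounted stable-phase weight is ≈1.30
cycles, and the published cost items support a per-cycle cost of either
≈$1,854 (TAS-102 × 1 plus fees, total ≈$2,466, −28%) or ≈$3,688 (TAS-102
× 2, total ≈$4,786, +39%) — no integer multiplicity set lands within 10% of
$3,434.83 while the other three cost-side quantities fit within 6%. The
acceptance test asserting the published total therefore fails honestly; the
tolerance was not widened.

## Probabilistic sensitivity analysis

All tabulated parameters with non-zero ranges are resampled independently
per draw (the source states no correlation structure): probabilities and
utilities from beta distributions, costs from gamma distributions, both
moment-matched to mean = base and sd = (max − min)/3.92 (so the published
±25% range is an approximate 95% interval). Sampled transition rows that
would exceed probability 1 are renormalized proportionally and counted; the
bundled ranges never trigger this. Runs are deterministic given the seed
(default stored in the scenario).

With the bundled scenario and default seed, 97.8% of 1000 draws fall in the
northeast quadrant (more QALYs at higher cost) — slightly below the
published claim that *all* resamplings had a positive ICER, because the
overlapping ±25% death-probability ranges occasionally reverse the QALY
gain. The CEAC at $20,000/QALY is 0.387, not the published "approximately
50%": a base-case ICER near $22,800 (and even the published $21,554) sits
*above* $20,000, so an acceptability of ~50% at that threshold is internally
inconsistent with the publication's own ICER. Both discrepancies are
asserted as published in `tests/test_acceptance.py` and fail by design.

## Deterministic sensitivity analysis

One-way (tornado) analysis sets each parameter to its min and max with all
others at base and reranks by the induced ICER range. Stable-phase and
progressed-phase utilities move together with their complication twins, as
the published ranges tie them. The widest bars are the progressed-phase
utilities, both arms' progression→death probabilities and the combination
stable-state utility — consistent with the published finding that survival
and the combination's stable-state utility drive the result. A zero-range
parameter (e.g. an item with multiplicity 0) produces a zero-width bar.

## Verification

- **Closed forms** — geometric decay of the stable phase, expected
  time-in-state 1/p, full-horizon accrual of a static cohort, Table-level
  per-cycle QALY values.
- **Invariants** — probability conservation and non-negativity of the
  trace, monotone death occupancy, discounting monotonicity,
  complication-neutrality of QALYs (twins inherit parent utilities), ICER
  scale equivariance and antisymmetry, net-monetary-benefit ties at
  λ = ICER, CEAC normalization and monotonicity — checked on the bundled
  scenario and on 100 generated random scenarios.
- **Microsimulation oracle** — an independent per-patient simulation of the
  same transition matrix agrees with the cohort totals within 3 Monte-Carlo
  standard errors at 10⁵–1.5×10⁵ patients for both arms.
- **Determinism** — identical results for identical seeds across the base
  case, tornado and PSA.

## Limitations

- The model inherits the source analysis's structure: no treatment
  discontinuation separate from progression, death only via progression,
  exponential survival throughout, and a single complication bundle.
- The calibrated multiplicities are a best fit to internally inconsistent
  published totals, not a documented dosing schedule; the clinical schedule
  (TAS-102 twice, bevacizumab four times per 8-week cycle) yields costs far
  from the published totals under every convention.
- PSA parameters are sampled independently; correlated survival parameters
  would likely shrink the off-quadrant draw fraction.
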