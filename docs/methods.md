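# Methods

## Decision problem

Patients with completely resected gastrointestinal stromal tumours (GIST) at
high risk of recurrence can receive adjuvant imatinib (400 mg/day) for one or
three years, which delays metastatic recurrence, at a drug cost of roughly
111,000 THB per month. The package evaluates six strategies that differ in
adjuvant duration and in the treatment sequence after recurrence:

| option | adjuvant | recurrence during adjuvant | recurrence after adjuvant / no adjuvant |
|---|---|---|---|
| 1 (baseline) | none | — | imatinib → BSC |
| 2.1 | 1 year | BSC | imatinib → BSC |
| 2.2 | 3 years | BSC | imatinib → BSC |
| 3.1 | 1 year | sunitinib → BSC | imatinib → sunitinib → BSC |
| 3.2 | 3 years | sunitinib → BSC | imatinib → sunitinib → BSC |
| 4 | none | — | imatinib → sunitinib → BSC |

Outcomes are lifetime costs (THB, 2014 prices, societal perspective), life
years and QALYs, discounted at 3%/year, compared as incremental
cost-effectiveness ratios (ICERs) against the Thai willingness-to-pay ceiling
of 160,000 THB per QALY.

## Cohort model

A deterministic Markov cohort model with monthly cycles propagates a cohort
entering at age 60 with no recurrence. Although the decision problem is
usually drawn with three health states, treatment after recurrence depends on
adjuvant history, so the engine expands to eight states: four no-recurrence
states (never-adjuvant, on-adjuvant, completed, discontinued), three
recurrence states (one per treatment line) and death. Recurrence is assumed
metastatic and irreversible; death is absorbing.

Monthly transition probabilities are piecewise-constant in time since entry:
recurrence 0.0205 (months 1–12), 0.0154 (13–36), 0.0056 (37+); disease
death without recurrence 0.0017 / 0.0031 / 0.0028 / 0.0020 / 0.0038 at the
year-1/3/5/7/9 bands (each value held until the next reported year — the
simplest reading of values reported "at year k"). After recurrence, monthly
progression is 0.015 (imatinib) and 0.012 (sunitinib); monthly death is
0.0056 / 0.0289 / 0.0680 on imatinib / sunitinib / BSC.

The effect of adjuvant therapy is a hazard ratio on the recurrence
probability — 0.29 for the 1-year course and 0.133 for the 3-year course, the
latter an indirect (Bucher) combination of the 1-year-vs-none and
3-year-vs-1-year trial estimates (hazard ratios multiply; SEs add in
quadrature on the log scale). The ratio acts through the constant-hazard
transform p → 1 − (1−p)^HR and **only while the patient is taking the
drug**: after completion or early discontinuation the unmodified baseline
applies. Discontinuation hazards are duration-specific (1-year arm: 0.0136
then 0.0009 per month; 3-year arm: 0.0097 then 0.0028) and discontinued
patients who later recur follow the strategy's during-adjuvant pathway (they
stopped for intolerance, so re-exposure to imatinib is excluded).

### Mortality composition

Background all-cause mortality is combined multiplicatively (independent
competing risks) with disease-specific probabilities in every alive state.
In the recurrence states the chart-review year-banded disease mortality is
additionally combined with the treatment-specific probabilities. This
reading treats the banded schedule as applying to all patients without
*adjuvant* therapy rather than only to the no-recurrence state; it is the
package's default because it reproduces the published lifetime costs of four
of the six strategies within 0.6% (the no-recurrence-only reading inflates
them by 11–18%). `gist_death_in_recurrence: false` in the configuration
restores the narrower reading.

### Rewards and discounting

Monthly state costs stack drug cost (111,306 THB for imatinib in any state
that dispenses it; 82,173 THB for sunitinib, embedding its 4-weeks-on /
2-weeks-off schedule), treatment/monitoring cost, adverse-event cost (570
THB, on-adjuvant only) and direct non-medical cost (visit rate × 504 THB per
visit for travel, food and caregiver time). Utilities are 0.89 off drug
without recurrence, 0.79 on adjuvant imatinib, and 0.66 / 0.58 / 0.42 on
imatinib / sunitinib / BSC after recurrence. Rewards accrue to the state
occupied at the start of each cycle with no half-cycle correction; cycle t
(0-based) discounts by (1+r)^(−t/12). The horizon is 480 cycles (age 100);
residual alive mass (<1% at defaults) is reported on the trace.

Three monitoring-cost table cells are typographically ambiguous in the
source; the configuration carries both candidate parses and defaults to the
larger-mean reading (4213 / 7141 / 4247 THB per month), which is also the
clinically plausible one — recurrence monitoring should not cost a tenth of
the 2,758 THB/month charged without recurrence.

## Uncertainty

Every uncertain input carries a (mean, SE) pair and a distribution family
fitted by the method of moments — Beta for probabilities and utilities,
Gamma for costs and visit rates, Lognormal (moments matched on the natural
scale) for hazard ratios — because the evidence base reports means and SEs
only. Parameters with zero SE are fixed.

* **One-way analysis** moves each parameter to mean ± 1.96 SE on the natural
  scale, clipped to its support (the discount rate instead sweeps the 0–6%
  policy range), and records the deterministic ICER of option 2.2 vs 1 at
  both ends; bars sort by ICER range.
* **Probabilistic analysis** redraws all uncertain parameters independently
  (1000 iterations by default; a seed is always required), evaluates all six
  options per draw, and summarises cost-effectiveness acceptability curves
  on a WTP grid of 0–3,000,000 THB in 20,000-THB steps, splitting net
  monetary benefit ties equally. Independence extends to the bands of one
  probability schedule — a simplification; correlated draws would tighten
  the schedules' joint behaviour. If a sampled row's competing exits exceed
  one they are renormalised proportionally (a warning is emitted; at the
  default SEs this is vanishingly rare).
* **Threshold analysis** bisects on the imatinib tablet price in
  [1, 3659.40] THB, rescaling the monthly imatinib cost proportionally in
  every dispensing state (the price cut applies to the drug, not the
  indication), until the ICER of option 2.2 vs 1 is within 1e−6 of the WTP
  ceiling. Cohort traces are price-independent and are computed once.

## Synthetic inputs

The only input not reproducible from published tables is the Thai all-cause
life table. It is emulated by a Gompertz generator, q(age) = 1 − exp(−a·e^{b·age})
with defaults a = 4.0e−5, b = 0.092, giving q(60) ≈ 0.0099 and q(80) ≈ 0.061 —
the realistic range for an upper-middle-income country, and deliberately
*not* presented as Thai truth. Any real life table can be supplied as a CSV
(age, annual_qx). Annual probabilities convert to monthly via the
constant-hazard transform. With this stand-in, switching background
mortality off entirely moves option-1 discounted life expectancy by ≈13%,
so the stand-in shapes absolute survival modestly while disease-specific
mortality dominates; incremental results are even less sensitive.

Hand-checkable three-state miniatures (identity, two-cycle, discounting)
carry exact oracle totals, documented as fractions in-source, and anchor the
engine and accumulator tests to values computed by explicit loops.

## What the defaults reproduce, and what they do not

At the shipped defaults the deterministic model yields option-1 discounted
cost 2,748,649 THB (published 2,744,275), incremental discounted outcomes of
option 2.2 vs 1 of +1.22 LY / +1.12 QALY (published 1.23 / 1.16), ICERs of
1,606,870 THB/QALY for 2.2 vs 1 and 2,794,841 for 3.2 vs 2.2 (published
1,648,801 and 2,608,264), and the published dominance pattern (options 4,
2.1, 3.1 off the frontier). Two published quantities are *not* reproduced
within their tolerance and are reported as computed:

* the threshold price comes out at ≈360 THB per 400 mg rather than 288.
  Linearising ICER(price), the per-THB slopes of the two models agree, but
  the published analysis implies ≈39,000 THB of price-independent
  incremental cost whose source is not derivable from the published inputs
  (this model's is ≈2,000 THB);
* the probability that option 1 is cost-effective at 160,000 THB/QALY is
  ≈98% rather than the published 100%: in ~2% of draws a high year-1
  recurrence probability combined with slow progression on imatinib makes
  option 2.1 — which diverts early recurrences to inexpensive BSC — cheaper
  *and* more effective than option 1. This is a structural consequence of
  the history-dependent pathways, visible only in an implementation that
  keeps them distinct.

## Limitations

Individual-level heterogeneity, local (non-metastatic) recurrence,
high-dose imatinib rescue, parameter correlation, half-cycle correction and
budget impact are out of scope. Probabilities reported "at year k" are read
as piecewise-constant from year k to the next report; other band
conventions are defensible and contribute to the residual gap against the
published table. The Gompertz life table is a stand-in whose level (not
shape) was fixed a priori to a realistic q(60) ≈ 1%.
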