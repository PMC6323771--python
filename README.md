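# gist-cua

Cost-utility analysis of **adjuvant imatinib after resection of high-risk
gastrointestinal stromal tumours (GIST)** in the Thai setting: a
monthly-cycle Markov cohort model over six treatment strategies, with
deterministic ICER/dominance analysis, one-way (tornado) and probabilistic
sensitivity analysis, cost-effectiveness acceptability curves, and a
drug-price threshold solver.

The package is written for health-economics analysts and modellers: every
step — parameter handling with uncertainty distributions, the cohort engine,
discounted accumulation, the efficiency frontier, PSA/CEAC and the threshold
search — is an importable, tested library function, driven by numbered
narrative scripts under `analysis/` and a `gist-cua` command-line tool.

## The model in brief

A cohort of 60-year-olds with resected high-risk GIST occupies eight health
states (four no-recurrence states distinguishing adjuvant history, three
metastatic-recurrence states by treatment line, and death) over monthly
cycles to age 100. Adjuvant imatinib lowers the monthly recurrence
probability p through a hazard ratio, p → 1 − (1−p)^HR (HR = 0.29 for a
1-year and 0.133 for a 3-year course, the latter from a Bucher indirect
comparison: HR₃ᵧ,ₙₒₙₑ = HR₃ᵧ,₁ᵧ · HR₁ᵧ,ₙₒₙₑ), only while the drug is taken.
Strategies are compared by

ICER = (C_b − C_a) / (E_b − E_a)   [THB per QALY, both discounted at 3%/yr]

against the Thai willingness-to-pay ceiling λ = 160,000 THB/QALY, and by net
monetary benefit NMB = λ·E − C in the probabilistic analysis. All costs are
THB at 2014 prices. Full model documentation is in
[docs/methods.md](docs/methods.md).

## Worked example

```sh
python analysis/01_base_case.py
```

prints (abridged):

```
Efficiency frontier: options 1 -> 2.2 -> 3.2
  ICER option 2.2 vs previous frontier member: 1,606,870 THB/QALY
  ICER option 3.2 vs previous frontier member: 2,794,841 THB/QALY
Dominated options: 2.1, 4, 3.1
Option 2.2 vs option 1: +1.22 discounted LY, +1.12 QALYs, +1,801,838 THB
```

Three years of adjuvant imatinib followed by imatinib then best supportive
care on recurrence (option 2.2) buys about 1.1 discounted QALYs over current
practice, but at ~1.6 million THB per QALY — ten times the Thai ceiling — so
the no-adjuvant baseline remains the cost-effective choice. The remaining
drivers:

```sh
python analysis/02_owsa_tornado.py    # tornado: on-adjuvant utility dominates
python analysis/03_psa_ceac.py 1      # 1000-draw PSA: option 1 wins in ~98% of draws
python analysis/04_threshold_price.py # imatinib must fall to ~360 THB per 400 mg
```

Each script writes its tables under `results/`. The same computations are
available as a CLI:

```sh
gist-cua run --out results
gist-cua psa --out results --seed 1 --n 1000
gist-cua owsa --out results
gist-cua threshold --out results
gist-cua export-params --out results/parameters.csv
gist-cua make-lifetable --out results/lifetable.csv
```

All inputs live in a YAML configuration (see
`gist_cua.fixtures.default_parameter_file()`), including both parses of the
typographically ambiguous monitoring-cost cells and switches for background
mortality. The Thai life table is emulated by a Gompertz stand-in
(q(60) ≈ 1%/yr); pass any real table with `--lifetable age,annual_qx.csv`.

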