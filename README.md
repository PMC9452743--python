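# cardiocea

A Markov cohort decision model for the cost-effectiveness of **proton versus
photon breast irradiation** when the goal is minimizing radiation-induced
**ischemic heart disease (IHD)**.

Incidental heart exposure during breast radiotherapy raises the lifetime risk
of IHD roughly linearly with mean heart dose (MHD) — an excess relative risk
of about **7.4% per Gy** — with the patient's preexisting cardiac risk acting
as the base. Intensity-modulated proton therapy keeps the MHD near 0.5 Gy but
costs several times more than photon irradiation. This package is for health
economists and radiation oncology groups who want to quantify that trade-off:
it prices the avoided cardiac risk in quality-adjusted life-years (QALYs) and
dollars, and maps out which patients — by age, photon MHD, and
cardiac-risk-factor (CRF) burden — protons are cost-effective for.

## The model

A closed cohort starts 100% healthy at the end of radiotherapy and cycles
annually to age 80 through five states: *healthy*, *non-fatal IHD*, and three
absorbing states (*IHD death*, *cancer death*, *other death*). Per-cycle
transition probabilities are built from:

- a baseline annual IHD-death curve q(a) by attained age (no radiotherapy,
  no CRFs), scaled by the dose-response RR(MHD) = 1 + 0.074·MHD, a
  preexisting-risk multiplier m, and a calibration scalar s_death;
- non-fatal IHD incidence tied to the scaled death hazard by an age-banded
  ratio (5×/4×/2×/1× below 50 / 50s / 60s / 70+) with its own scalar
  s_nonfatal;
- a 6% five-year background cancer mortality (first five cycles only);
- all-cause female life-table mortality for competing "other death".

The two scalars are **calibrated by bracketed root searches of the full
cohort model** so the cumulative IHD-death and total-IHD incidences at age 80
hit stated targets exactly (to 1e-9) — for the reference 50-year-old:
2.0%/4.6% at the 0.5 Gy proton dose and 2.7%/6.1% at the 5 Gy photon dose.
Costs (radiotherapy, one-time percutaneous coronary intervention, $2,000/yr
IHD care, $1,000/yr follow-up) and utilities (0.95 healthy, 0.695 non-fatal
IHD) are accumulated with half-cycle correction and discounted at 3%/yr; the
headline statistic is the incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY (protons vs photons), judged against willingness-to-pay
(WTP) thresholds of $37,653, $50,000 and $100,000 per QALY.

On top of the engine sit a probabilistic sensitivity analysis (uniform costs,
beta utilities, 50,000 iterations), a tornado (one-way) analysis over the
PSA's 90% intervals, a patient-level microsimulation oracle that validates
the cohort algebra, and a threshold module that finds the **minimum photon
MHD at which protons become cost-effective** for each (age, risk level,
proton cost, WTP) cell — green if ≤ 5 Gy, yellow if 6–16 Gy, gray if never.

All inputs load from plain CSVs or are generated synthetically (exponential
age-increasing risk curve, Gompertz life table, Framingham-anchored strata
table), so the whole pipeline runs and is tested with no downloads.

## Worked example

Price the reference comparison — a 50-year-old without CRFs, 5 Gy photon MHD
vs 0.5 Gy proton MHD, proton cost $50,000:

```sh
cardiocea run
```

prints (abridged):

```json
{
  "cea": {
    "delta_cost": 37857.93109313354,
    "delta_qaly": 0.052315792933500305,
    "icer": 723642.4981889416,
    "label": "icer",
    "cost_effective_at": {"37653.0": false, "50000.0": false, "100000.0": false}
  }
}
```

Protons buy 0.052 QALY for an extra $37,858, an ICER of ~$724k/QALY — far
above every WTP threshold, so protons are *not* cost-effective for this
low-risk patient. (The exact ΔQALY depends on the age-shape of the annual
risk curve; see `docs/methods.md` for what the synthetic default does and
does not represent.) The risk-stratified picture changes the verdict:

```sh
cardiocea grid --out grid.csv --crf-out crf.json   # 432-cell threshold grid
cardiocea psa --n-iter 50000 --out psa.csv         # probabilistic SA
cardiocea tornado --out tornado.csv                # one-way SA, widest first
```

Other subcommands: `fixtures` (write the synthetic input CSVs), `calibrate`
(report the calibration scalars). Every command takes `--config config.yaml`
(schema-validated; unknown keys rejected) and writes a config hash into its
artifacts so identical configs give byte-identical outputs. Supplying
`inputs.risk_curve_csv` / `inputs.life_table_csv` switches from the synthetic
stand-ins to user data.

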