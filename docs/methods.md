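# Methods

## Model structure and assumptions

The model is a five-state annual-cycle Markov cohort: HEALTHY,
NONFATAL_IHD, and absorbing IHD_DEATH, CANCER_DEATH, OTHER_DEATH. A cohort
of women begins 100% healthy at the end of breast radiotherapy (age 40, 50
or 60) and is cycled to age 80 ("horizon − start age" cycles). From HEALTHY
a patient may move to any other state in a cycle; from NONFATAL_IHD only to
the death states (no second non-fatal event, no recovery); transitions
within a cycle are simultaneous (a single row of competing probabilities, no
intra-cycle sequencing). Assumptions carried by the structure:

- the only difference between strategies is cardiac: tumour control, other
  toxicity and the background mortality streams are identical;
- proton MHD is fixed (default 0.5 Gy); photon MHD is the scenario variable;
- the IHD risk of the non-irradiated breast-cancer population equals that of
  the general female population.

## Hazards

Annual IHD-death probability at attained age a:

    p_death(a) = min( m · RR(MHD) · s_death · q(a), 0.999 )

with RR(MHD) = 1 + err_per_gy·MHD (default err_per_gy = 0.074 /Gy), m the
preexisting-risk multiplier (m = 1 is the no-risk-factor base), and q(a) the
baseline curve. The default combination is **linear on the annual
probability**, matching the linear risk statement of the dose-response
source; a hazard-rate variant 1 − (1−q)^(m·RR·s) is selectable
(`scaling_mode="hazard_rate"`) since the underlying excess relative risk is
rate-based. The two differ only at second order for the probabilities
involved here. Multiplication is commutative so the order of m, RR, s is
immaterial; the clamp is applied last.

Non-fatal IHD incidence is ratio(a) · s_nonfatal · p_death(a) with the
age-banded ratio 5/4/2/1 for ages <50, 50–59, 60–69, ≥70. The source prints
the fourth band ambiguously; ≥70 is the only non-overlapping reading and is
used. The ratio is age-only — m does not scale the non-fatal:fatal mix.

Background cancer mortality: the 6% five-year cumulative rate is converted
to a constant annual probability 1 − 0.94^(1/5) ≈ 0.0123 applied in the
first five cycles only, from both alive states. Other-cause mortality is the
life-table qx used directly; `subtract_ihd_from_other=True` optionally
removes the baseline IHD component from qx to avoid double counting (off by
default — the competing-risk overlap at these magnitudes is ~1e-4 and the
source analysis gives no subtraction procedure).

## Calibration

Two scalars are fitted sequentially by bracketed Brent root searches on the
full cohort model (bracket [1e-6, 1e3], monotonicity asserted, tolerance
1e-9 on cumulative probability): s_death pins cumulative IHD-death occupancy
at the horizon to its target; then s_nonfatal pins deaths + incident
non-fatal events to the total-IHD target. The searches decouple because the
death hazards from HEALTHY and NONFATAL_IHD are identical. Two modes:

- **per_strategy** (default): each arm calibrated to its own dose-specific
  targets at its own dose — the reproduction mode for the reference
  comparison, where both target pairs are published (2.0/4.6% at 0.5 Gy,
  2.7/6.1% at 5 Gy for the 50-year-old);
- **at_zero_dose**: one calibration at 0 Gy against back-transformed targets
  (anchor targets divided by RR at the anchor dose), with RR applied on top
  for any dose — the mode for dose/risk sweeps and threshold grids, where
  no per-dose targets exist.

## Accounting

QALYs and costs are accumulated per cycle with trapezoidal half-cycle
correction (state membership = the mean of the cycle-start and cycle-end
occupancies) and mid-cycle discounting (1+r)^−(t−0.5), r = 3%/yr. The
radiotherapy cost is booked at t = 0 undiscounted; the PCI cost attaches to
the incident non-fatal flow in its cycle; IHD care ($2,000/yr) accrues in
NONFATAL_IHD and follow-up ($1,000/yr) in both alive states, with the QALY
weights. Because both outputs are linear in the unit costs and utilities,
the trace collapses to a small set of sufficient statistics
(`AccumulationCoefficients`); the deterministic accumulator and the PSA
evaluate through the same object, so they cannot diverge.

Decisions at a willingness-to-pay λ use net monetary benefit λ·ΔE − ΔC ≥ 0,
which is well-defined in every quadrant of the cost-effectiveness plane;
the ICER itself is reported when ΔE > 0, with standard dominance labels
otherwise.

## Sensitivity analyses

PSA: each unit cost is drawn from Uniform(base·(1−w), base·(1+w)) and each
utility from a Beta with mean = base and SD = f·base (method-of-moments
shapes; an error is raised if the SD is infeasible for the mean). The
spreads are configuration because the source analysis never states them;
defaults w = 0.25 and f = 0.10. A documented setting w = 0.2875 reproduces a
proton-cost 90% interval of ≈(37,063; 62,938) around $50,000, matching the
published tornado endpoints. 90% intervals are empirical 5th/95th
percentiles over 50,000 iterations by default; a fixed seed makes the table
reproducible. The tornado re-evaluates the ICER one parameter at a time at
the bounds of these intervals and sorts by descending span.

## Thresholds and grids

The minimum cost-effective photon MHD solves NMB(MHD) = 0 on [1, 16] Gy by
Brent's method on the continuous dose axis — NMB is increasing in dose,
which is asserted from the bracket endpoints — then ceils to the integer
grid (with a local verification step so the result provably equals an
exhaustive integer scan). Cells are green (≤5 Gy), yellow (6–16 Gy) or gray
(not cost-effective within 16 Gy); a CRF stratum joins the "cost-effective
group" when its threshold is ≤ 5 Gy. The risk axis scales the baseline
annual hazards uniformly; because cumulative incidence is sub-linear in a
hazard multiplier, the implied lifetime-risk ratio is reported alongside
each grid row so results can be read on either axis.

## Synthetic study conditions

The generators replace three data objects that are not redistributable here:

- **Risk curve** q(a): exponential in age, q(a) = k·d^((a−start)/10) with
  d = 2 per decade by default, k solved so the product-complement cumulative
  incidence hits a stated target to 1e-10 (annual probabilities capped at
  0.999, beyond which a target is reported infeasible). Real IHD mortality
  rises steeply with age; d is configurable and the absolute level is
  irrelevant after calibration, but the *slope* controls event timing and
  therefore discounted incremental QALYs.
- **Life table**: Gompertz qx(a) = a₀·e^(b·(a−start)), default a₀ = 0.0016
  at age 40 and b = 0.082 — a fit to recent US female all-cause mortality
  (q ≈ 0.0016 at 40 rising to ≈ 0.042 at 80).
- **Strata table**: lifetime IHD risk to 80 for 50-year-old women anchored
  on the published Framingham figures (8.2% all-optimal, 20.5% overall,
  40.2% for ≥2 major CRFs, 57.3% for diabetes as a lower bound); the
  single-factor hypertension/cholesterol/smoker entries are synthetic
  fill-ins respecting the published qualitative ordering, and the same risk
  set is reused at index ages 40 and 60.

What passing tests therefore show: the engine, calibration, accounting,
sensitivity and threshold machinery are correct against closed forms,
brute-force scans and a microsimulation oracle, and the calibrated model
reproduces any stated cumulative incidences exactly. What they do not show:
agreement of absolute incremental QALYs with analyses built on the real
annual-risk and life tables — event *timing* depends on the true age-slope
of the risk curve, which no printed summary pins down. Under the synthetic
defaults the reference comparison yields ΔE ≈ 0.052 QALY (published
analyses with the original tables report ≈ 0.043); supplying the original
tables as CSVs restores exact-reproduction mode.

## Numerical choices and degenerate inputs

- Cohort conservation is asserted at 1e-12; absorbing occupancies are
  checked non-decreasing; incident flows must integrate to final absorbing
  occupancy.
- Exit probabilities summing to ≥1 from an alive state raise a hazard
  overflow error naming the age rather than renormalizing silently.
- A total-IHD target equal to the death target calibrates s_nonfatal to 0.
- Degenerate PSA spreads (w = 0 or f = 0) reproduce the deterministic
  result bit-for-bit.
- Threshold queries where even 16 Gy is not cost-effective return "none"
  (gray); a non-monotone NMB bracket raises a diagnostic error rather than
  returning a silently wrong dose.
- Problem sizes used by the test-suite oracles: 200,000 microsimulated
  patients (agreement within 3 standard errors), 50,000 PSA iterations
  (uniform percentiles within 0.5% of closed form), 20 randomized threshold
  queries cross-checked against exhaustive scans, and 432-cell default
  grids.

## Known limitations

Cardiac substructure doses (left anterior descending artery, ventricle) are
not modelled — mean heart dose is the only dosimetric input. No tunnel
states for post-event risk escalation, no repeat PCI, no cause-specific
life-table adjustment beyond the optional IHD subtraction. Ages outside
40–60 and horizons beyond 80 are parameterizable but unvalidated. The
female-only life table and the Framingham strata limit generalization to
male breast cancer and to populations with different background risk.
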