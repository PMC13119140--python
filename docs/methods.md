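# Methods

## Model

The static drug–drug interaction (DDI) model relates the victim drug's AUC
ratio to two scalars: CR, the fraction of the victim's oral clearance
carried by the affected CYP, and the perpetrator's time-integrated potency —
IR ∈ [0, 1] for inhibitors, IC ≥ 0 for inducers:

    AUCR = 1/(1 − CR·IR)   (inhibition)      AUCR = 1/(1 + CR·IC)   (induction)

Extrapolation to a pediatric age rests on two empirical corrections applied
to CR only:

* **Ontogeny.** The affected pathway's intrinsic clearance is scaled by
  Z_ontogeny(age), an Emax-type maturation curve
  `Z = (A − B)·age^h/(age50^h + age^h) + B` with isoform-specific birth
  fraction B, adult asymptote A, half-maturation age age50 (years) and Hill
  coefficient h:

  | isoform   | A     | B    | age50 | h    |
  |-----------|-------|------|-------|------|
  | CYP1A2    | 1.05  | 0.08 | 1.69  | 1.1  |
  | CYP2B6    | 1.0   | 0.1  | 1.0   | 1.0  |
  | CYP2C9    | 1.0   | 0.17 | 0.016 | 0.53 |
  | CYP2C19   | 1.0   | 0.3  | 0.28  | 2.44 |
  | CYP3A4/5  | 1.061 | 0.0  | 0.66  | 0.78 |

  The CYP3A4/5 asymptote 1.061 is the global maximum of Z. Enzymes outside
  this table are refused rather than assumed mature: silently setting Z = 1
  for, say, CYP2D6 would fabricate a prediction the framework cannot
  support.

* **Allometry.** Total (hepatic) clearance is scaled by
  `W = (WT_ped/WT_adult)^0.75`. Pediatric weight defaults to the Luscombe
  weight-for-age rule `WT_ped = 3·age + 7` kg; an observed weight may
  override it. The adult reference weight is 70 kg — the conventional
  reference adult, which also exactly regenerates the packaged CYP3A4
  validation predictions. Both the exponent and the adult weight are
  configurable.

Because IR/IC are taken as age-invariant (perpetrator potency mainly
reflects molecular affinity), CR·IR cancels and the pediatric prediction
needs only the adult AUCR:

    AUCR_ped = 1/(1 − (Z/W)·(1 − 1/AUCR_adult))

The inhibition and induction forms of this equation are algebraically
identical, so a single implementation serves both; a test certifies their
equality to 1e−12 over 10,000 random parameter tuples. Three approaches
fix (Z, W): A = (1, 1) (direct carry-over), B = (Z, 1), C = (Z, W).

Note the shape of the combined correction: Z/W peaks near age 1.5 y —
ontogeny matures faster than body size grows — and then falls toward 1, so
Approach C predictions for an inhibition DDI are largest in toddlers and
decay toward the adult value through adolescence. They are *not* monotone
from birth.

## Parameters and defaults

| parameter            | default | meaning                                          |
|----------------------|---------|--------------------------------------------------|
| adult_weight_kg      | 70      | reference adult weight in W                      |
| allometric_exponent  | 0.75    | clearance allometry exponent                     |
| guest_delta          | 1.25    | tightness of the Guest acceptance interval       |
| rounding_decimals    | 2       | precision of published-value comparisons         |

Ages are decimal years; the age grammar accepts points and ranges in years
(`y`, default), months (`m`, /12) and weeks (`w`, /52 — adequate for data
carrying two significant figures). A unit trailing a range with none on the
first bound applies to both bounds ("10-108 m"); otherwise each bound
carries its own unit ("2 w-7.8 y"). Ranges resolve to the midpoint; a
per-record `age_override_years` column lets users substitute e.g. a cohort
mean age.

## Validation dataset

The packaged table holds 25 victim–perpetrator cases (14 CYP3A4, 5 CYP1A2,
2 each CYP2B6/CYP2C9/CYP2C19) with observed pediatric and adult AUCRs and
the originally published predictions of the three approaches, transcribed
verbatim (including the original "Etopside" spelling). These are clinical
patient data: observed values fold in disease status and co-medication,
which the model does not represent. Passing the validation suite therefore
shows the implementation reproduces the published analysis of this dataset,
not that the model is unbiased for new populations.

## Performance metrics

* GMFE = exp(mean |ln(pred/obs)|) — absolute-log folding; always ≥ 1.
* MAPE = 100·mean(|pred − obs|/obs).
* Two-fold criterion: pred/obs ∈ [0.5, 2.0], boundaries inclusive.
* Guest limits: with R = max(obs, 1/obs), L = (delta + 2(R − 1))/R and
  acceptance iff 1/L ≤ pred/obs ≤ L. delta = 1.25 is the
  bioequivalence-variability variant; delta = 1 the strict one (at obs = 1
  it degenerates to requiring exact prediction).
* OLS of predicted on observed, unweighted with intercept
  (scipy.stats.linregress).

`evaluate` runs either **printed** mode (the stored predictions, i.e. the
published analysis) or **recompute** mode (predictions regenerated from
adult AUCR, isoform and canonical age), and always attaches a
reproducibility audit: rows whose recomputed prediction, rounded to the
table's two decimals, differs from the stored one by more than 0.01.

## Reproducibility of the published analysis

What recomputation from the two-decimal table reproduces exactly:
Approach A OLS slope 0.2052 / intercept 0.9259; GMFE 1.41 (A), 1.42 (B),
1.36 (C); MAPE 34.23% (A), 34.91% (B), 35.61% (C); counts outside the
two-fold range 3/3/1 for A/B/C. The single-age CYP3A4 rows regenerate their
stored Approach B and C predictions from the equations with the defaults
above (one stored B value, 1.44 for a carbamazepine–erythromycin row at age
9, is a rounding slip: an identical row prints 1.45, the value the equation
gives).

What does not reproduce, and is surfaced by the audit instead of imitated:

* All stored CYP1A2 predictions behave as if 1 − Z had been used in place
  of Z; the implementation follows the equations as written.
* The stored CYP2C9 phenytoin rows are unreachable from the CYP2C9 curve at
  any age in the stated ranges (its near-zero age50 makes Z ≈ 1 beyond
  infancy; combined with allometry the recomputed Approach C values are far
  larger).
* The stored CYP2C19 rows equal 1.00 for both corrected approaches, which
  the equations do not give.
* Some range-age rows (bupivacaine–diazepam, digoxin, etoposide) match an
  age other than the midpoint.
* The Approach B/C slopes recompute to 0.1888/0.5391 vs the published
  0.1909/0.5382 — second-decimal sensitivity of OLS to the two-decimal
  rounding of the table.
* The published Guest counts (13/25, 15/25, 10/25) are not recoverable for
  any delta tried (1.25 gives 7/7/6; 1.0 gives 14/15/13); the Guest count
  is reported for a configurable delta and never asserted against those
  numbers.

## Numerical choices

* Full float precision throughout; rounding (half away from zero, via
  `decimal`) only when comparing against printed two-decimal values.
* Domain guard: `(Z/W)(1 − 1/AUCR_adult) ≥ 1` raises a typed
  `ModelDomainError` (the corrected model would predict non-positive
  clearance) instead of returning a negative or infinite AUCR.
* Corrected CR above 1 is returned unclamped with an `OutOfFractionWarning`;
  clamping would silently change predictions.
* The inverse mapping (pediatric → adult AUCR) is exact algebra but
  ill-conditioned as Z → 0, where the forward map collapses to 1; round-trip
  accuracy of 1e−9 holds for Z ≳ 1e−3, the whole physiological range.
* Ages above 25 y are accepted (one validation cohort reaches 20.7 y) with
  a log warning, since the maturation curves are then pure extrapolation.
* Age 0 is the exact limit value of each curve (all Hill exponents are
  positive, so no 0^0 arises).

## Limitations

Empirical, dataset-dependent corrections — not a mechanistic (PBPK) model:
no gut/hepatic separation, no time-varying perpetrator exposure, no
multiple perpetrators or transporter effects, no disease adjustments, and
IR/IC fixed at adult values. The validation set is small (n = 25) and
heterogeneous; metrics computed from it carry that uncertainty.
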