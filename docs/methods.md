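# Methods

## The surface model

The package estimates a patient's total peritoneal surface area (PSA) from
anthropometry and tracks how cytoreductive surgery (CRS) reduces it.

**Body surface area.** The DuBois–DuBois formula

    BSA (m²) = 0.20247 · height(m)^0.725 · weight(kg)^0.425

is the only BSA model in scope. Patient entry is in centimetres (the
clinical convention); the conversion to metres happens inside
`compute_bsa`, so a silent 100× unit error cannot occur at the call site.
The formula itself only requires positive inputs; the plausibility gate
(height 100–250 cm, weight 20–300 kg, overridable with
`check_bounds=False`) lives on `PatientRecord`, where a transposed
height/weight must fail loudly during intraoperative entry.

**BSA → PSA.** The total PSA is taken equal to the BSA expressed in cm²
(`psa_total_cm2 = bsa_m2 × 10,000`). Anatomical estimates support treating
BSA as a usable proxy for the peritoneal membrane area; whether a
correction factor ≠ 1 would be more faithful is an open empirical question,
and the identity is implemented as the model states it.

**The 40-region partition.** The peritoneum is decomposed into 40 named
regions in four groups — supramesocolic visceral (SMCVP, 16), supramesocolic
parietal (SMCPP, 6), inframesocolic visceral (IMCVP, 12) and inframesocolic
parietal (IMCPP, 6). Each region i carries a fractional contribution X_i
(percent of total PSA); the fractions must sum to 100 within tolerance.
The canonical listing fixes a stable index 1–40 (group by group, in reading
order) used by all matrix exports, and region names are keyed by a slug
canonicalization (lowercase, strip punctuation/diacritics, hyphenate) so
that punctuated anatomical names survive file round-trips.

No numeric X_i values are shipped as clinical truth: published per-region
fraction tables exist in the anatomical literature but are transcription
inputs, not package defaults. The bundled `uniform_fractions.csv`
(2.5% each) is explicitly a non-clinical placeholder for tests and demos;
`region_fraction_template.csv` is the blank form a user fills from their
chosen source. Sum-to-100 validation uses 1e-6 percentage points in strict
mode and 0.5 points in lenient mode, because published tables are rounded
to one or two decimals and would otherwise fail spuriously.

**Resection arithmetic.** The surgeon enters, per region, the resected
share y_i ∈ [0, 100] of that region (0 = untouched, 100 = completely
resected; unlisted regions default to 0). Then

    area_before_i   = PSA_total · X_i / 100
    area_after_i    = area_before_i · (1 − y_i/100)
    area_resected_i = area_before_i − area_after_i

and patient totals are sums over regions. One modelling choice deserves
a note: an alternative reading would treat the entered percentages as
contributions relative to *total* PSA rather than to the region. That
reading breaks at the boundary — entering 100% everywhere would not drive
the remaining PSA to zero — so the per-region interpretation is used; it is
the only one under which "complete peritoneal resection" empties the
surface and the resected total is always non-negative.

The surface ratio is reported as 100·PSA/BSA (percent). A literal
transcription of the published ratio arithmetic divides by 100 instead,
yielding 0.01 for an intact peritoneum; that variant is kept behind
`as_printed=True` purely for auditability.

Reports are recomputed from scratch on every entry edit (last-write-wins):
the arithmetic is trivial, and full recomputation guarantees the
conservation invariants after any edit sequence. All areas are carried at
full double precision; rounding to whole cm² happens only in the
human-readable rendering.

## Cohort statistics

The cohort matrix is region × patient with resected areas (cm²) as cells,
so each column sums to that patient's resected total — the numeric
counterpart of the published resection heatmaps. Summaries report the
sample mean, sample SD (n−1) and SEM, all labeled; SD and SEM are easily
conflated in clinical tables, so both are computed. At n = 1 the SD is
reported as absent rather than 0 — a silent zero would corrupt downstream
pooling.

The before/after comparison defaults to the **unpaired pooled-variance
Student's t-test**, replicating the analysis convention of the clinical
literature this tool serves, even though before/after measurements on the
same patients are intrinsically paired; a warning is logged when the
unpaired default meets equal-length groups, and both `paired=True` and
`welch=True` are exposed. The tests themselves are delegated to
scipy.stats; independent textbook-formula oracles verify them in the test
suite.

## The Dedrick two-compartment model

The transfer of drug from the peritoneal cavity to the blood follows
Fick's law: rate = PA·(C_P − C_B), with PA = P·A the permeability–area
product. The rate law alone cannot be simulated, so the package extends it
to the minimal dynamic system:

    dC_P/dt = −(PA/V_P)(C_P − C_B)
    dC_B/dt = +(PA/V_B)(C_P − C_B) − k_e·C_B,   C_P(0) = dose/V_P, C_B(0) = 0

The initial conditions, the first-order elimination term k_e and the AUC
outputs are extensions beyond the bare rate law, and are labeled as such.
Assumptions: both compartments well mixed, constant volumes, linear
(concentration-independent) permeability, no tissue binding or penetration
depth, no thermal effects of hyperthermia.

**Units.** P in cm/min, A in cm², volumes in L, concentrations in mg/L,
time in min. The cm³→L factor (1/1000) is applied exactly once, where PA
enters the ODE; the unit convention string is embedded in every output.
No drug-specific permeability is shipped as a default — published values
vary by agent — so example configs carry clearly illustrative numbers.

**Integration.** The system is linear and non-stiff, so a fixed-step
classical RK4 integrator (default step 0.1 min) is used instead of an
adaptive solver: it is deterministic, step-convergence is testable, and
the result can be compared directly against the closed-form
double-exponential solution, which serves as the independent oracle in the
tests (mass conservation and closed-form agreement hold to better than
1e-9 relative at the default step; the acceptance tolerance is 1e-6).
AUCs are accumulated as auxiliary quadrature states inside the same RK4
step, so they carry fourth-order accuracy rather than trapezoid error.
The half-equilibration time (first time the C_P−C_B gap falls to half its
initial value) is located by linear interpolation on the output grid and
reported as absent for a sealed membrane (PA = 0) or when the horizon is
too short.

`psa_sensitivity` re-runs the scenario over a grid of remaining-PSA
values: more remaining surface equilibrates faster, and with k_e > 0 it
drains peritoneal exposure (AUC_P decreases) while feeding the systemic
compartment — the quantitative form of the dose-adjustment argument.

## Synthetic cohorts

The generator emulates the statistical *shape* of an adult CRS/HIPEC
cohort, not any specific published dataset (the clinical series this kind
of tool was evaluated on is unpublished, and so are the clinical X_i
fractions):

- height ~ N(170, 10) cm and weight ~ N(78, 15) kg, truncated to the
  plausibility bounds by exact rejection sampling — plausible adults whose
  BSA lands in the ~1.5–2.5 m² range;
- resection is two-part (zero-inflated) per region: Bernoulli(any
  resection, per-group probability) × 100·Beta(2, 2) for the extent given
  resection. Defaults {SMCVP 0.2, SMCPP 0.4, IMCVP 0.3, IMCPP 0.6} follow
  the clinical ordering that inframesocolic parietal peritonectomy is
  relatively most extensive and supramesocolic visceral least. The
  two-part model reproduces the many-zeros-sparse-large-values texture of
  real resection heatmaps and exercises the sparsity paths of the cohort
  matrix.

All draws come from one `numpy.random.default_rng(seed)` (PCG64), so a
fixed seed reproduces a cohort bit-for-bit across platforms.

What passing tests on synthetic cohorts do **not** show: agreement with
any real cohort's means, realistic correlation between anthropometry and
resection extent (none is modelled), surgeon-dependent estimation bias, or
clinical validity of the placeholder fraction table.

## Problem sizes

The test suite and the acceptance script use 1,000 randomized
registry/patient/resection triples for the conservation sweep, 100 random
vectors for the t-test oracle, a 3×3×3 scenario grid at step 0.1 min over
60 min for the PK checks, and n = 10,000 patients for the generator's
binomial contract — sizes at which every check is statistically meaningful
while the whole suite runs in seconds.

## Known limitations

- The BSA = PSA identity ignores body-composition effects on the
  peritoneal membrane; obese and cachectic extremes are least well served.
- Region fractions are static inputs; no imaging-derived personalization.
- No peritoneal regrowth, adhesion or partial-thickness modelling; no PCI
  scoring.
- The PK model is the minimal linear two-compartment system: no
  distributed/PBPK structure, no temperature dependence, no nonlinear
  binding.
- Percent-entry granularity is continuous; the tool does not model
  surgeon estimation error, which dominates real-world variance.
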