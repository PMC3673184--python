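# Methods

## The problem

Urinary cadmium normalized to creatinine (U-Cd, µg/g creatinine) is a marker
of cumulative lifetime cadmium exposure: the kidney accumulates cadmium over
decades and releases it into urine slowly. Given group geometric-mean (GM)
U-Cd values from population biomonitoring — here a low-exposure urban group
(Bangkok, n = 399) and a high-exposure rice-farming group (Mae Sot district,
n = 6,747), stratified by sex, age band and smoking category — the package
inverts a lifetime toxicokinetic model to estimate the external doses behind
the biomarker: dietary cadmium intake (µg/day) for never smokers, and
smoking rate (packs/day) for current smokers on top of their dietary
background. The estimates are then compared with the WHO tolerable intake
(25 µg/kg bw/month, 62 µg/day at 70 kg; urinary threshold 5.24 µg/g
creatinine) and the EFSA tolerable intake (2.5 µg/kg bw/week, 25 µg/day;
urinary threshold 1 µg/g creatinine).

## The toxicokinetic model

The simulator is a linear multi-compartment disposition scheme in the
classic cadmium-kinetics tradition: a fast blood uptake pool (B1), a bound
blood pool (B2), a systemic blood pool (B3), liver (L), kidney (K) and a
lumped "other tissue" pool (T), with urinary, fecal and exhaled elimination.
All transfers are first-order daily fractions (day⁻¹); the state is advanced
with explicit daily difference equations,

    s(t+1) = A s(t) + b(t),

where `A` is the (column-stochastic over body compartments plus elimination
sinks) daily update matrix and `b(t)` deposits the day's absorbed intake.
Route handling: a fraction `absorption_gut` (0.05 males, 0.10 females —
females absorb more, consistent with lower iron stores) of cadmium reaching
the gut enters B1 and the rest passes to feces; of inhaled cadmium, a
fraction `absorption_lung` (0.10) is absorbed, `mucociliary_to_gut` (0.40)
is swallowed and subjected to gut absorption, and the remainder is exhaled.

Consequences of this construction, all enforced by tests:

- **Exact mass conservation** — every microgram of intake is, after each
  step, in a compartment or a cumulative sink (relative error ≤ 1e-9,
  typically ~1e-15).
- **Exact homogeneity of degree 1** — doubling the exposure series doubles
  every burden and every U-Cd value to floating-point precision. This makes
  reverse dosimetry a division rather than a search.
- **Monotone accumulation** — under constant adult intake, U-Cd rises
  steadily with age through at least age 60, the qualitative pattern the
  biomarker is known for.

U-Cd on a given day is that day's urinary excretion divided by an age- and
sex-specific daily creatinine excretion (piecewise linear: male plateau
1.5 g/day at ages 20–50 declining to 1.0 at 80; female 1.0 declining to 0.7;
childhood ramp from 0.2 g/day). The U-Cd "at age a" is the mean over the
final 365 simulated days, which removes day-granularity artifacts.
Dietary intake is specified at the adult level and scaled through childhood
by a caloric-intake multiplier (0.3 at birth rising linearly to 1.0 at 18).

### Coefficient choices

The coefficient values of the original published model family are not
publicly printed, so the shipped catalogue (`data/default_params.yaml`) is a
literature-shaped set chosen by structural reasoning, not fitted to any test
outcome:

- kidney elimination `k_KU = 1e-4/day` (≈ 19-year half-life), with a small
  kidney→blood recycling term;
- the liver takes the largest share of the fast pool's outflow and releases
  slowly (`k_LB3 = 1e-4/day`), acting as a delayed feed into the kidney —
  this two-stage (liver→blood→kidney) chain is what sustains the age rise of
  U-Cd into late adulthood;
- a slow "other tissue" depot (return time ~90 years);
- direct filtration to urine (`k_B3U`) kept small so that the kidney
  dominates urinary output, as is physiologically expected;
- at steady state well over half of the body burden sits in kidney + liver
  (≈ 88% at age 50 under constant intake).

Because absolute levels under such a set cannot be trusted, **no
quantitative claim is made before anchoring**: for each (locality, sex)
group the model's output scale is calibrated on one published
(intake, U-Cd) pair — the 20–39-year never-smoker cell — after which other
age bands and the smoker groups are genuine predictions. The anchored model
reproduces the published 40–59 never-smoker intake calibrations within
~3–10% (e.g. Bangkok males 51 vs 50 µg/day; Mae Sot males 200 vs 188
µg/day); agreement at the tens-of-percent level is the honest expectation
given the unpublished original coefficients.

## Reverse dosimetry

By linearity, a group's predicted U-Cd at its evaluation age is
`gain × intake` (diet) or `U_diet + g_smoke × packs` (smoking), where the
gain is obtained from one unit-intake forward run (memoised per age and
sex). Calibration inverts these relations in one step and then *verifies*
the result with an actual forward simulation at 1e-6 relative tolerance; a
bisection fallback (100 steps on [0, 10× the linear estimate]) covers any
future nonlinear model variant, but never fires for the linear model. Age
bands are evaluated at their midpoints (16, 30, 50, 70) — the symmetric
choice, since the original evaluation ages are unstated. Table outputs are
rounded to the published granularity (integer µg/day; 0.1 packs/day), exact
values are kept alongside.

Smokers are assumed to share the never smokers' dietary intake of the same
band (the source analysis's own stated assumption), to smoke a constant
amount from age 18 (adult initiation; configurable), and — for the 13–19
band, which is evaluated at 16 — from the band's lower edge (13). The
per-pack inhaled dose is 5.5 µg (Bangkok) or 6.5 µg (Mae Sot); the higher
Mae Sot value is implemented as a larger dose per pack with unchanged lung
absorption. Former smokers are not calibrated (their exposure history is
unspecified), and groups of fewer than five are skipped, both mirroring the
published tables. Groups are calibrated for the current-smoker category the
study calibrated: light-to-moderate in Bangkok, heavy in Mae Sot.

Kidney-damage-induced excess excretion is deliberately not modelled: the
calibration strategy relies on a monotone (effectively linear) exposure →
U-Cd response, and the default model stays linear.

## Biomonitoring statistics

U-Cd summaries follow the field convention for right-skewed biomarkers:
geometric mean with the **arithmetic** SD of untransformed values (the
published tables show SD > GM, which rules out log-scale or geometric SDs).
Values below the 0.05 µg/L detection limit are replaced by LOD/√2; a value
exactly at the limit counts as detected. The (GM, SD) pair is inverted into
lognormal parameters exactly: with w = (1 + √(1 + 4(SD/GM)²))/2,
µ = ln GM and σ² = ln w, which reproduces both moments identically (checked
analytically and by simulation).

Group comparisons mirror the source analysis: Kolmogorov–Smirnov
goodness-of-fit screens (raw and log10 scales, against a normal with
estimated moments); two groups get Student's t-test when both pass the
raw-scale screen, otherwise the Mann–Whitney U test; three or more groups
get one-way ANOVA on log10 values with Dunnett contrasts against the
never-smoker reference (`scipy.stats.dunnett`, which computes the
multivariate-t critical values). Significance is declared at p ≤ 0.05; the
empirical type-I error of the two-group battery is verified to sit in the
3–7% band over 1,000 null replicates. Zero-variance groups are reported as
degenerate rather than crashed on. Published GM cells are used as printed
when forming smoker/never ratios, so a ratio can differ in the last decimal
from one computed on unrounded values.

## Synthetic cohorts

Individual records are not public, so the generator emulates the survey's
*statistical* structure: within each (locality × sex × age band × smoking
category) cell it draws U-Cd from the exactly-inverted lognormal, ages
uniformly within the band (only locality-level age moments are published;
uniform is the least-informative in-band choice), and cigarettes/day
uniformly within the category's range (light-to-moderate 10–25, heavy
26–80; a pack is 20). Cell sizes use the printed table values where
available; categories without printed per-band sizes (former smokers, and
one small heavy-smoker cell) get their prevalence-implied totals allocated
across bands proportionally to the never-smoker age distribution with
largest-remainder rounding, so each cohort sums exactly to its published
size (199 + 200 Bangkok, 3,021 + 3,726 = 6,747 Mae Sot). Generation is
deterministic given the seed, and regeneration is byte-identical.

What the emulation does **not** claim: the real per-cell distributions are
not exactly lognormal, so individual-level threshold percentages (fractions
≥ 1 or ≥ 5 µg/g creatinine) computed on synthetic cohorts are reported but
are not expected to match the published percentages; within-cell
age–exposure correlation and former smokers' pack-year histories are also
not represented. Passing tests therefore demonstrate the pipeline's
correctness on lognormal-structured data, not distributional fidelity to
the unpublished raw data.

## Risk references

The reference catalogue stores the WHO and EFSA tolerable intakes and
urinary thresholds as printed constants. The WHO per-kg conversion uses a
28-day month so that 25 µg/kg/month × 70 kg reproduces the stored 62 µg/day
(25 × 70/28 = 62.5); the 30.44-day calendar-month alternative (57.5 µg/day)
is documented but not used. Exceedance reports flag each group against both
intake references and both urinary thresholds and list the U-Cd range of
the exceeding groups.

## Numerical and design notes

- Explicit daily stepping (timestep 1 day) rather than an ODE solver:
  determinism, exact linearity, exact conservation; a lifetime run is
  ~30k sparse 9×9 updates and takes ~50 ms.
- Stability is validated up front: each compartment's total outgoing daily
  fraction must not exceed 1, so negative burdens are unreachable.
- In a degenerate single-pool parameterization the simulator matches the
  analytic cumulative-urine formula `A·I·(t − (1−e^{−λt})/λ)` within 0.1%.
- The Mae Sot exposure history is modelled as a constant lifetime
  adult-scaled intake (no contamination-onset year is available); if onset
  were recent, intakes for older bands would be underestimated.
- Problem sizes in the test suite (cohorts at the published sizes, 100
  round-trip calibrations, 1,000 null replicates for test size) were chosen
  to make sampling error small relative to the tolerances being checked.

## Known limitations

- Absolute dose estimates inherit the anchoring pair's uncertainty; only
  relative (cross-age, smoker-vs-never) structure is independently testable.
- Body-weight growth, iron/zinc/calcium modulation of absorption, water as
  an exposure source, and nicotine nephrotoxicity are not modelled.
- The smoker calibration attributes the entire U-Cd excess over never
  smokers to inhaled tobacco cadmium; under-reported diet or passive
  smoking would bias packs/day upward.
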