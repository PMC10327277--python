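# Methods

## Scope and model

`lifegap` quantifies how much of the female−male difference in life
expectancy (SGLE) and in life disparity (SGLD) is carried by avoidable
mortality, and by which ages and causes.  The computational chain is:

1. sex × age × cause death counts and person-years on an abridged age
   grid (`<1, 1–4, 5–9, …, 85+`; 19 groups by default);
2. classification of ICD-10 causes into five mutually exclusive groups
   — IHD, treatable & preventable, preventable, treatable,
   non-avoidable — with every death at or above an upper age limit
   (default exact age 75, compared against the age-group lower bound)
   forced to non-avoidable;
3. abridged period life tables per sex from all-cause rates;
4. LE and e† levels and the signed gaps (female minus male);
5. continuous-change decomposition of each gap over the age × cause
   rate matrix.

## Life tables

Closed intervals use the standard rate-to-probability conversion
`q = n·m / (1 + (n − a)·m)`, capped at 1; the terminal open interval
uses the constant-hazard rules `q = 1, L = l/m, e = 1/m`.  The
within-interval survivorship parameter is `a = n/2` for all closed
intervals except infancy, where the Andreev–Kingkade piecewise-linear
rule in `m0` applies (sex-specific coefficients; the sex-neutral
variant averages the male and female rule values).  A constant `a0`
(e.g. 0.3) or a full explicit `a` vector may be supplied instead; the
hand-recursed test fixtures do exactly that.

Life disparity is computed as `e† = (1/l0) Σ d_i · ē_i`, where for
closed intervals `ē_i` interpolates `e` linearly to the interval's mean
age at death `x_i + a_i`, i.e. `ē_i = (1 − a_i/n_i)·e_i +
(a_i/n_i)·e_{i+1}`, and the open interval uses its own `e`.  This is
the documented abridged approximation of the continuous definition
(mean remaining expectancy at death); under a constant hazard μ on a
fine grid it reproduces the closed form `e0 = e† = 1/μ` to well under
1%, which the test suite verifies.

Degenerate inputs remain valid tables: `q` is capped at 1, `l` floored
at 0, and a zero rate in a closed interval simply produces no
attrition.  A non-positive rate in the open interval is rejected
(remaining expectancy there would be undefined).

## Decomposition

The Horiuchi continuous-change method attributes `f(rates_female) −
f(rates_male)` to each age × cause cell by integrating `∂f/∂x_j` along
the straight-line (arithmetic) path between the two flattened rate
matrices, discretised into N equal steps with central differences of
half-increment width at each step midpoint.  Design choices:

* **Path and N.**  Straight-line path in rate space; N defaults to 1000
  and is configurable.  The additivity residual |ΣC − (f(to)−f(from))|
  is computed against the directly evaluated endpoint difference and
  reported, never silently absorbed; on the demo scenario it is below
  10⁻⁹ years at N = 1000.
* **Exact zeros.**  Cells with identical male and female rates receive
  exactly zero contribution by construction.
* **Functional evaluation.**  LE and e† functionals collapse causes by
  summation before the life-table recursion, making them invariant to
  how the all-cause schedule is partitioned into causes; the recursion
  is vectorised over batches of perturbed rate vectors, so a full
  19 × ~17-cell decomposition at N = 1000 takes ~1 s on one core.
* **a0 along the path.**  The infant separation factor is re-evaluated
  from `m0` at every point of the path (the functional is a pure
  function of the rate vector).  The pipeline's level tables use the
  same sex-neutral a0 convention as the decomposition functional so
  that contributions are exactly additive against the reported gaps;
  sex-specific coefficients remain available for standalone life
  tables.
* **Cross-check.**  A stepwise-replacement decomposition averaged over
  the forward and backward sweep orders serves as an independent
  oracle in the tests (it telescopes exactly, and agrees with the path
  integral for linear and near-linear functionals); it is never used as
  the primary method.

## Cause classification

Rules map an ICD-10 code or inclusive range to a (group, label) pair.
Precedence is IHD → treatable & preventable → preventable → treatable,
then file order within a group (so, e.g., drug-poisoning codes listed
before the broad injury range win); 4-character codes match 3-character
patterns by prefix.  Codes with no rule below the age limit fall into
the non-avoidable group under an "Other" label; everything at or above
the limit gets the "Non-avoidable" label.  The shipped default map
implements the standard report-label structure (IHD; cerebrovascular,
diabetes, hypertensive under treatable & preventable; alcohol-related,
cancers including lung, drug-related, infectious, injuries, respiratory
under preventable; cancer, digestive, genitourinary, infectious,
maternal/perinatal, respiratory under treatable) with representative
ICD-10 ranges; it is deliberately not a full-fidelity OECD/Eurostat
list, which users can supply as YAML/CSV — the engine is list-agnostic.

## Data interfaces

The WHO Mortality Database reader supports the 26-column flat layouts
whose age bands include `<1`, `1–4` (combined or as single years) and
5-year groups; bands above 85 collapse into the open group, and any
format coarser than the target grid is rejected rather than
interpolated (no invented splits).  Unknown-age deaths are
redistributed proportionally to the known-age distribution within each
sex × cause, conserving totals; counts may therefore be fractional, and
all downstream arithmetic accepts that.  Sexes other than male/female
are dropped with a logged warning.  Population denominators default to
the WHO population file summed over the pooled years.

## Synthetic scenarios

A scenario specifies per-sex Gompertz–Makeham hazards
`μ(x) = α·e^{βx} + c` evaluated at interval midpoints (the open
interval uses lower bound + 5 as a proxy midpoint, configurable),
piecewise-constant cause fractions that sum to one per sex × age,
per-cell additive rate offsets, populations, a seed and a noise model
(exact expected counts or Poisson).  The additive offsets exist because
a single-cell rate perturbation — the basis of the parameter-recovery
tests — cannot be expressed through normalised fractions alone.

The demo scenario emulates the structure of the Iranian 2015–2016
extract this pipeline targets: female parameters (α = 1.30·10⁻⁵,
β = 0.1030, c = 5.5·10⁻⁴) and male parameters (α = 1.55·10⁻⁵,
β = 0.1015, c = 1.45·10⁻³) chosen so the noise-free levels sit near
LE ≈ 80/76 years and e† ≈ 12.5/14.4 years, with the male excess
weighted toward injuries at ages 15–39 and IHD/lung cancer at 50–74, a
female-only breast-cancer and maternal component, ICD-10-coded causes
so the classification stage runs for real, and ~80 million person-years
per sex on a young-heavy age pyramid (two pooled years of a ~40M
population).  The generator does *not* emulate registration
incompleteness, cause-coding garbage, or temporal trend; passing tests
therefore demonstrate the correctness of the estimators on
well-registered data, not robustness to the coding errors real vital
registration suffers.  The demo's avoidable shares consequently run
higher than a real population's (its non-avoidable male excess is
modest by construction), and the decomposed values are qualitative,
not replications.

## Numerical conventions

Radix 1 internally; years to 6 decimals in machine output, 3 decimals
in report CSVs (a full-precision sidecar is written alongside);
avoidable shares are computed from unrounded contributions and then
rounded to whole percent.  Problem sizes used by the validation
scripts: N = 1000 decomposition steps on the full demo scenario,
single-year grids to age 110 for the continuous-limit checks, and
N = 200 for the localization scenarios — all chosen as the points where
the measured discretisation error is far below the tolerances being
checked.

## Known limitations

* No smoothing/graduation of rates and no confidence intervals on LE,
  e† or contributions.
* No redistribution of ill-defined ("garbage") causes; they classify
  like any other code.
* ICD-10 only; coarse WHO age formats are rejected, not interpolated.
* The stepwise oracle is order-averaged over two sweeps only (forward
  and backward), which suffices as a cross-check but is not a full
  Shapley average.
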