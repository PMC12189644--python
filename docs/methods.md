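# Methods

## The scientific problem

The maximum electron transport rate a C3 leaf devotes to CO2 assimilation,
J_A-max, is usually estimated indirectly: an A_n–C_i curve (net assimilation
versus intercellular CO2 at saturating irradiance) is fitted with the
Farquhar–von Caemmerer–Berry (FvCB) model and the fitted electron transport
parameter J is read off. Chlorophyll fluorescence measures something larger
and more direct: the total PSII electron flux J_f, which also feeds
photorespiration, nitrate reduction and Mehler-reaction oxygen uptake,

    J_f = J_A + J_O + J_Nit + J_MAP.

Because every term is non-negative, a credible indirect estimate must obey
J_A-max < J_f-max, where J_f-max is the maximum of the fluorescence-derived
J–C_i curve. This package implements both sides of that intercomparison —
the FvCB fits, the empirical description of the J–C_i curve, the summary
statistics — and the electron-budget credibility criterion itself.

## Models

### FvCB A–Ci composition (`fvcb_model`)

Net assimilation is the hard minimum of three candidate rates:

* Rubisco-limited: `Ac = Vcmax (Ci − Γ*) / (Ci + Kc(1 + O/Ko)) − Rd`
* RuBP-regeneration (electron-transport) limited:
  `Aj = J (Ci − Γ*) / (a Ci + b Γ*) − Rd`
* Triose-phosphate-utilization limited: `Ap = 3 TPU − Rd`

with tie precedence Rubisco < RuBP < TPU. No hyperbolic smoothing is used:
smoothing would introduce a parameter the three-phase description does not
reference. The `(a, b)` pair selects the electron-requirement sub-model:
(4, 8) when RuBP regeneration is limited by NADPH alone (sub-model I),
(4.5, 10.5) under NADPH+ATP co-limitation (sub-model II), (3, 7) when the
cytochrome b6f Q cycle raises the proton yield to H+/e− = 3. Because the
sub-model II denominator is larger at every Ci, the J fitted to the same
curve is larger under sub-model II; pointwise the required-J ratio lies in
[4.5/4, 10.5/8] = [1.125, 1.3125].

Writing the denominator as `a (Ci + Γ*/f)` identifies `f = a/b` with the
mol CO2 released in the photorespiratory pathway per mol RuBP oxygenated:
0.5 for (4, 8), and ≈ 0.57 when b is tightened to ≈ 7.02.

Rubisco kinetics default to widely used 25 °C values — Kc = 404.9 µmol
mol⁻¹, Ko = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹ — and are configurable.
All concentrations are intercellular (infinite mesophyll conductance);
temperature responses and the post-TPU decline some species show at very
high CO2 are out of scope. The TPU phase is a flat plateau without the
optional Γ*-dependent refinement.

### Empirical CO2 response of electron transport (`empirical_co2`)

    J(Ci) = α (1 − β Ci) Ci / (1 + γ Ci) + J0

with closed-form maximizer and maximum

    Cisat  = (√((β+γ)/β) − 1) / γ
    Jf-max = α (√(β+γ) − √β)² / γ² + J0.

This functional form is the one for which the two closed forms are exactly
the interior maximizer/maximum (verified symbolically before
implementation). β = 0 degenerates to a monotone curve with no maximum and
is signalled as such. The model's validity domain is Ci ∈ [0, 1/β]; fitting
is not restricted to it, but the coefficients carry no agreed mechanistic
interpretation and are reported as-is.

### Light response (`light_response`)

The irradiance analogue `An(I) = α_i (1 − β_i I) I / (1 + γ_i I) − Rd`,
with the same closed-form maximizer, gives the saturating irradiance Isat
at which CO2-response curves are measured. Rd is a fitted parameter of the
light curve.

## Fitting (`fit_engine`)

All models are fitted by bounded least squares: simulated annealing with
Metropolis acceptance, then a deterministic Nelder–Mead polish.

* Proposals are Gaussian steps, per-parameter scale 2 % of the bound width,
  reflected back into the bounds.
* Acceptance: ΔSSE ≤ 0 always; ΔSSE > 0 with probability exp(−ΔSSE/T).
* Schedule: T starts at the SSE of the initial point (configurable) and
  cools by 0.95 per sweep; 200 sweeps × 50 proposals by default.
* The polish (two chained Nelder–Mead runs, parameter tolerance 1e-10)
  makes the result a local SSE minimum; the second run restarts the simplex
  to escape flat valleys such as a TPU plateau that stops binding.
* Everything is driven by one integer seed; identical inputs give
  bit-identical results.

The initial point is data-driven (standard practice in A–Ci fitting tools):
TPU from the high-CO2 plateau, Vcmax and J by inverting the Rubisco- and
RuBP-limited forms at representative Ci, Γ* at 40 µmol mol⁻¹, Rd at 1.5
µmol m⁻² s⁻¹. Rd cannot be initialized from the CO2-free point because the
composition gives An(0) = −J/b − Rd there, not −Rd. Mid-bounds starts were
rejected: they leave the annealer in biased local minima on a meaningful
fraction of noisy curves.

Default bounds are generous physiological ranges (e.g. Vcmax 5–500, J
10–600 µmol m⁻² s⁻¹, Γ* 20–80 µmol mol⁻¹). Goodness of fit is
R² = 1 − SSE/SST.

### Shared-biochemistry sub-model comparison

The two FvCB sub-models differ *only* in the stoichiometry of the
RuBP-limited phase. The intercomparison therefore fits sub-model I with
all five parameters free, then re-estimates J under sub-model II on the
RuBP-limited segment identified by that fit, holding Vcmax, TPU, Rd and Γ*
fixed (segment-wise phase estimation, as in spreadsheet A–Ci fitting
tools; Aj is linear in J, so the segment least-squares solution is closed
form). A free refit of (Vcmax, J, TPU) under sub-model II was implemented
and rejected: on synthetic curves the CO2-free observation An(0) = −J/b −
Rd (≈ −26.5 µmol m⁻² s⁻¹ at J = 200) dominates such a refit — the other
phases absorb the mid-Ci points and J collapses onto the single Ci = 0
datum, an artifact of the hard-minimum composition that real leaves (and
the replicated measurements the package emulates) do not produce. The
shared-biochemistry estimate keeps the II/I ratio where the stoichiometry
puts it (≈ 1.15–1.18 on the default synthetic curves).

## Statistics (`intercompare`)

Replicates are fitted independently (n = 3 per species) and summarized as
mean ± SE; all tests operate on these summary statistics.

* Two-sample comparisons use Student's pooled-variance t-test with
  df = n1 + n2 − 2 (Welch correction available).
* One-way ANOVA is computed from group means/SEs; when it is not
  significant at α all groups share one letter.
* Letters: two conventions. The standard compact letter display
  (insert-and-absorb over all pairwise tests: groups share a letter iff
  not significantly different) and an observed-anchored convention —
  estimates not significantly different from the observed group share its
  letter, the remaining estimates are lettered among themselves — which is
  how gas-exchange comparison tables anchored on a measured column are
  typically marked. The report uses the observed-anchored convention by
  default (`reference="observed"`); note that an anchored display can give
  different letters to a pair that is itself not significantly different.
* Letters are assigned in descending order of mean ('a' = highest).
* No multiple-comparison adjustment is applied by default; the choice is
  surfaced rather than hidden because the tables being reproduced do not
  state one.

The credibility criterion: a sub-model's J_A-max is an **overestimate**
only when its mean is at or above the observed J_f-max *and* the one-sided
t-test rejects J_A-max < J_f-max at α — sampling noise alone can never
flag an overestimate. Observed J_f-max is the per-replicate maximum of the
measured J–C_i curve, averaged over replicates (this yields an SE with
n = 3, matching how the quantity is reported).

When a sub-model overestimates, `threshold_b_coefficient` solves for the
Γ*-coefficient b* at which the mean fitted J_A-max equals the observed
mean: bisection on b ∈ [4.01, 12] to |ΔJ| < 0.01, with J(b) computed by
the shared-biochemistry segment re-estimate (continuous and strictly
increasing in b). The returned `implied_f = 4/b*` is the photorespiratory
release the adjustment implies; b* < 8 forces f > 0.5.

## Synthetic data (`synthetic_data`)

Generators emulate the measurement protocol the analysis assumes:
12 CO2 levels (1600, 1400, 1200, 1000, 800, 600, 420, 300, 200, 100, 60,
0 µmol mol⁻¹, stepped high to low), 15/13/12-level light grids from 2000
µmol m⁻² s⁻¹ down to darkness, n = 3 replicates, additive homoscedastic
Gaussian noise on the dependent variable. Defaults: noise sd 0.3 µmol m⁻²
s⁻¹ on An (matching the 1–3 % SE/mean scale of replicated gas-exchange
measurements) and 1.0 µmol m⁻² s⁻¹ on fluorescence-derived J.

The default FvCB truth (Vcmax = 120, J = 200, TPU = 14, Rd = 1.5, Γ* = 40)
is a generic healthy C3 leaf at 25 °C chosen so that all three limitation
phases appear on the 12-level grid: TPU = 14 puts the RuBP-limited window
at Ci ≈ 370–670 (grid points 420 and 600). With TPU much lower (e.g. 12)
the plateau swallows the RuBP window entirely and J becomes unidentifiable
from the curve — a degenerate design, not a fitting failure.

`gen_paper_like_study` bundles four synthetic species (A–Ci, J–Ci and A–I
curves × 3 replicates) whose ground truths put J_A-max and J_f-max in the
215–365 µmol m⁻² s⁻¹ range, with species A built to violate the
electron-budget criterion (FvCB J = 320 above its fluorescence maximum
≈ 295) and species B/D to satisfy it under sub-model I.

The threshold-coefficient demonstrations use a separate warm-leaf truth
(Vcmax = J = 200, TPU = 12, Γ* = 55 µmol mol⁻¹, a value typical of
30–33 °C leaves) whose RuBP-limited phase sits at low-mid Ci (grid points
100–420). That placement is what gives the Γ* coefficient enough leverage
over the fitted J for the sub-8 solution to exist: when the RuBP phase
sits at high Ci the `a·Ci` term dominates the denominator and no b in the
physically motivated family can lower J_A-max by the required ≈ 7 %.

What the generators deliberately do not simulate: instrument drift, leaks,
stomatal dynamics, heteroscedastic noise, and biological
replicate-to-replicate parameter spread. Passing recovery tests on these
data therefore demonstrate correctness of the estimation machinery under
the stated error model, not robustness to every artifact of real gas
exchange.

## Numerical choices

* Phase transitions (`transition_ci`) are located by dense sign scan plus
  Brent bisection to |ΔA| < 1e-9 on (Γ*, 2000]; the RuBP→TPU crossing also
  has a closed form used as a cross-check. A missing crossing is reported
  as absent, not as an error.
* Ties in the three-way minimum resolve Rubisco < RuBP < TPU.
* R² is undefined (raises) when all observations are identical.
* Degenerate inputs — fewer points than parameters + 1, duplicated
  independent values, J–Ci curves without J — raise typed validation
  errors before any optimization runs.
* Test and pipeline runs use a reduced annealing budget (100 sweeps × 30
  proposals) with the polish enabled; this is the package's chosen
  desk-scale problem size and gives results indistinguishable from the
  full default schedule on the synthetic curves.

## Known limitations

* The hard-minimum composition misdescribes real leaves near Ci = 0 (it
  predicts An(0) = −J/b − Rd, far more negative than measured CO2-free
  assimilation); conclusions that hinge on the CO2-free point should not
  be drawn from these fits.
* Mesophyll conductance is not modelled; all rates are on a Ci basis.
* The empirical J–Ci coefficients have no mechanistic reading; Cisat and
  Jf-max are the only derived quantities interpreted.
* The annealing schedule is a declared default, not an inference about any
  particular published fitting service; any schedule satisfying the
  Metropolis contract is admissible.
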