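# Methods

This note documents the models implemented in `sedpep`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Assay reduction and Michaelis-Menten inference

A saturation assay is a set of paired-timepoint fluorescence readings
across substrate concentrations (default ladder 0, 25, 50, 75, 100, 200,
300 μM), one record per concentration and treatment (live or autoclaved
control). The reduction

v₀ = (ΔF / slope) · V_slurry / m_wet / Δt

uses only the calibration slope; the intercept cancels in ΔF. Negative
drifts are preserved and flagged rather than clipped — they are
informative about the noise floor, and clipping would bias low-rate fits.

The Michaelis-Menten fit excludes the zero-substrate blank, requires at
least four distinct nonzero concentrations, and uses
`scipy.optimize.curve_fit` with nonnegativity bounds from a 3×3 log-spaced
multi-start grid around (V_max⁰ = max v₀, K_m⁰ = median S); convergence
tolerances are 1e-10. Standard errors are the square roots of the
Gauss-Newton covariance diagonal, i.e. the local linearization at the
optimum. The fit is declared degenerate — and the fallback applied: V_max
= mean v₀ at the highest concentration, no K_m — when no start converges,
the K_m estimate collapses to the zero boundary (rates flat across the
ladder), or its standard error is not finite. Autoclaved controls are
reported but not subtracted by default, because autoclaving does not fully
destroy mineral-stabilized enzymes and the control is qualitative; a
`subtract_killed` switch enables the quantitative correction. A reduced
plate-reader schema (`vmax_proxy`) reports v₀ at a single saturating
concentration (400 μM) as a V_max stand-in for noisier campaigns. When
replicate saturating-concentration readings are present they enter the
least-squares fit like any other record (and the fallback mean), the
default behaviour where either choice was defensible.

ΣV_max per depth is the plain sum over substrates; its standard error is
the quadrature sum of per-fit SEs, which is exact for a linear
combination. Substrate comparison follows a two-branch design: one-way
ANOVA on log₁₀ V_max with Tukey HSD post hoc; Kruskal-Wallis on K_m with
the same post hoc on log₁₀ values. Compact letters are the maximal cliques
of the non-significance graph, lettered from the fastest group (ties
alphabetical); when the global test is not significant all groups share
one letter.

## The 2-G sulfate/methane reaction-transport model

Domain [4.5, 200] cm: above 4.5 cm oxic/suboxic processes and bioturbation
would matter and are out of scope; below, solids advect at the sediment
accumulation rate ω without mixing. Governing equations (per porewater
volume, steady state):

- solids: ω dG_i/dz = −k_i G_i, solved in closed form (no numerical decay
  error),
- solutes: D_s C″ − ω C′ + ΣR/φ = 0 with D_s = D₀/θ², θ² = 1 − 2 ln φ,
- carbon oxidation r_C = k₁G₁ + k₂G₂, routed to sulfate reduction with
  Monod factor M = SO₄/(K_SO₄ + SO₄) and to methanogenesis with (1 − M),
- AOM = k_AOM·[CH₄]·[SO₄] consuming both 1:1 (a first-order-in-CH₄ form is
  available behind `aom_bimolecular=False`),
- stoichiometry a = (4 − s)/8 mol SO₄ (or CH₄) per mol C from electron
  balance at mean carbon oxidation state s = −0.7,
- boundary conditions: measured concentrations at 4.5 cm, zero gradient at
  200 cm.

The reactive carbon flux is anchored by the sulfate flux across 4.5 cm
plus methane burial below 200 cm: C-flux = (J_SO₄ + J_CH₄,burial)/a, and
G_i(z_top) = f_i·C-flux/ω.

### Defaults and rationale

| parameter | default | unit | rationale |
|---|---|---|---|
| ω | 0.3 | cm yr⁻¹ | measured accumulation rate at the site |
| φ | 0.8 | — | typical fine estuarine mud; compaction neglected |
| D₀(SO₄), D₀(CH₄) | 280, 440 | cm² yr⁻¹ | free-solution values near 16 °C |
| SO₄(4.5 cm) | 12 | mM | seawater sulfate scaled to salinity ≈ 15 |
| CH₄(4.5 cm) | 0 | mM | methane flux at the top observed ≈ 0 |
| s (ox. state) | −0.7 | — | assumed mean oxidation state of reactive OM |
| K_SO₄ | 0.1 | mM | keeps methanogenesis suppressed until sulfate is nearly exhausted |
| k₁, k₂ | 0.08, 0.018 | yr⁻¹ | labile/refractory decay; sets deep:surface r_C ≈ 0.17% |
| f | 0.5 | — | equal partitioning as the neutral default |
| k_AOM | 3 | mM⁻¹ yr⁻¹ | within the literature range; sharp but identifiable SMTZ |
| J_SO₄(top) | 182 | μmol cm⁻² yr⁻¹ | sets sulfate depletion ≈ 43 cm |
| CH₄ burial | 15 | μmol cm⁻² yr⁻¹ | modest deep methane reservoir |

The free parameters of the calibration are {k₁, k₂, f, k_AOM}; everything
else is configuration. Defaults were fixed once against the two field
shape anchors — sulfate depleted near 43.5 cm, deep (82.5 cm) oxidation
rate ≈ 0.17% of the 4.5 cm rate — plus the qualitative requirement that
methane stays near zero above the sulfate-methane transition. With the
first Monod/AOM constants tried (K_SO₄ = 0.5 mM, k_AOM = 1) methane leaked
upward while sulfate was still abundant, contradicting the site's
structure, so those two were revised once to the values above.

### Numerics

Uniform finite-difference grid (default 0.5 cm), central differences
(cell Péclet ≪ 1), Dirichlet top row, symmetric-ghost Neumann bottom row.
The coupled nonlinear system is solved by damped Picard sweeps: sulfate is
solved as a tridiagonal system with the Monod consumption linearized as
(a·r_C/φ)·C/(K + C_old) — which vanishes smoothly as sulfate is exhausted
and keeps iterates nonnegative — and AOM taken semi-implicitly against the
previous methane field; methane follows analogously. Negative intermediate
values are clamped within a sweep and vanish at convergence. Convergence
is declared when the nondimensionalized residual of the full nonlinear
system drops below 1e-8; the default configuration converges in ~60
sweeps, a few milliseconds. Grid-refinement tests show second-order
convergence (measured order ≥ 1.8) and <0.1% profile change on halving
the default step.

Calibration minimizes weighted residuals (1/σ when the profiles carry
errors, otherwise unit weights scaled per solute by the profile maximum)
over log-transformed rate constants and the logit of f. A 3⁴ log-spaced
grid of starts is ranked by forward SSE and the best two are polished with
`scipy.optimize.least_squares` (trf). Because the two carbon fractions
are exchangeable, fits are canonicalized to k₁ > k₂ (swapping f → 1 − f).
Standard errors are Gauss-Newton estimates delta-transformed to the
natural scale; they describe curvature at the optimum, not full posterior
uncertainty.

## Derived indices

Porosity: φ = (m_w/ρ_w) / (m_w/ρ_w + (m_d − S·m_w/100)/ρ_ds) with ρ_ds =
2.5 g cm⁻³; the salt correction removes sea salt left in the dried solids.
Wet bulk density ρ_wet = φρ_w + (1 − φ)ρ_ds (1.3 g cm⁻³ at the default
porosity) converts per-gram activity to per-volume; cell-specific activity
is ΣV_max·ρ_wet/cells, reported in amol cell⁻¹ h⁻¹. Errors propagate in
first-order relative quadrature throughout; in practice cell-count
uncertainty dominates. The ΣV_max : r_C ratio is reported only relative to
its value at a reference depth (default 4.5 cm) because the absolute
magnitude depends on the substrate mix and enzyme specificity overlap.

Depth trends use an explicit transform ladder replacing judgment by eye:
OLS on the raw values, Shapiro-Wilk normality and Breusch-Pagan
homoskedasticity tests on the residuals at α = 0.05; on failure, refit on
log₁₀ values; if diagnostics still fail (or values are nonpositive),
Spearman rank correlation. The result records the branch actually used
and both diagnostic p-values. Interpolation between unmatched depth grids
is linear with no extrapolation; out-of-domain depths are dropped with a
warning.

## Gene census

A gene is counted as secreted ("SP-positive") when at least one of the
four signal-peptide predictors flags it; the per-tool breakdown is always
available because no consensus rule is canonical. Frequencies are
SP-positive genes of a family divided by *all* peptidase genes in the
zone, so per-zone frequencies plus the SP-negative share sum to one.
Family labels are validated against a bundled list of MEROPS clan/family
codes plus a structural pattern; unknown labels warn but pass, since
annotation pipelines emit free-text descriptors alongside codes.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the field data streams — the
concentration ladder with paired timepoints and autoclaved controls, the
3-cm core-section porewater sampling over the upper 85 cm, log-linear cell
decline through the two measured anchors (4.5×10⁸ cells ml⁻¹ at 1.5 cm,
7.4×10⁷ at 82.5 cm), the published activity-ratio trend lines
(slopes 5.60×10⁻³ and 2.26×10⁻³ cm⁻¹, intercepts 0.146 and 0.451), and a
gene table with per-zone totals 685/1994/1060 whose SP-positive pool is
43% gingipain-like C25. Noise models are additive Gaussian on rates and
concentrations (porewater noise optionally proportional per point,
sd = 5% of value plus a 1%-of-scale detection-limit floor, the natural
model for chromatographic data), and multiplicative lognormal on cell
counts because counts are strictly positive. Killed controls retain 10% of
the live rate by default, reflecting incomplete enzyme destruction by
autoclaving.

Not emulated: fluorophore sorption to particles (measured negligible at
the site), plate-reader positional effects, substrate depletion during
incubation, temperature corrections, transient diagenesis, bioturbation,
gas-phase methane (ebullition), and any spatial heterogeneity between
cores. Passing tests therefore demonstrate the correctness of the
inference chain under these idealized conditions, not the field
variability of real assays.

The campaign-level defaults are anchored so the summed potential declines
log-linearly from 9.09 μmol g⁻¹ h⁻¹ at 4.5 cm to 1.24 at 82.5 cm (13.6%),
with per-substrate shares that make the endopeptidase substrates and
Gly-AMC fastest and Arg-AMC slowest, and true K_m declining downcore
(higher affinity in more degraded organic matter).

## Problem sizes used in tests and the acceptance script

Monte-Carlo suites use 200 seeds for single-assay parameter recovery, 40
seeds for trend-sign recovery (6 substrates × 5 depths each), 20 seeds for
noisy diagenesis calibration (54 observations per seed), and 4×10⁴ draws
for quadrature-vs-resampling checks; the diagenesis grid is 0.5 cm
(0.25 cm in refinement and budget checks). These sizes give stable
medians and coverage estimates while keeping the whole suite fast.

## Known limitations

- First-order (quadrature) error propagation is accurate to better than
  10% against Monte-Carlo only while relative errors stay below ~15-20%;
  beyond that the skewness of ratios makes the linearization undercover.
  Cell-count errors of 40% are reported as quadrature SEs for continuity
  with practice, but should be read as approximate.
- K_m is weakly constrained when the top of the concentration ladder is
  only ~2×K_m (as with K_m ≈ 138 μM against a 300 μM maximum): individual
  estimates scatter ~20% at 5% assay noise even though the median is
  nearly unbiased. Extending the ladder, not the fitter, is the remedy.
- The calibration's parameter uncertainties are local Gauss-Newton
  estimates; strongly correlated parameters (k₁ with f) can make them
  optimistic.
- The 2-G model omits oxic/suboxic electron acceptors, so its oxidation
  rates are lower bounds above the sulfate reduction zone, and its
  "methane burial" closure term is an estimate, not a measurement.
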