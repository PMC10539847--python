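# Methods

## The equilibrium model

`slowex` models a receptor with two independent ligand-binding sites —
orthosteric (dissociation constant `KDO`) and allosteric (`KDA`) — and a
single ligand species shared between them.  Independence means the same
`KDO` governs orthosteric binding whether or not the allosteric site is
occupied (and vice versa); there is no cooperativity parameter.  Under
this assumption the occupancy of each site factorizes in the free-ligand
concentration L, `f_O = L/(KDO+L)`, `f_A = L/(KDA+L)`, and the four
state concentrations are products of these factors.  The only nonlinear
unknown is L itself, fixed by ligand conservation:

    g(L) = L + Et·f_O(L) + Et·f_A(L) − Lt = 0.

g is strictly increasing on [0, Lt] with g(0) = −Lt ≤ 0 and g(Lt) ≥ 0,
so Brent's method on that bracket converges globally to the unique
physical root; no analytic cubic (with its branch-selection pitfalls) is
needed.  The solver refuses to return a state whose conservation
residuals exceed a relative 1e-10 (configurable).  Algebraic terms are
grouped so that exchanging `KDO ↔ KDA` permutes the state concentrations
bit-exactly, which makes the swap symmetry a hard invariant rather than
an approximate one.

A dissociation constant ≥ 1 M (`SITE_DISABLED_KD`) acts as a
pseudo-infinite sentinel that switches a site off while keeping a single
code path; with one site disabled the solver reproduces the closed-form
single-site quadratic isotherm

    Eb = ((Et+Lt+KD) − sqrt((Et+Lt+KD)² − 4·Et·Lt)) / 2,

evaluated in the subtraction-free form `2·Et·Lt/(b + sqrt(b²−4EtLt))`
for numerical stability in the tight-binding corner.  The quadratic is
also the fitting kernel of the one-site model variants.

The competition model (one site, two mutually exclusive ligands) uses
the same reduction with free enzyme as the scalar unknown:
`f(E0) = E0 + Rt·E0/(KdR+E0) + Ct·E0/(KdC+E0) − Et` is monotone on
[0, Et].  Bound fractions are normalized to total enzyme; the
displacement fraction `1 − ER(with C)/ER(without C)` is independent of
that normalization.

All internal concentrations are molar.  I/O accepts explicit unit tags
(`"79 uM"`, `"10 nM"`) so nanomolar and micromolar constants cannot be
silently confused by a factor of 1000.

## Slow-exchange populations

When exchange between the apo and bound conformations is much slower
than their resonance-frequency separation (angular separation
`2π·Δδ·ν`; e.g. 0.6 ppm of ¹⁵N at 60 MHz ≈ 226 s⁻¹ ≈ 200 s⁻¹ to one
significant figure), each state gives a separate peak and the bound
population is `p_i = I_i/(I_i+I_a)`.  This assumes the two resonances of
a residue have equal per-molecule intensity — equal linewidth and
relaxation in both states.  The assumption is explicit: an optional
per-residue observability factor c rescales `p_i = c·I_i/(c·I_i+I_a)`
(default 1.0), but no automatic correction for differential line
broadening is attempted.

Pairing of observed peaks to states is by reference position: a peak
matches the apo (or bound) reference of a residue if it lies within a
tolerance box of 0.03 ppm (¹H) × 0.3 ppm (¹⁵N).  Two peaks matching one
reference, or one peak within tolerance of both references, abort with
an ambiguity error listing the candidates — never a silent choice.  A
missing peak contributes intensity 0 with a `*_not_detected` flag: at
titration endpoints only one state is visible, and its partner's
intensity really is indistinguishable from zero there.  When both peaks
of a residue are missing the population is undefined (NaN, flagged),
and downstream fits drop such rows explicitly.

Peak lists are the Sparky `.list` text dialect (assignment, w1, w2,
height) with w1 = ¹⁵N and w2 = ¹H, stated in the file header because
dimension order is genuinely ambiguous in the wild.

## KD fitting and identifiability

Fits minimize `Σ (p_i,obs − occupancy_model(Lt))²` over `log10 KD`
within bounds [1e-12, 1e-1] M, pooled across all residues of one
reporter class — the per-residue curves are treated as reports of a
single global equilibrium, and per-residue residuals are returned so a
deviant reporter is visible.  A coarse grid (15 points per decade)
seeds a bounded trust-region refinement, which makes the 1–2 parameter
problem robust to the many-decade search range.

Model variants: `orthosteric_only` and `allosteric_only` fit the
single-site quadratic isotherm to their own reporter class;
`two_site` fits both constants jointly to the ATP-site and
allosteric-site reporters against the full four-state model.  Notably,
the joint fit can pin even a nanomolar `KDO` at 79 µM receptor, because
the weak-site reporters sense the free-ligand concentration near the
equivalence point, which `KDO` controls.

Identifiability is reported honestly.  The RSS profile over the full
log10 KD grid defines a flat region around the optimum using the
threshold `RSS_min + max(n·(1e-3)², 0.05·RSS_min)`: parameter values
whose predicted populations differ by less than ~1e-3 per point (or
5 % in RSS) are treated as indistinguishable.  If the flat region
reaches the lower parameter bound the data are stoichiometric
(Et ≫ KD) and the fit raises `upper_bound_only`, reporting the upper
edge of the flat region as the supported bound instead of a
spuriously precise KD; symmetrically, `lower_bound_only` marks binding
too weak to resolve.  For a noiseless 79 µM titration of a 10 nM site
the reported bound is ≈ 0.1–1 nM-scale–µM-scale depending on noise,
always ≤ 1 µM — the data genuinely cannot say more.

Uncertainty: a curvature (J^T J) standard error on log10 KD, plus a
seeded nonparametric bootstrap over residues (default 200 resamples,
95 % percentile interval).  Bootstrap refits warm-start from the full
fit and skip profile diagnostics.  AIC is reported as auxiliary
information only; mechanism claims rest on the RSS comparison below.

Because nominal concentrations from gravimetric/absorbance preparation
are typically trusted only to 10–20 %, every report includes a
sensitivity block refitting all models with the ligand totals scaled by
±15 %.

## Mechanism discrimination

`discriminate_mechanism` asks which occupancy curve the core-opening
(`sh3_sh2_core`) reporters follow, at fixed candidate constants
(default KDO = 10 nM, KDA = 10 µM): it computes the RSS of the pooled
core populations against the orthosteric and the allosteric occupancy
curves of the full two-site model and prefers the smaller, reporting
the ratio.  It also quantifies concordance between the per-point class
means of the core and ATP-site reporters (max absolute difference and
Spearman rank correlation) — the orthosteric mechanism predicts the
two classes change identically with ligand.  On synthetic data with 10
reporters per class and 5 % intensity noise the preferred mechanism
matches the generator's ground truth in ≥ 99 of 100 seeded runs for
either mechanism (measured: 100/100 for both).

The report plot shows both per-residue points and class means over the
two theoretical dashed curves; no claim is made about which of the two
a published figure would show.

## The synthetic-data generator

`slowex.synth` emulates exactly the data structure the analysis
consumes.  Defaults are the reference study conditions: 79 µM receptor;
molar ratios 0, 0.1, 0.3, 0.5, 0.7, 1.0, 3.0; KDO = 10 nM,
KDA = 10 µM; 11 reporter residues (4 core, 4 ATP-site, 3 allosteric);
2 % multiplicative intensity noise; 2 % detection floor.  For each
point the four-state model is solved; each residue's apo/bound heights
are `base·(1−p)·η` and `base·p·η` with η lognormal
(`exp(N(0, σ))` — peak heights are positive and dominated by
proportional error at high signal-to-noise, so no additive floor is
modelled).  Peak positions receive Gaussian jitter (0.002 ppm ¹H,
0.02 ppm ¹⁵N).  States below the detection floor are omitted, which
reproduces endpoint spectra where one set of resonances has vanished —
and introduces the same small censoring a real analyst faces.

The mechanism switch couples the core reporters to either site's
occupancy (`orthosteric_opens_core` / `allosteric_opens_core`); the
ATP-site and allosteric-site reporters always follow their own site, so
the switch changes only what is scientifically at stake.  Residue
labels mirror commonly used Abl reporters (V92, V130, G149, Y283 core;
N316, D382, G340, A384 ATP-site; F444, G455, F505 allosteric); their
shift values are synthetic placeholders laid out to be unambiguous at
the pairing tolerances, not real assignments, and the class split of
the less-documented residues is this package's own choice.  A
generation-time collision check rejects any residue panel whose
reference peaks could be confused by the pairing step (within one
tolerance box plus 5σ of jitter), so generated fixtures are always
analyzable — `generate_edge_cases` deliberately bypasses it to produce
the ambiguous-overlap fixture.

What the generator does **not** emulate: 2-D lineshapes and their
fitting, differential relaxation between states (the equal-observability
assumption is exactly true in synthetic data), intermediate-exchange
coalescence, baseline/phase artifacts, and real assignment ambiguity
beyond simple positional overlap.  Passing tests therefore demonstrate
the correctness and statistical power of the analysis chain given
slow-exchange peak heights, not robustness to spectral-processing
pathology.

## Problem sizes and numerical defaults

Monte-Carlo checks use 100 seeds (parameter recovery at 2 % noise;
discrimination power at 5 % noise) and a 1000-tuple random grid for
solver/oracle agreement (1 nM–10 mM in all four parameters, agreement
to 1e-8 relative).  Solver tolerance: relative 1e-10 on conservation
residuals; invariant checks in the test suite assert 1e-9.  Fit
convergence tolerances are 1e-14 (xtol/ftol/gtol) on the trust-region
refinement.  Degenerate inputs are handled before root finding:
`Lt = 0` returns the all-apo state exactly, `Et ≤ 0` is a domain error.

## Known limitations

- Independent sites only: no cooperativity between orthosteric and
  allosteric pockets, and one ligand species; ternary mixtures beyond
  the single-site competition model are out of scope.
- Equilibrium only: no on/off kinetics, no exchange-lineshape
  modelling; the exchange-regime functions do arithmetic on
  user-supplied rates, they do not estimate rates from spectra.
- The one-site fit's `upper_bound_only` threshold is a pragmatic
  plateau criterion, not a formal likelihood-ratio interval; treat the
  reported bound as an order-of-magnitude statement.
- Populations from intensities inherit the equal-observability
  assumption; systematic linewidth differences between states bias
  `p_i` in a way no internal check can detect.
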