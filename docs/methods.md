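# Methods

## Natural-abundance correction

A measured fragment envelope is modeled as `raw = M·x`, where
`x = (x_0 … x_c)` are the fractions of molecules carrying 0 … c tracer
¹³C atoms (c = number of backbone carbons) and column *j* of **M** is the
theoretical isotopologue envelope of the derivatized fragment with *j*
carbons withdrawn from the natural pool, shifted up *j* mass units and
truncated to the measured window.  Envelopes are built by discrete
convolution of per-atom isotope distributions (binary exponentiation over
atom counts), which is exactly equivalent to enumerating atom-isotope
assignments; the unit tests verify this against a brute-force enumeration
oracle on small formulas.

Correction solves the linear model by non-negative least squares
(`scipy.optimize.nnls`) and renormalizes the solution to sum to 1.  On
noiseless data this reproduces the exact inverse (round-trip error < 1e-6
for every shipped fragment over random mixtures); with noise the
non-negativity constraint prevents the small negative fractions an
unconstrained solve would produce.  Tracer isotopic purity defaults to 1;
a purity *p* < 1 replaces each tracer carbon's pure one-unit shift with a
(1−p, p) two-point distribution in the forward columns.

The measured window defaults to `n_backbone_carbons + 2` shifts.  For most
fragments this captures > 99% of every column's envelope; for the
Si₄-heavy citrate [M−57]⁺ fragment the fully-labeled column retains ~95%,
which is harmless because the solver renormalizes.  Truncated theoretical
envelopes are deliberately *not* renormalized (so widening the window never
shrinks a retained entry); only corrected outputs are strict probability
vectors.

### Default fragment library and isotope table

The shipped fragments are the MOX/TBDMS [M−57]⁺ ions of glutamine,
glutamate, α-ketoglutarate, fumarate, malate, aspartate and citrate, with
formulas derived from the derivatization chemistry (TBDMS replaces an
active hydrogen, net +C6H14Si; methoximation of a ketone, net +CH3N;
[M−57]⁺ loses C4H9).  Different instruments integrate different ions, so
the library is a default, overridable via a TSV
(`cystrace fragments --out my_fragments.tsv`, edit, pass back with
`--fragments`).  Isotope abundances are IUPAC representative terrestrial
values at nominal mass resolution (isobars at the same nominal shift are
summed by construction); the table is versioned and replaceable from YAML.

## Enrichment statistics

`normalized_contribution` divides a metabolite's diagnostic-shift fraction
by the tracer enrichment measured in the same sample (glutamine m+5 by
default; an external reference MID can be passed instead, mirroring
in-vivo designs where plasma enrichment is the reference).  Under a
well-mixed precursor model this ratio is the fraction of the metabolite
pool derived from the tracer.  Per-replicate ratios are computed first and
then averaged — each replicate is normalized to its own enrichment — rather
than dividing condition means; with small enrichment spread the two
conventions differ negligibly, and the per-replicate form gives a
dispersion for testing.

Diagnostic shifts are fixed per metabolite class (m+5 for the five-carbon
pool, m+4 after one oxidative decarboxylation) and configurable per
metabolite.

The comparison statistic ("cystine-induced increase of glutamine
contribution to αKG") is the difference of mean normalized contributions
between a high- and a low-cystine condition, with per-replicate values
retained and a two-tailed unpaired t-test attached (equal-variance
Student's by default — appropriate for the n = 3 designs this targets —
Welch via `equal_var=False`).  No multiple-testing correction is applied;
outputs label p-values as raw.

### Steady-state rule

A labeling time course is declared at isotopic steady state at the endpoint
of the first successive change from which every later successive relative
change is ≤ `rel_tol` (default 0.05); a perfectly constant series is steady
from its first point, and a series whose final change still exceeds the
tolerance is not steady.  The endpoint convention reflects that steadiness
can only be *confirmed* once a small change has been observed.

## Growth and exchange fluxes

`proliferation_rate` is log2(final/initial)/elapsed in doublings/day.
`fit_exponential_growth` fits `N(t) = N₀·e^{rt}` by nonlinear least
squares with residuals weighted by the observed counts (a relative-error
objective).  Cell-count noise is multiplicative, so an unweighted
count-scale objective lets the latest, largest counts dominate and
noticeably widens the doubling-time sampling distribution; the weighted
objective restores near-log-linear efficiency while remaining a nonlinear
regression of the exponential model.  `relative_residuals=False` selects
the unweighted objective.  Two-point data use the exact closed form, which
coincides with the proliferation-rate formula.

`integrated_cell_days` uses the closed form `N₀(e^{rt₁} − e^{rt₀})/r` with
the series limit `N₀(t₁ − t₀)` below |r·Δt| < 1e-12, keeping the function
continuous at r = 0.  `exchange_rate` is (ΔC · volume)/cell·days with ΔC in
µM and volume in mL: 1 µM over 1 mL is 10⁶ fmol, so rates come out in
fmol/cell/day, release positive.  Exchange experiments use the two-point
growth fit (initial and final counts), matching the spent-media design
where only those counts exist.

## Isotope-dilution quantification

Single-point isotope dilution with a unit response factor: concentration =
(analyte signal / internal-standard signal) · standard concentration ·
(mix volume / sample volume).  The default volumes are 10 µL + 10 µL
(dilution factor 2).  Uniformly labeled standards are assumed fully
mass-shifted, so no cross-talk correction is applied; a per-analyte
response factor hook covers calibrated workflows.  `spike_to_enrichment`
solves x/(x + basal) = target for the tracer amount needed to hit a target
enrichment; with the serum glutamine level of 183 µM, a 33% target needs a
90 µM spike.

## Synthetic data generator

Labeling uses a two-parameter mixture per metabolite: the true
diagnostic-shift fraction at time t is `g·e·(1 − exp(−t/τ))` with g the
glutamine-derived fraction of the pool, e the tracer enrichment and τ the
pool turnover time constant; the remainder of the pool sits at m+0, and
the tracer itself has g = 1.  This is the minimal model whose steady state
(g·e) inverts exactly under correction + normalization and whose kinetic
mode reproduces the faster-labeling-under-cystine ordering; it is *not* a
flux network and cannot produce the partial isotopomers (m+1 … m+3) of
multi-turn TCA cycling, which is the main respect in which passing tests
do not certify behavior on real data.  True MIDs are pushed through the
fragment's correction matrix and perturbed with multiplicative lognormal
intensity noise (mean-1 factors).

Defaults and presets (chosen once, as the study conditions):

| parameter | default | basis |
| --- | --- | --- |
| tracer enrichment e | 0.33 | the tracer-spiking design this emulates |
| RPMI-like g (glutamate/αKG/others) | 0.80 / 0.70 / 0.62–0.65 | ~80% glutamate, >60% TCA intermediates in nutrient-rich culture |
| serum-like g | 0.35 / 0.30 / 0.25–0.28 | ~35% glutamate in serum culture |
| serum+cystine g | 0.65 / 0.55 / 0.48–0.50 | intermediate, below full RPMI |
| growth rate | ln2/2 per day (serum), ln2 (RPMI) | 48 hr vs ~24 hr doubling |
| τ (hours) | 1.5 (gln) → 4.5 (asp); ×0.6 under cystine | glutamine steady within 8 h; faster turnover at high cystine |
| noise CVs | 5% intensities, 10% counts, 3% quant signals | typical replicate scatter for these assays |
| media µM (serum preset) | gln 183, glu 192, cystine 0.3 | serum quantification ground truths |
| exchange fluxes (fmol/cell/day) | serum: gln −50, glu +15; +cystine: −100, +60; RPMI: −120, +80 | cystine-stimulated glutamine uptake and glutamate release, plausible per-cell magnitudes |

Per-metabolite g values other than glutamate are interpolated presets, not
estimates.  All generators take a single integer seed
(`numpy.random.default_rng`); identical spec + seed reproduces identical
bytes.  Every dataset ships with a ground-truth sidecar sufficient to score
recovery.

Problem sizes used by the shipped checks: triplicate samples per condition
(n = 10 for the noisy-recovery study), 9 daily time points for growth, 100
seeded runs for the condition-ordering property, 200 simulations for the
doubling-time coverage study.

## Known limitations

* The mixture labeling model omits multi-turn isotopomer fine structure,
  compartmentation, and reverse exchange; normalized contributions are
  precursor-enrichment ratios, not fluxes.
* Natural-abundance correction assumes nominal-mass (unit-resolution)
  envelopes; high-resolution isotope fine structure is out of scope.
* Media exchange assumes constant per-cell flux and no evaporation or
  feeding; depletion is floored at zero with a warning rather than modeled.
* Single-point isotope dilution assumes response linearity through the
  origin; calibration curves are not implemented (hook provided).
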