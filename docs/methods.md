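# Methods

This note documents the models, estimators, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Growth-curve estimation

### Model-free windowed regression

The growth-rate estimator makes no parametric assumption about the growth
curve. It exploits only the fact that during balanced exponential growth
ln OD is linear in time with slope μ:

1. **Blank correction.** Medium-only blank wells are averaged at each time
   point and subtracted from every sample well. The noise floor is
   `max(0.006, mean across time of the between-blank SD)` — 0.006 OD is the
   blank-to-blank variability bound of the targeted instrument setup.
   Corrected values at or below the floor are masked (they never enter a
   regression, and ln of a masked value is never taken); missing cells are
   masked per well rather than dropping the time point plate-wide. Blanks
   whose final mean exceeds three times their initial mean indicate
   contamination and abort the run; a between-blank SD above 0.006 raises
   the floor and flags the plate (`noisy_blanks`).
2. **Seeding.** Every window of duration 5 h anchored at a sample time with
   full coverage is fitted by OLS of ln OD on t over its unmasked points
   (at least 30 required). The window with the maximum slope is the seed;
   slope ties within 1e-12 resolve to the earliest start. Windows are
   defined by duration, not point count, so irregular sampling is
   tolerated.
3. **Expansion.** The seed grows one sample point at a time — the left end
   is tried before the right at each iteration — and an expansion is kept
   only if the refitted slope stays at least 95% of the *seed* slope and
   R² stays above 0.995. Both thresholds are configurable
   (`GrowthParams`); the ratio is always tested against the seed slope,
   not the running slope, which keeps the acceptance region fixed.
4. **Lag.** The lag time is the time of the first unmasked point of the
   final window, and zero when that point is the trace's first unmasked
   point (immediate growers have no lag).

### Estimation versus quality control

`mu` and `lag` are the estimator's output whenever a seed window exists.
`status` separately encodes quality: `growth` requires μ ≥ 0.01 h⁻¹,
final R² > 0.995 and a maximum corrected OD of at least twice the noise
floor; traces failing only the R² gate (or with a negative seed slope) are
`flagged` with their estimates retained for review; `no_growth` covers
everything without a usable signal and is reported as NA in result files.
Replicate summaries average only `growth`-status fits (sample SD, n−1).
Manual outlier curation is replaced by rule-based flags
(`negative_seed`, `marginal_r2` for R² in [0.990, 0.995], `low_r2`,
`diauxic`, `short_trace`) — nothing is dropped silently.

This separation matters because the R² > 0.995 gate is strict: with
additive OD noise of SD 0.006 (the blank-variability scale) the 5-h seed
window at inoculation densities near 0.02 rarely clears it, yet the point
estimates remain accurate (see the recovery benchmark below). On real
traces, per-well read noise is typically well below the between-well blank
variability, and the gate passes.

### Known estimator biases

Two small systematic effects are inherent to the windowed design and are
deliberately left uncorrected:

* **Boundary creep.** On a noiseless trace that switches abruptly from flat
  to exponential, expansion absorbs roughly 0.8 h of flat points before
  the R²/slope criteria reject further growth, biasing the lag early by
  that amount and the slope down by a few percent. (A single flat point
  among ~60 collinear points barely moves R²; rejection is cumulative.)
* **Curvature and the 95% allowance.** On saturating (logistic) curves the
  5-h window already averages a slope slightly below μ, and expansion may
  continue until the slope reaches 95% of the seed value. Together these
  bound the downward bias of μ at roughly 5–10% for typical parameters.

### Diauxie

Biphasic growth from carry-over of a second carbon source is detected from
the rolling 5-h slope profile: the trace is diauxic when an earlier slope
peak, wholly before the main (global-max-slope) window, reaches at least
`peak_ratio` (default 0.2) times μ and is separated from the main phase by
a trough below `trough_ratio` (default 0.5) times the smaller peak's
slope. The end of the initial phase is the last window start whose slope
is still clearly above the trough (trough + 10% of the peak-trough gap, a
numerical localization tolerance), and the adjusted lag is the main-window
start minus that time. The main phase is always the global-max-slope
phase, so a second phase slower than the first is not called diauxic —
a documented consequence of the "earlier peak" definition. Diauxic fits
keep their ordinary lag and report `lag_adjusted` alongside; the flag
marks them for review. On noisy traces the profile can produce spurious
flags; since the flag never alters μ or the primary lag, this errs toward
review rather than silent adjustment.

## Synthetic plates

The trace generator uses a delayed-logistic model — OD constant at the
inoculation density `od0` (default 0.02) until the lag, then logistic
growth toward carrying capacity `K` (default 1.0) — with additive Gaussian
noise (default SD 0.006) truncated at zero, sampled every 5 min over 80 h.
Diauxic traces are piecewise: exponential first phase, plateau, then a
delayed-logistic main phase. A delayed-logistic was chosen over
Baranyi-type models because the fitting algorithm is window-based and
model-agnostic, and this is the simplest model with unambiguous (μ, lag)
ground truth. Plates add a baseline offset (0.08) and at least six blank
wells whose across-well SD stays below 0.006.

What the generator does **not** emulate: spatial plate effects (edge
evaporation, temperature gradients), autocorrelated instrument drift,
condensation artifacts, or biological batch effects between replicates.
Passing recovery tests therefore demonstrate correctness of the estimator
under idealized noise, not robustness to every artifact of real plates.

**Recovery benchmark.** The standard benchmark draws 100 independent
(μ ~ U(0.1, 0.5) h⁻¹, lag ~ U(0, 40) h) pairs (one per seed 0–99) with
noise SD 0.006 and requires the median relative μ error ≤ 5% and median
absolute lag error ≤ 1 h. The dominant error source at low μ is selection
bias: the seed takes the *maximum* of many noisy window slopes, which
inflates μ̂ when the relative noise is large; this partially cancels the
downward curvature bias elsewhere in the range.

## Chemostat physiology

At steady state μ = D, giving `q_s = −D·(S_in − S_res)/X` and
`Y_X/S = X/(S_in − S_res)`; the identity |q|·Y = D holds to floating-point
rounding by construction and is asserted in tests at 1e-12. Consumption
rates carry a negative sign (consumption) in reports; a display option
strips signs.

The CO₂ yield cannot be measured from the liquid phase, so it is estimated
from the fermentation stoichiometry: each mole of ethanol or acetate
produced at the pyruvate node implies one mole of CO₂, and each mole of
formate replaces one, hence `Y_CO2 = M_CO2·(Y_eth/M_eth + Y_ac/M_ac −
Y_for/M_for)`. A formate-dominated (negative) estimate is flagged. CO₂
retained by carbonate/bicarbonate buffering is ignored — the estimate is
purely stoichiometric.

Carbon recovery converts every measured concentration to mol carbon per
litre using free-acid molar masses (HPLC of acidified supernatant measures
free acids): `100 × Σ_i P_i·(nC_i/M_i) / [(S_in − S_res)·(nC_s/M_s)]`.
Biomass carbon (from TOC, at 12.011 g/mol) and the CO₂ estimate are
included by default and individually toggleable; the estimate is skipped
whenever a measured CO₂ concentration is present, so the two never double
count. The synthetic generator can close the balance exactly (residual
carbon assigned to CO₂, TOC set to the biomass carbon), which pins the
recovery computation at 100% ± 1e-9 in tests.

Enzyme assays: specific activity (U per mg protein, 1 U = 1 µmol/min) is
`ΔA₃₄₀/min × V_mL / (6.22 × path_cm × stoichiometric factor × mg
protein)`, using the NAD(P)H extinction coefficient 6.22 AU mmol⁻¹ L cm⁻¹.
Proportionality in the amount of cell-free extract is exact by
construction and asserted in tests.

## Variant consequences

Filtering keeps records with supporting-read fraction ≥ 0.35 **and** depth
≥ 10 (boundary values kept — records are *eliminated* only below the
thresholds); a strict-inequality mode is available. Raising either
threshold can only shrink the kept set (property-tested).

Classification conventions: 1-based inclusive coordinates; insertions
anchored to the base before the inserted sequence; indels left-aligned
before classification; genetic code table 11 with the literal codon
translation reported (the toy generator always uses ATG starts, so
alternative-initiator handling is untested against real genomes);
residue numbering from the initiator; nonsense as `RefAA Pos *` and
frameshift as `RefAA Pos fs` at the first affected codon; for minus-strand
genes the CDS position is counted from the gene's 3'-most genomic base and
alleles are complemented. Upstream/downstream for intergenic variants is
defined relative to the *nearest gene's own strand*, so an element inserted
before the genomic start of a reverse-strand gene is "downstream" of it.
Mobile-element insertions (named alt tokens) are classified by position
only; their internal breakpoints are out of scope.

The classifier is validated two independent ways: against the generator's
constructed truth, and against a full-protein-diff oracle that rebuilds
the entire mutant CDS, translates both proteins and classifies from their
difference. For frameshifts the coordinate-based first-affected codon may
precede the first *observable* protein difference (identical-codon runs),
so the oracle checks `impl ≤ oracle` for the residue and exact agreement
for the category.

Variant *calling* (read mapping, realignment, breakpoint detection) is out
of scope; the module starts from a called variant table (TSV or minimal
single-allele VCF).

## Numerical and design choices

* OLS fits use centered closed-form sums; R² is clamped to [0, 1] and
  defined as 0 for flat signals (a horizontal line explains nothing).
* Expansion order (left before right) is deterministic; alternatives
  differ only at noise level.
* Time is internally always hours; plate files are re-read with
  round-trip float parsing so write/read cycles are bit-exact.
* Display rounding in reports: two decimals for rates and yields, one for
  lag hours; full-precision columns are always written alongside.
* The simulators, the CLI and the acceptance script take explicit seeds;
  identical seeds reproduce byte-identical outputs.
* Problem sizes in the test suite (100-seed recovery benchmark, 200-trace
  window-oracle comparison, 1000 spiked variants) were chosen as the
  smallest sets that exercise each property across its parameter range
  with stable medians.

## Limitations

* The growth estimator reports the steepest sustained ln-OD slope; for
  strongly saturating curves this is a lower bound on the true maximum
  specific growth rate (see the bias discussion above).
* The no-growth call (μ < 0.01 h⁻¹, max OD < 2× floor, or R² never met
  within the horizon) is an operational definition tied to the 80-h
  screening horizon, not a biological statement.
* Carbon recovery treats the compound table's molar masses as exact;
  two-decimal rounding of reported yields makes results insensitive to
  small differences in the table.
* The frequency matrix reports variants as given; it does not merge calls
  that different callers would represent differently (e.g. alternative
  indel anchors beyond left-alignment).
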