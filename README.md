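# evophys

Analysis pipeline for laboratory-evolution studies of *Clostridium
thermocellum* (and similar anaerobes) growing on soluble sugars. It covers
the three computational stages such a study needs, end to end:

1. **Plate-reader growth phenotyping** — extract the maximum specific
   growth rate μ (h⁻¹) and lag time (h) from 96-well OD₆₀₀ kinetics,
   including blank correction, noise masking, diauxie detection, and
   replicate summaries.
2. **Chemostat physiology** — from steady-state measurements at dilution
   rate *D*, compute biomass-specific consumption rates *q*, biomass and
   product yields *Y*, a stoichiometric CO₂-yield estimate, carbon
   recovery, and enzyme specific activities from NAD(P)H assays.
3. **Variant consequences** — filter resequencing variant calls by
   supporting-read fraction and depth, classify them against a genome and
   CDS models (missense / nonsense / frameshift / synonymous / intergenic /
   mobile-element insertion), and build per-isolate mutation-frequency
   matrices.

A synthetic-data module generates plates, steady-state records, and toy
genomes with known ground truth, so the whole pipeline is testable offline.

## The core algorithms

**Growth rate and lag.** During balanced exponential growth,
ln OD(t) is linear with slope μ. The estimator is a two-step windowed
regression: (1) scan all 5-h windows of the blank-corrected trace and fit
ordinary least squares of ln OD on *t* over points above the noise floor
(default 0.006 OD); the window with the maximum slope seeds the fit;
(2) expand the window one 5-min sample at a time (left end first), keeping
an expansion only if the refit slope stays ≥ 95% of the seed slope and
R² > 0.995. Then μ is the final slope and the lag is the start of the final
window (zero for immediate growers). Biphasic (diauxic) curves are detected
from the rolling slope profile, and the adjusted lag is the gap between the
end of the initial phase and the start of the main exponential phase.

**Chemostat stoichiometry.** At steady state μ = *D*, so

    q_s = −D·(S_in − S_res)/X,   Y_X/S = X/(S_in − S_res),   |q_s|·Y_X/S = D

with product yields Y_i = P_i/(S_in − S_res). The CO₂ yield is estimated
from the fermentation products via the molar balance at the pyruvate node
(ethanol + acetate − formate), and carbon recovery is the percentage of
consumed substrate carbon found in products (optionally plus biomass carbon
from TOC and the CO₂ estimate).

**Variant classification** maps each variant into CDS coordinates
(strand-aware), translates reference and alternative codons with the
bacterial genetic code (table 11), and reports protein changes in
three-letter notation (e.g. `Gly148Val`, `Glu115*`, `Ala361fs`); indels
with length not divisible by 3 are frameshifts. Intergenic variants are
annotated with the distance and orientation (upstream/downstream relative
to the gene's own strand) to the nearest gene.

## Worked example

```python
>>> from evophys import (TraceParams, simulate_plate, fit_plate,
...                      summarize_replicates)
>>> plate, layout, truth = simulate_plate(
...     [("evolved", "fructose",
...       TraceParams(mu=0.41, lag=2.0, noise_sd=0.001), 5)], seed=7)
>>> fits = fit_plate(plate, layout)
>>> keys = [("evolved", "fructose")] * len(fits)
>>> s = summarize_replicates(fits, keys)[0]
>>> print(f"mu = {s.mu_mean:.2f} +/- {s.mu_sd:.2f} 1/h, "
...       f"lag = {s.lag_mean:.1f} +/- {s.lag_sd:.1f} h, "
...       f"growth in {s.n_growth}/{s.n_total} wells")
mu = 0.37 +/- 0.00 1/h, lag = 1.4 +/- 0.1 h, growth in 5/5 wells
```

Five simulated replicates of an evolved isolate on fructose (true
μ = 0.41 h⁻¹, lag 2.0 h, 0.001 OD per-well read noise) are fitted back to
0.37 ± 0.00 h⁻¹ with a 1.4 ± 0.1 h lag: the windowed estimator carries a
small, documented downward bias (logistic curvature inside the window plus
the 95%-of-seed expansion allowance) and all five wells pass the
R² > 0.995 quality gate. At noisier settings the same fits are retained
with status `flagged` instead of entering the replicate means — see
`docs/methods.md` for how estimation and quality control are separated.

On the chemostat side:

```python
>>> from evophys import ChemostatRecord, steady_state_physiology
>>> rec = ChemostatRecord(substrate="glucose", D=0.10, S_in=4.8, S_res=0.02,
...                       X=0.447, products={"ethanol": 0.67, "acetate": 1.34,
...                                          "formate": 0.29})
>>> res = steady_state_physiology(rec)
>>> print(f"q = {res.q_substrate:.2f} g/g/h, Y = {res.Y_biomass:.2f} g/g, "
...       f"Y_CO2 = {res.Y_co2_est:.2f} g/g")
q = -1.07 g/g/h, Y = 0.09 g/g, Y_CO2 = 0.28 g/g
```

i.e. a glucose-limited culture at *D* = 0.10 h⁻¹ consumes glucose at
1.07 g per g biomass per hour, yielding 0.09 g biomass and an estimated
0.28 g CO₂ per g glucose.

A command-line interface mirrors the library
(`evophys fit-growth | summarize | chemostat-yields | enzyme-activity |
annotate-variants | simulate-*`); every command writes a `manifest.json`
with parameters, seed, and input digests so runs are reproducible.

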