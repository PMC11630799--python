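# radhab

Radiolytic habitability analysis for deep subsurface brines: how long can
microbial populations persist in fracture fluids irradiated by in-rock
radionuclide decay, and what do their genomes say about how they make a
living there?

The package is aimed at geomicrobiologists and astrobiologists working on
low-biomass, long-isolated fluid systems (deep mine brines, shield
fracture waters, analogue planetary brines). It implements three groups
of computations:

1. **Dose model.** An irradiation scenario is an absorbed dose rate Ḋ
   (Gy/yr) plus a particle mix (f_α, f_β, f_γ). The biologically weighted
   rate is

       Ḋ_eff = Ḋ · (f_α·w_α + f_β·w_β + f_γ·w_γ)

   with configurable weighting factors (default w_α = 20, w_β = w_γ = 1,
   the standard radiation-protection quality factors). Radiolytic
   production of water-splitting products (H₂, H₂O₂, OH·, …) follows the
   G-value model, P = (G/100) · Ḋ · ρ · (eV/J) / N_A in mol · L⁻¹ · yr⁻¹.

2. **Survival model.** Inactivation is single-hit exponential:
   S(D) = 10^(−D/D₁₀). Published survival curves are fitted by least
   squares on log₁₀ S vs dose (intercept pinned to 0 when the curve
   includes the unirradiated control) to extract the decimal-reduction
   dose D₁₀; the dose at which a 10⁻⁶ population fraction remains is
   6·D₁₀, and the time to inactivation of a dormant population is
   t = D_thresh / Ḋ_eff. Thresholds for three reference organisms ship as
   published constants: *E. coli* 1000 Gy, *B. subtilis* 8400 Gy,
   *D. radiodurans* 15 000 Gy.

3. **Annotation and QC rules.** Module completeness (fraction of a
   metabolic module's steps with ≥1 annotated gene family), threshold
   presence calls (strict > 0.70 for KEGG-module style matrices,
   non-strict ≥ 0.75 for nutrient-cycling pathway calls), genus-level
   aggregation over the top-3 most complete genomes per genus, family
   composition and cross-fluid shared-taxon detection; plus the genome
   retention filter (completeness ≥ 1%, contamination ≤ 10%), bin
   tiering, the contig trim-then-length rule (−100 bp per end, keep
   > 2000 bp), and genus assignment by best ANI hit at ≥ 95%.

A seeded synthetic-data generator (`radhab.simulate`) produces taxonomy,
annotation, quality and survival-curve fixtures with planted ground
truth, so the whole pipeline is testable without any sequence downloads.

## Worked example

The numbered drivers under `analysis/` run the full study workflow on
packaged presets and synthetic fixtures, writing tables under `results/`:

```
python analysis/01_survival_scenarios.py
```

prints, among the six scenarios (excerpt):

```
west_rand_low_gamma  (0.02 Gy-eq/yr weighted)
  E. coli         <= 50 000 yr
  B. subtilis     <= 420 000 yr
  D. radiodurans  <= 750 000 yr
...
vaal_reef_high_alpha  (6 Gy-eq/yr weighted)
  E. coli         <= 170 yr
  B. subtilis     <= 1 400 yr
  D. radiodurans  <= 2 500 yr

Longest survival: D. radiodurans under west_rand_low_gamma (750 000 yr).
```

Reading: at the low-uranium dose rate (0.02 Gy/yr) under pure gamma
irradiation, a dormant *D. radiodurans* population would take 750 000
years to accumulate its 15 000 Gy inactivation dose; alpha-dominated
irradiation at the high rate shortens every organism's horizon to a few
thousand years at most. `02_radiolysis_production.py` reports the
corresponding radiolytic H₂/H₂O₂/OH production (e.g. 1.4 × 10⁻⁸ mol
H₂ · L⁻¹ · yr⁻¹ at 0.3 Gy/yr), `03_annotation_profiles.py` builds the
95-genome synthetic brine community (55 of 95 genomes — 58% — in the
dominant halophile family) and its module/pathway matrices, and
`04_qc_filters.py` exercises the retention rules (95 of 121 synthetic
single-cell genomes retained).

The same functionality is scriptable through the `radhab` CLI
(`simulate`, `dose`, `survival`, `profiles`, `qc`); every run writes a
`provenance.json` with the package version, seed and config hash.

## Layout

- `src/radhab/` — the library: `dose`, `survival`, `annotations`, `qc`,
  `simulate`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
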