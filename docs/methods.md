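# Methods

## Dose model

An irradiation scenario is specified by an absorbed dose rate Ḋ in gray
per year and a particle mix (f_α, f_β, f_γ) summing to 1. The
biologically weighted ("effective") rate multiplies each component by a
relative-biological-effectiveness weighting factor:

    Ḋ_eff = Ḋ · (f_α w_α + f_β w_β + f_γ w_γ)   [Gy-eq/yr]

Defaults are w_α = 20, w_β = w_γ = 1 — the standard radiation-protection
quality factors, chosen because densely ionising alpha tracks cause far
more biological damage per unit absorbed dose than sparsely ionising
gamma rays. The weighting is configurable per run: quality factors are a
protection-oriented convention, and organism- or endpoint-specific RBE
values can differ. Accumulated dose over an interval is Ḋ_eff · t
(constant-rate assumption; no decay-chain ingrowth or rate evolution,
which is reasonable for the ≤10⁶-yr horizons considered against the
multi-Gyr half-lives of ²³⁸U, ²³²Th and ⁴⁰K).

The two reference dose rates — 0.02 Gy/yr for ~1 μg/g-U host rock and
0.3 Gy/yr for ~100 μg/g-U host rock — ship as opaque named presets
(`west_rand_low`, `vaal_reef_high`). The ppm→dose-rate mapping is site
specific (geometry, stopping-power partitioning between rock and pore
fluid) and visibly non-linear between these presets, so the package
deliberately does not derive them; a generic linear
inventory→dose helper exists for user-supplied per-ppm coefficients
only.

Radiolytic production uses the G-value formalism: a species with yield G
molecules per 100 eV is produced at

    P = (G/100) · Ḋ · ρ · 6.2415×10¹⁸ eV/J / 6.0221×10²³ mol⁻¹   [mol/L/yr]

with ρ the water density in kg/L (default 1). The packaged defaults are
standard pure-water gamma-radiolysis primary yields (G(H₂)=0.45,
G(H₂O₂)=0.70, G(OH)=2.70, G(e⁻aq)=2.60, G(H)=0.60); O₂ is a secondary
product and carries a primary yield of 0. Salinity and LET dependence of
G-values are real (halide scavenging raises molecular yields in brines)
but out of scope; the table is user-replaceable.

## Survival model

Inactivation is modelled as single-hit exponential (log-linear):
S(D) = 10^(−D/D₁₀), where D₁₀ is the decimal-reduction dose. This is the
minimal model consistent with extrapolating published curve points to
very low surviving fractions, and it makes the 10⁻⁶ threshold exactly
6·D₁₀. Shouldered (e.g. linear-quadratic) kinetics are not fitted; the
fit reports R² of the log-linear regression as a shoulder diagnostic,
and a non-decreasing curve is rejected as non-inactivating rather than
silently producing a negative D₁₀.

Fitting: least squares on y = log₁₀ S versus dose. When the curve begins
at the unirradiated control (0, 1), the intercept is pinned to 0 (the
slope is then Σ D·y / Σ D²); otherwise both slope and intercept are
free. D₁₀ = −1/slope.

Time to inactivation under a scenario is t = D_thresh / Ḋ_eff. A zero
effective rate returns an explicit "never" sentinel (infinite time), not
an error or a division failure. All times describe **dormant,
non-repairing** populations passively accumulating damage; metabolically
active cells performing continuous repair would persist longer, and
mixed-community effects (shielding, cross-feeding of protective
solutes) are not modelled. Every result object carries the dormancy
assumption as a flag, and formatted reports state it. Reported times are
rounded to 2 significant figures in human-readable output; machine
output keeps full precision.

Packaged thresholds (accumulated dose at 10⁻⁶ survival, tagged
`source="published"`): *E. coli* 1000 Gy, *B. subtilis* 8400 Gy,
*D. radiodurans* 15 000 Gy — a radio-sensitive / radio-tolerant /
radio-resistant triplet. Users can instead supply curve points and fit.

## Annotation summaries

A module definition is an ordered list of steps, each step a set of
alternative gene families, any one of which satisfies the step. This
flat "steps with alternatives" structure covers the common OR-blocks of
KEGG-style module grammars without implementing the full nested boolean
grammar; complex definitions should be pre-flattened. Completeness is
the satisfied-step fraction; gene copy number beyond presence is
ignored (an annotation is either found or not). The denominator is
steps, not raw genes; a raw-gene-fraction mode was considered and
rejected for the default because step structure is what makes
alternatives meaningful, but the completeness matrix is threshold-
agnostic, so either convention can be layered on top by the caller.

Presence calls: strict `> 0.70` for module-matrix calls and non-strict
`>= 0.75` for nutrient-cycling pathway calls — both comparators
deliberate, both overridable. Genus aggregation selects each genus's
top-N (default 3) genomes by completeness, breaking ties by lower
contamination then genome id (determinism across runs), and calls a
pathway present for the genus if any selected genome has it.

Family composition reports exact fractions (summing to 1) alongside
half-up integer percents for labels; genomes lacking a family assignment
are grouped under an explicit "unassigned" bucket. Shared-taxon
detection intersects non-empty names at one of the seven canonical
ranks.

## QC rules

* Single-cell genome retention: completeness ≥ 1% **and** contamination
  ≤ 10%. The boundary semantics derive from the exclusion wording of the
  source rules ("<1% … not considered", ">10% … not considered"): the
  retained complements are inclusive. Comparators are explicit fields
  and overridable.
* Bin tiers: high = completeness > 90 and contamination < 5; medium =
  not high, completeness ≥ 50 and contamination < 10; else fail.
  Mutually exclusive, exhaustive.
* Contigs: trim 100 bp from each end **before** the length test, then
  retain strictly > 2000 bp. Trim-first ordering matches the stated
  processing order of the assembly workflow this emulates.
* ANI genus assignment: an unassigned genome inherits the genus of its
  highest-ANI annotated partner at ≥ 95% identity; equal-ANI ties break
  lexicographically on reference id.

## Synthetic data

Generators are pure functions of (spec, seed). One global seed fans out
to per-stage substreams as `seed XOR crc32(stage_name)` masked to 31
bits, so each stage can be regenerated independently.

* Taxonomy: integer family counts by largest-remainder apportionment of
  the target proportions (avoids the drift of independent rounding; ties
  on remainder break by family name). Default composition is the
  eight-family brine collection at n = 95, with a three-family +
  aggregated-tail variant also packaged.
* Annotations: per (genus, module) targets are snapped to the nearest
  achievable step fraction k/n_steps (half rounds up; a warning reports
  any snap), then exactly k randomly chosen steps are populated via one
  randomly chosen alternative each. Untargeted modules get nothing, so
  the scorer must return exactly the planted value — the
  generator–scorer round trip is the oracle for both sides.
* Quality: uniform draws within configurable ranges, plus a dedicated
  threshold-straddling fixture that plants an exact number of
  retention-filter passers (default 95 of 121) with failures rotating
  among completeness-only, contamination-only and both.
* Survival curves: n points evenly spaced on [0, 6·D₁₀];
  S = 10^(−D/D₁₀ + ε) with ε ~ Normal(0, σ) in decades (default
  σ = 0.1, n = 6), clipped at 1. The zero-dose point is emitted as the
  exact control (0, 1) — published curves are normalised to the
  unirradiated control, and this keeps the surviving-fraction invariant.
  At the default geometry the clip never binds beyond dose 0. At
  σ = 0.1 the intercept-pinned estimator has a relative sd on D₁₀ of
  ≈1%, so the 10%-recovery property test is a wide-margin check of the
  whole generate→fit loop, not a tuned threshold.

What the generators do **not** emulate: sequence content, assembly
artefacts, correlated annotation error, phylogenetic structure within
genera, or covariance between completeness and annotation recovery.
Passing tests therefore demonstrate the correctness of the rules and
estimators as specified, not robustness to real-data pathologies such
as systematically incomplete single-cell assemblies.

## Numerical and design notes

* Particle-mix validity is checked to |Σf − 1| ≤ 1e-9; weighted-rate and
  time computations are closed-form, with property tests asserting
  linearity, additivity and inverse-rate scaling at 1e-12 relative
  tolerance.
* The survival grid orders deterministically (scenario-major, organism
  order as given); duplicate organism or scenario labels are rejected
  outright.
* All tabular IO is single-header TSV; FASTA via Biopython. Every
  pipeline run writes `provenance.json` (version, seed, config hash) and
  omits timestamps so reruns are byte-identical.
* Problem sizes used in the shipped analyses and tests — 95-genome
  collections, 100 × 50 completeness grids, 1000-replicate recovery
  simulations, 200-contig filters — keep every stage comfortably
  desk-scale while exercising all boundary cases.

## Known limitations

* Constant dose rate over the whole horizon; no decay-chain or
  geometry/transport modelling, no neutron dose.
* Single-hit inactivation only; no dose-protraction or repair kinetics.
* Pure-water G-values as defaults; brine-specific yields must be
  supplied by the user.
* The module grammar is flat; deeply nested boolean definitions need
  pre-flattening.
* Percent labels use half-up rounding; collections whose true
  composition sits near rounding boundaries can print label sets that
  do not sum to exactly 100.
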