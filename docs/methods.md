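# Methods

## The reporter model

A mitochondria-targeted tandem mCherry-EGFP fusion fluoresces in both
channels at cytosolic pH ("yellow" mitochondria) and in mCherry only after
delivery to the acidic lysosome, where EGFP is quenched ("red-only"
mitolysosomes). The analysis treats each segmented mitochondrial structure as
one object and classifies it from the ratio of background-corrected
integrated intensities, `r = ∫EGFP / ∫mCherry`: red-only iff `r <
ratio_threshold`. The per-cell red-only count is the mitophagy index; a field
is summarised by its mean over included (non-border) cells.

`ratio_threshold` defaults to 0.3. Yellow objects have `r ≈ 1` by
construction of the reporter; a red-only object's EGFP content is only
spectral bleedthrough (2% by default), so `r ≈ 0.02–0.05`. The threshold
sits an order of magnitude above the bleedthrough floor and three-fold below
the yellow population, which is why classification is exact on clean images;
it is exposed on the CLI because real acquisitions with different filter
sets may need a different cut.

## Segmentation

- **Nuclei** — Gaussian smoothing (σ = 2 px), Otsu threshold, connected
  components, minimum area 50 px. Components larger than
  `nucleus_split_area` (200 px) are declumped by a distance-transform
  watershed whose peaks must be ≥ 7 px apart; two nuclei blurred together
  below that separation deliberately stay one object (the rule is tested,
  not hidden). A flat channel yields zero nuclei with a warning.
- **Cells** — seeded watershed from the nuclei over the smoothed mCherry
  channel, the one channel present on every reporter-bearing structure. The
  foreground mask uses the lower cut of a three-class Otsu (background | dim
  diffuse cell body | bright organelles) at half weight, which keeps the dim
  cytosolic haze and the rolled-off cell rim inside the mask; nuclei are
  always foreground. Cells touching the field border are flagged and
  excluded from summaries by default (truncated cytoplasm biases counts).
- **Mitochondrial structures** — median background subtraction (fields are
  mostly background), light smoothing (σ = 0.5 px), Otsu threshold over the
  positive residual, 8-connected components, minimum object size 4 px.
  Objects are assigned to the cell under their mCherry-weighted centroid;
  a centroid on background leaves the object unassigned. Label 0 is
  background everywhere; pixel indices are 0-based row-major.

Scale invariance: every threshold is derived from the image (Otsu family),
and the classification ratio is homogeneous of degree zero, so multiplying
both reporter channels by any c > 0 changes no label — a property test.

## Colocalization

LC3 puncta are detected with the same spot recipe on the LC3 channel. A
mitochondrial object counts as colocalizing when ≥ `overlap_min` (default
0.5) of its pixels are LC3-positive; mitochondria are the reference set.
The per-cell ratio of integrated mCherry to integrated LC3 over LC3-positive
pixels is emitted as a secondary, intensity-based readout. Cells without
mitochondrial objects have an undefined fraction and are excluded (logged).

## Tissue quantification

Motor-neuron (MN) boundaries are either supplied as label masks (mirroring
manual delineation on the TOMM20 stain) or derived automatically (smoothed
TOMM20, Otsu, hole filling, minimum area 300 px). Marker positivity (p62,
TOMM20) is an Otsu threshold restricted to the union of MN masks; a channel
that is uniform inside the union is treated as all-positive if nonzero.
Areas are reported in px and as a fraction of MN area; 10–15 MN per stack is
expected and deviations warn. Aggregation is strictly hierarchical: MN →
stack mean → animal mean → group mean ± SEM with n at the animal level. The
group mean is therefore invariant to duplicating records within a stack and
generally differs from the pooled-MN mean on unbalanced designs (tested
against a hand-computed oracle).

## Screen statistics

Percent inhibition of an induced response is
`100·(inducer − treated)/(inducer − control)`; it is affine-invariant,
undefined (an error) when the inducer did not exceed control, and values
above 100% are retained with a flag. A compound is a hit when inhibition
reaches the 50% threshold **and** its Dunnett-adjusted p-value against the
inducer condition is below α = 0.05 with the treated mean below the inducer
mean. The replicate unit for all tests is the independent experiment (field)
mean, never the single cell, to avoid pseudo-replication.

Dunnett's many-to-one adjustment uses the exact multivariate-t rectangle
integral (scipy) for families of up to 8 comparisons; wider families (the
49-compound screen) use the package's seeded Monte Carlo of the max-|t| null
with 2·10⁵ draws, exploiting the one-factor correlation structure
corr(T_i, T_j) = λ_i λ_j with λ_i = √(n_i/(n_i+n₀)). The two routes agree to
|Δp| < 0.01 at k = 12 (tested), and a single comparison reduces exactly to
the two-sided Student t-test. The equicoordinate critical value (brentq on
the seeded rectangle probability) backs the familywise-error simulation:
rejection iff max|t| exceeds it, which is the same decision rule as the
per-comparison adjusted p against α. The Shapiro–Wilk gate is reported but
does not switch tests to nonparametric alternatives; the autophagy flux
ratio is LC3-II with inhibitor over without (the LC3-II difference is a
secondary column).

## The synthetic-microscopy generator

The generator is the testing oracle: it emulates the assay, not any
particular microscope.

- Cells are non-overlapping disks (radius 16 ± 1.5 px, truncated at ±3 sd)
  on a jittered grid with ≥ 4 px clearance; infeasible packings (more cells
  than grid slots, or mean cell area × n over 80% of the field) raise an
  explicit error. A nucleus disk (0.32 r) is rendered in the nuclei channel.
- The mitochondrial network is a set of dilated random chords through the
  cytoplasmic annulus, rendered with equal EGFP and mCherry amplitude
  (100 ± 15% per object, identical factor in both channels so the ratio
  carries no expression-level signal).
- Acidified mitolysosomes are compact disks (radius 2–3 px) rendered in
  mCherry only. Per-cell counts are Poisson(λ·m) with λ the basal
  `acidified_rate` (default 1) and m the treatment's multiplier. Puncta are
  placed **first**, by exact feasibility masks (distance-transform
  geometry), and the network is carved with a ≥ 3.5 px moat around them, so
  the Poisson law is untruncated at the rates used (λ ≤ 4; at λ = 9 about
  20% truncation remains and no test asserts the mean there).
- Separation discipline: all distinct rendered structures keep ≥ 3 px gaps
  (pairwise punctum margin 3; network pieces closer than 3.5 px to a larger
  kept piece are dropped; sub-width slivers are removed by opening). At the
  default PSF (Gaussian σ = 0.8 px) inter-object bridges stay far below any
  detection threshold, which is what makes noise-free recovery exact rather
  than approximate.
- A lysosomal block (BafA1 added late in the treatment) reverts the realized
  red-only count to the basal law Poisson(λ) — the pre-block steady state —
  and renders the induced excess Poisson(λ·(m−1)) as dual-channel puncta.
  Blocked fields are therefore statistically identical to untreated control
  in the red-only readout, matching the biology of a short late block.
- Optional LC3: free puncta (Poisson per cell, scaled by the treatment's
  `lc3_multiplier`) placed clear of mitochondria, plus LC3 painted exactly
  on a Bernoulli(`lc3_mito_overlap_fraction`) subset of mitochondrial
  objects, so the planted colocalization fraction is known.
- Imaging model: Gaussian PSF (σ = 0.8 px default), symmetric 2% spectral
  bleedthrough between EGFP and mCherry, then Poisson shot noise
  (`poisson_scaling` = 0.5 photons per intensity unit) and Gaussian read
  noise (sd = 2). A dim cytosolic haze (6 units) over the cell body stands
  in for out-of-focus light and gives cell segmentation a realistic support.
- Tissue sections render MN somata (radius 24 ± 3 px) with a nuclear stain,
  a TOMM20 fill of exactly `round(fraction · area)` pixels nearest the soma
  centre, and Poisson-count p62 puncta; group effects scale the p62 rate and
  the TOMM20 fill. Cohorts advance seeds by a running counter.
- Determinism: one `numpy` Generator per field seeded from the config;
  identical (config, effect, seed) is bit-identical. Dose series use seeds
  `base + dose_index`, so a one-element series equals a single field.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: 3-D optics and confocal sectioning (tissue stacks
are treated as projections), photobleaching, autofluorescence, cell-shape
irregularity, touching/overlapping cells, uneven illumination, and
expression-level heterogeneity beyond ±15% per object. Results on real
microscopy will degrade where those factors break the separation discipline
above; the configurable thresholds exist for exactly that case.

## Problem sizes and numerical choices

- End-to-end recovery checks use 100-cell fields (456×456 px); small unit
  fixtures use 16-cell fields (200×200 px).
- The screen emulation runs 48 inert + 1 planted compound (multiplier 0.4 =
  60% effect) with 3 replicate fields per condition: once at 100 cells/field
  with a fixed seed, and 20 replicate screens at 50 cells/field for the
  sensitivity/false-hit rates — the planted effect (~90% inhibition) is ~13
  within-condition standard errors at the smaller size, so the two scales
  are equivalent for hit calling.
- Familywise-error calibration: k = 3 treatments vs control, n = 5, 10,000
  simulated datasets, decision by the equicoordinate critical value.
- Degenerate inputs have defined behaviour: flat channels give zero objects
  with warnings; identical constant groups give t = 0, p = 1 while two
  different constant groups are an error; groups with n < 3 skip the
  normality gate; fewer than 2 animals report a mean with undefined SEM.
- Ties: object centroids are resolved to the integer pixel they fall in
  (row-major floor); equal-size network pieces are ordered by label id.

## Known limitations

- The generator's defaults are chosen for testability (well-separated
  structures, known amplitudes); they are not calibrated to any real
  per-cell count distribution, which the source assay does not report.
- Otsu-family thresholds assume bimodal/trimodal intensity histograms; very
  sparse or very dense real fields may need manual thresholds.
- The Monte-Carlo Dunnett p-values carry ~2·10⁻³ sampling error; exact
  integration is used wherever the family is small enough to afford it.
- Tissue mode quantifies 2-D projections only and does not locate the
  ventral horn or classify neurons beyond size gating.
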