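# mitoquant

Quantification pipeline for tandem mCherry-EGFP mitophagy reporter imaging,
with a synthetic-microscopy testbed that supplies exact ground truth.

## The problem

Mitophagy — the selective autophagic degradation of mitochondria — can be read
out with a mitochondria-targeted mCherry-EGFP fusion. At cytosolic pH both
fluorophores emit and mitochondria look *yellow*; once a mitochondrion is
delivered to the acidic lysosome (~pH 4.9) EGFP is quenched and the structure
turns *red-only*. Counting red-only structures per cell therefore measures the
mitophagy rate, and the readout responds in the expected directions to an
iron-chelator inducer (DFP), to small-molecule inhibitors, and to bafilomycin
A1, which neutralises the lysosome and abolishes the signal.

`mitoquant` implements the full analysis around that reporter for people who
need a tested, scriptable alternative to an ad-hoc CellProfiler pipeline:

- **Reporter quantification** — nuclei segmentation, seeded-watershed cell
  segmentation, spot/structure detection on the mCherry channel, and per-object
  classification by the ratio of integrated intensities
  `r = EGFP / mCherry` (red-only iff `r < 0.3` by default). The per-cell
  red-only count is the mitophagy index; the field summary is its mean.
- **Colocalization** — LC3 puncta per cell and object-based mitochondria-LC3
  overlap (a mitochondrial object colocalizes when ≥ 50% of its pixels are
  LC3-positive), plus the per-cell mCherry/LC3 integrated-intensity ratio.
- **Tissue mode** — p62 and TOMM20 stained area per motor neuron in spinal-cord
  sections, aggregated hierarchically: MN → stack mean → animal mean → group
  mean ± SEM over animals (never pooled over MN).
- **Screen statistics** — percent inhibition of an induced response,
  `100·(inducer − treated)/(inducer − control)`, with hit calling at a 50%
  threshold gated by Dunnett-adjusted significance against the inducer
  condition; Shapiro–Wilk normality gate; unpaired two-tailed Student t-test;
  one-way ANOVA + Dunnett many-to-one comparisons; the LC3-II autophagy flux
  ratio (intensity with / without lysosomal inhibitor).
- **Synthetic microscopy** — `mitoquant.simulate` renders multi-channel fields
  (nuclei, EGFP, mCherry, optional LC3) and tissue sections with
  Poisson-distributed red-only puncta, treatment effects, spectral
  bleedthrough, Gaussian PSF and Poisson-Gaussian noise — emitting exact
  per-cell and per-object ground truth so every stage can be tested against a
  known answer.

## Worked example

```bash
python analysis/01_simulate_example_fields.py
python analysis/02_quantify_reporter.py
```

prints, for 100-cell fields under the three canonical conditions:

```
     control: 1.02 red-only/cell over 100 cells
         dfp: 2.87 red-only/cell over 100 cells
   dfp_bafa1: 0.98 red-only/cell over 100 cells
```

The untreated control sits at its basal rate (λ = 1 by construction), DFP
induction triples it, and the BafA1 arm collapses back to control level —
the quantified means here equal the generator's ground truth exactly. The
remaining drivers run the dose-response trend (`03`, Spearman ρ = −1.0 across
5 doses), the 48+1 compound screen (`04`, the planted inhibitor is the only
hit at 92.7% inhibition, Dunnett p < 10⁻⁵), and the tissue cohort (`05`,
transgenic p62 reduced to 0.59× wild type with the rescue arm intermediate).

The same operations are exposed as a CLI:

```bash
mitoquant simulate --n-fields 3 --treatment dfp --multiplier 3 --out sim/
mitoquant quantify --input sim/ --ratio-threshold 0.3 --out quant/
mitoquant screen   --input plate.csv --out screen/
```

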