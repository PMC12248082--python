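# sacmorph

Quantification toolkit for starburst amacrine cell (SAC) biology and the
direction-selective retinal circuit: single-cell dendrite morphometry,
soma-mosaic spacing statistics, inner plexiform layer (IPL) lamination
profiling, synaptic-puncta compartmentalization, and direction-selective
ganglion cell (DSGC) classification from multielectrode-array (MEA)
recordings — together with seeded synthetic-data generators that emulate
the statistical structure of each data type, so the entire pipeline is
testable without any imaging or electrophysiology data.

It is written for retinal neurobiologists who quantify reconstructed
neurons (SWC), soma coordinate tables (CSV), sorted MEA units (JSON spike
counts), depth-intensity profiles and puncta tables, and for method
developers who need reproducible, oracle-tested reference implementations
of the classic measures.

## The measures

* **Morphometry** (per reconstructed cell): total dendritic length; branch
  points (nodes with ≥ 2 children, soma excluded); dendritic field area as
  the 2-D convex hull; Sholl intersection profiles at fixed radius steps,
  normalized as mean counts over each 10% of the radial extent; dendrite
  self-crossings within single z-planes; caliber classification — any
  dendrite over 1 μm in diameter counts as *hypertrophic*; soma area.
* **Mosaic spacing**: nearest-neighbour regularity index (mean/SD of NN
  distances, ≈ 1.91 for complete spatial randomness), a regularity-index
  ratio against matched random simulations, and the Rodieck density
  recovery profile (DRP) with its effective exclusion radius.
* **Lamination**: intensity-vs-depth profiles reduced to 20 equal IPL
  bins of intensity fractions; background-normalized ROI intensities.
* **Puncta**: exclusion of puncta under 0.5 μm equivalent diameter,
  counts/volumes/soma distances, and the fraction localized to the outer
  third of the arbor.
* **DSGC classification**: units with ≥ 400 total spikes, direction
  selectivity index DSI = (P − N)/(P + N) > 0.37, a von Mises tuning fit
  r(θ) = b + A·exp(κ(cos(θ − μ) − 1)) with R² > 0.5, and ≥ 10 average
  spikes in the preferred direction are classified as putative DSGCs;
  tuning width is the closed-form FWHM = 2·arccos(1 − ln2/κ).
* **Statistics**: Student's t / ANOVA + Tukey HSD / Kruskal–Wallis, Sholl
  area-under-curve comparisons, and a from-scratch two-sided Fisher exact
  test (sum of hypergeometric probabilities ≤ that of the observed table).

## Worked example

Generate a synthetic conditional-knockout-like SAC and measure it:

```python
from sacmorph.synth import ArborGenParams, gen_arbor, GENOTYPE_PRESETS
from sacmorph.morphometry import morphometry

preset = dict(GENOTYPE_PRESETS["pten_cko"]); preset.pop("hypertrophic_prob")
arbor = gen_arbor(ArborGenParams(seed=11, hypertrophic=True, **preset))
result, sholl = morphometry(arbor)
print(result.total_length, result.n_branch_points, result.is_hypertrophic)
```

prints `11809.1  385  True`: an arbor with ~11.8 mm of dendrite, 385
branch points, and a hypertrophic primary dendrite (max caliber 1.68 μm >
1 μm). The field area is 45,226 μm² with a 150 μm radial extent.

A full cohort study — synthetic control vs knockout cohorts, per-cell
morphometry, group statistics and Fisher's exact test on hypertrophic
counts — runs from one seed:

```python
from sacmorph.pipeline import RunConfig, run_cohort_study

report = run_cohort_study(RunConfig(
    seed=1, n_control=12, n_cko=16,
    forced_hypertrophic={"control": 1, "cko": 13}))
h = report["hypertrophic"]
print(h["control"], h["cko"], round(h["fisher_p"], 6))
```

prints `1/12 13/16 0.000341`: 8.33% of control cells and 81.25% of
knockout cells carry a hypertrophic dendrite, and the two-sided Fisher
exact p-value for that contingency prints as 0.0003. From the shell,
`sacmorph stats fisher 13 3 1 11` prints
`two-sided Fisher exact p = 0.000341006`.

The same operations are available from the shell:

```
sacmorph simulate arbor out.swc --seed 1 --branch-rate 0.3
sacmorph analyze morphometry out.swc --out metrics.csv
sacmorph analyze ds responses.json --out dsgc.csv
sacmorph stats fisher 13 3 1 11
sacmorph run config.toml
```

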