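# cytolink

Quantitative cell–cell connectivity analysis for arrayed extracellular
receptor–ligand screens and downstream multicellular modelling. The
package covers the full chain from raw screen plates to predicted and
measured cell–cell interaction changes:

- **`cytolink.screen`** — two-way Tukey median polish of bait×prey
  absorbance matrices, orientation summation (homophilic doubling),
  primary-hit selection at a signal threshold, 3×-weighted combination
  with a secondary screen, promiscuous-binder filtering (top-1,000 /
  >20-appearance rule) and ROC / precision–recall benchmarking against
  positive/negative reference pair sets.
- **`cytolink.interactome`** — expression binarization (10 %
  single-cell detection, strict-majority bulk replicates), enumeration
  of the per-cell-pair interaction key, affinity profiles (log-scale and
  arithmetic mean K_D), the activation affinity-switch Welch test with
  Holm correction, and eigenvector centrality of the weighted cell-type
  graph with Welch/BH group testing.
- **`cytolink.kinetics`** — copies-per-cell → spherical surface
  density, 3D→2D dissociation-constant conversion, saturation-binding
  bound densities, summed cell-pair relative affinities, a
  law-of-mass-action doublet ODE integrated to equilibrium,
  imaging-compatible interaction scores, protein-knockout perturbation
  and the top-third prediction/measurement comparison (one-sided Welch,
  BH, one-fifth-of-median eligibility).
- **`cytolink.spatial`** — spot QC (4,000–36,000 counts, <20 % mito,
  ≥2,000 genes, genes in ≥5 spots), 150-unit self-inclusive neighbor
  graphs, receptor–ligand colocalization scores, permuted-pair nulls and
  ANOVA + Tukey HSD group comparison.
- **`cytolink.imaging`** — 40-px nuclear-centroid contact detection per
  image site, random-mixing-normalized interaction scores, control
  normalization bounded in [−1, 1], Welch testing at 10 % FDR.
- **`cytolink.synthetic`** — seeded generators for every input: screen
  matrices with additive plate effects and planted binder pairs,
  expression with activation fold changes, zonated spot lattices, and
  imaging cell tables with planted pairwise association preferences —
  each returning its ground truth for end-to-end testing.

## CLI

```sh
cytolink simulate screen --seed 1 --out out/sim        # synthetic inputs + truth
cytolink screen process --primary out/sim/primary.tsv \
    --secondary out/sim/secondary.tsv --out out/proc   # polish/score/filter
cytolink screen benchmark --scores out/proc/pair_scores.tsv \
    --positives positives.tsv --seed 1 --out out/bench
cytolink integrate key|affinity|switch|centrality ...  # expression integration
cytolink model equilibrate|perturb ...                 # mass-action model
cytolink coloc --spots ... --counts ... --network ...  # spatial colocalization
cytolink imaging --cells cells.tsv --out out/img       # imaging scores
cytolink run-all --seed 1 --out out/run                # simulate -> screen -> benchmark
```

All inputs and outputs are plain TSV/JSON; every run writes a
`manifest.json` with a provenance block (version, config hash, seed) and
identical config + seed reruns are byte-identical.

## Notes on conventions

- Median polish sweeps rows first, tolerance 1e-8, max 100 iterations;
  missing cells stay missing and the additive reconstruction is exact.
- A pair measured in only one bait–prey orientation keeps that value
  un-doubled and is flagged `single_orientation`.
- "Majority of replicates" is strictly more than half; the single-cell
  detection threshold is ≥ 0.10 (parameterized).
- The imaging interaction score counts a heterotypic contact once and a
  homotypic contact twice, against a total of summed per-cell contacts,
  so random mixing scores ≈ 1 for every pair; the model applies the
  identical formula to its equilibrium doublet frequencies.
- Model constants (confinement length, collision rate, dissociation
  scale) are order-of-magnitude placeholders; only relative comparisons
  between cell pairs are meaningful, and equilibrium results depend on
  the collision/dissociation rates only through their ratio.
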