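# rangearc

Tools for inferring the **geographic mode of speciation** from a dated
phylogeny and species range maps, built around the accentors (Prunellidae),
a Palearctic family of mountain songbirds, as the worked study system.

Given a rooted ultrametric chronogram (ages in Ma) and one breeding-range
geometry per tip taxon, the package asks: did these lineages diverge in
allopatry, sympatry, or peripatry?  It answers with an **age–range
correlation (ARC)** analysis:

- **Node sympatry** at an internal node compares the joint (union) ranges
  of the two daughter clades: `sympatry = overlap / min(area_A, area_B)`,
  a proportion in [0, 1].
- **Range symmetry**: `min(area) / (area_A + area_B)`, bounded by 0.5.
- A **species-level variant** uses the mean and maximum of the pairwise
  overlap proportions over all cross-clade tip pairs at each node.
- Indexes are arcsine-square-root transformed (symmetry doubled first) and
  regressed on node age, both linearly
  (`y = β₀ + β₁·Age`) and with a three-parameter logistic sigmoid
  (`y = a / (1 + b·e^(−c·Age))`).

Predominantly **allopatric** speciation leaves zero sympatry at young nodes
and rising sympatry with age (positive slope, intercept ≈ 0, and typically
a sigmoidal shape from secondary contact); **sympatric** speciation
predicts the opposite trend; **peripatric** speciation predicts a positive
symmetry–age slope.

The package also reimplements the **dispersal–extinction–cladogenesis
(DEC)** model for ancestral range reconstruction: a continuous-time Markov
chain on nonempty subsets of biogeographic areas (here W/C/H/E — western,
central Palearctic, Himalayan region, eastern Palearctic) with per-area
dispersal rate *d* and local-extinction rate *e*, uniform cladogenetic
inheritance scenarios (vicariance and subset speciation), maximum-likelihood
rate estimation, and per-node ranked split reconstructions in the
`upper/lower` slash notation.

A fully seeded synthetic-data module generates Yule chronograms, range
evolution under each speciation mode, and forward DEC histories, so every
stage is testable with known truth and no external data.

## Worked example

The packaged 15-tip accentor-like fixture carries the published node ages
(root 7.31 Ma), area codings, and stylized synthetic rectangle ranges:

```bash
rangearc fixture --out results/fixture
rangearc arc --tree results/fixture/tree.nwk \
             --ranges results/fixture/ranges.geojson --out results/fixture_arc
rangearc dec --tree results/fixture/tree.nwk \
             --coding results/fixture/coding.tsv --out results/fixture_dec
```

or equivalently `python analysis/02_fixture_arc.py`, which prints:

```
node sympatry (arcsine scale): linear 0.203 + 0.233 x Age, r2=0.59, slope P=0.0014, intercept P=0.23
logistic 1.502/(1 + 12.8 e^(-1.322 Age)), r2=0.72
preferred model: logistic3
symmetry: mean 0.321 +/- 0.130 (raw), age slope P=0.62 -> no peripatric signal
```

Read: node sympatry rises significantly with node age from an intercept
indistinguishable from 0, the sigmoid fits better than the line, and
symmetry carries no age signal — the allopatric (and non-peripatric)
signature.  `python analysis/03_fixture_dec.py` then reconstructs ancestral
ranges; the root's most probable scenario involves the Himalayan region:

```
ML rates: dispersal d=0.589/Myr, extinction e=1.573/Myr, lnL=-32.90
n0: top scenario H/H (relative likelihood 0.067)
```

The numbered scripts under `analysis/` run the full study: `01` simulates
one dataset per speciation mode, `02`/`03` analyse the fixture, and `04`
runs the 20-replicate Monte-Carlo check that each mode's diagnostic is
recovered.  All outputs land under `results/`.

## Layout

- `src/rangearc/range_geometry.py` — range loading/validation, raster
  oracle, overlap/union areas
- `src/rangearc/phylo_io.py` — chronogram validation, node ages, clade table
- `src/rangearc/arc_stats.py` — indexes, transforms, linear/logistic fits,
  taxonomic lumping
- `src/rangearc/dec_model.py` — DEC state space, pruning likelihood, ML
  rates, ancestral splits
- `src/rangearc/synthetic_data.py` — Yule trees, range evolution by mode,
  DEC forward simulation, the packaged fixture
- `src/rangearc/pipeline.py`, `cli.py` — deterministic end-to-end runs and
  the `rangearc` command
- `docs/methods.md` — models, parameters, and design notes
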