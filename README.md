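# bdtt — β-diversity through time along climatic gradients

Tools for asking *at which evolutionary depth* climate structures
compositional turnover.  Given a dated (ultrametric) phylogeny, a
site × species presence/absence table, and a site table with projected
coordinates and six bioclimatic variables, the pipeline:

1. **slices** the phylogeny at a schedule of depths t (Myr): branches
   crossing age t become lineages whose distribution is the union of
   their descendant species' distributions;
2. computes, for every site pair at every depth, three turnover
   metrics — Simpson taxonomic turnover
   β_sim = min(b, c)/(a + min(b, c)), its branch-length analogue
   β_sim.phy (tip-weighted), and the mean pairwise patristic distance
   D_pw in Myr (basal-weighted);
3. relates each turnover vector to geographic distance (planar
   Euclidean, km) and climatic distance (Euclidean over z-scored
   bioclim columns) via Spearman rank correlation and a two-predictor
   variance partition: R² split into a unique geographic fraction, a
   unique climatic fraction, and the spatially structured climatic
   fraction shared by both (total climate effect = unique climate +
   shared = R² of climate alone).

A synthetic-data module generates Yule trees, Brownian niche optima
(with a Pagel-style conservatism dial), linear transects with six
correlated climate columns, and Gaussian-filtered occupancies — with an
optional scenario biasing the two basal clades toward opposite transect
ends — so the whole pipeline is testable without any occurrence data.

Audience: ecologists and biogeographers working with phylogenetic
β-diversity who want depth-resolved climate/geography attribution, and
anyone needing a seeded community-assembly simulator with controllable
niche conservatism and deep-pool structure.

## Worked example

```python
import bdtt

tree, occ, sites, cfg = bdtt.make_scenario("latitudinal-like", seed=42)
table = bdtt.bdtt_sweep(tree, occ, sites)   # 6 slices x 3 metrics
row0 = table.set_index(["slice_time", "metric"])
for t in (0.0, 75.0):
    r = row0.loc[(t, "sim_tax")]
    print(f"t={t:>4} Myr  r_s(clim)={r.r_s_clim:.3f}  "
          f"climate R2={r.total_climate_effect:.3f}  unique geo={r.unique_geo:.3f}")
```

prints

```
t= 0.0 Myr  r_s(clim)=0.935  climate R2=0.777  unique geo=0.002
t=75.0 Myr  r_s(clim)=0.782  climate R2=0.703  unique geo=0.002
```

i.e., for this simulated single-pool gradient the rank correlation of
taxonomic turnover with climatic distance is strong at the species
level and weakens at the 75-Myr slice, climate (directly plus through
its spatial structure) explains less turnover variance at depth, and
geography adds almost nothing beyond climate — the signature of
environmental filtering on conserved niches from a single species pool.

The same run from the shell:

```bash
bdtt simulate --preset latitudinal-like --seed 42 --out-dir fixtures/
bdtt run --tree fixtures/tree.nwk --occ fixtures/occ.csv --sites fixtures/sites.csv \
         --slices 0,15,30,45,60,75 --out results.tsv
```

## Analysis scripts

`analysis/` holds the numbered drivers that produced the tables under
`results/`: `01_simulate_scenarios.py` (write both scenario bundles),
`02_bdtt_sweep.py` (six-depth sweep per scenario),
`03_fine_dpw_sweep.py` (1-Myr D_pw close-up, 0–15 Myr), and
`04_trend_replicates.py` (the two qualitative contrasts over ten seeded
gradients).  Each is a thin wrapper over the library; run them in order
from the repository root.

`docs/methods.md` documents the model, the slicing tie rule, all
defaults and units, and what the generator does and does not emulate.

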