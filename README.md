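# haptonet

Diversity, environmental-driver and co-occurrence network analysis of
pico-haptophyte amplicon count tables.

Marine haptophytes — a lineage of mostly pico/nano-sized algae such as
*Phaeocystis* and *Chrysochromulina* — are profiled in sea-water surveys by
sequencing a haptophyte-specific 18S rRNA marker and denoising the reads
into ZOTUs (zero-radius operational taxonomic units). A typical polar study
samples paired depth layers (surface water and the subsurface chlorophyll
maximum, SCM) at a transect of stations and asks three questions:

1. **Diversity** — how do richness, Shannon entropy and Faith's
   phylogenetic diversity differ between layers, and which environmental
   covariates do they track?
2. **Drivers** — which covariate best explains community dissimilarity?
   (ANOSIM on habitat groups; Mantel tests of the Bray–Curtis matrix
   against per-variable distances; a multiple regression of the unfolded
   dissimilarities with an LMG decomposition allocating R² to predictors.)
3. **Co-occurrence structure and stability** — after filtering rare,
   sparse ZOTUs, which pairs co-vary (Spearman ρ ≥ 0.6 with
   Benjamini–Hochberg *q* < 0.01)? Which ZOTUs are habitat-enriched, what
   modules does Louvain find, and how quickly does each habitat's
   subnetwork lose *natural connectivity*
   λ̄ = ln[(1/N) Σᵢ e^{λᵢ}] (λᵢ the adjacency eigenvalues) as nodes are
   removed by degree, betweenness, or at random?

`haptonet` implements this whole post-denoising workflow as a tested
library plus a thin CLI, together with a synthetic-data generator that
plants all of the structure the analysis is meant to detect (habitat
contrast, a temperature gradient, correlated ZOTU blocks), so every stage
can be validated end to end without any sequencing download.

## Worked example

```python
from haptonet import RunConfig, SyntheticDesign, run_pipeline

config = RunConfig(seed=1, design=SyntheticDesign.paper_like(seed=1))
bundle = run_pipeline(config, out_dir="demo_run")

print(bundle["anosim"]["bray_curtis"])
print(bundle["mantel"].sort_values("r_squared", ascending=False).head(3))
print(bundle["patterns"])
```

prints (seed 1):

```
{'R': 0.3134110787172012, 'p_value': 0.001, 'n_permutations': 999}
      variable         r  r_squared      p
1  temperature  0.496305   0.246318  0.001
0        depth  0.411637   0.169445  0.001
3          PO4  0.392827   0.154313  0.001
{'surface_alpha_higher': True, 'habitat_anosim_significant': True,
 'surface_subnetwork_denser': True, 'surface_network_more_robust': True}
```

The ANOSIM R of 0.31 (p = 0.001) says the surface and SCM communities are
compositionally distinct; the Mantel table ranks temperature as the
strongest single driver of Bray–Curtis dissimilarity (r² = 0.25); and the
four pattern flags confirm that the planted study-level contrasts — higher
surface alpha diversity, significant habitat separation, a denser and more
attack-robust surface subnetwork — are all recovered by the pipeline.
`demo_run/` holds every intermediate artifact (rarefied table, distance
matrices, PCoA coordinates, Mantel/LMG tables, GraphML + GML networks,
attack curves, manifest with per-stage seeds).

The same stages are available from the shell:

```bash
haptonet simulate --out sim --seed 1
haptonet alpha  --table sim/zotu_table.tsv --tree sim/tree.nwk \
                --metadata sim/metadata.tsv --depth min --seed 1 --out alpha
haptonet beta   --table sim/zotu_table.tsv --metadata sim/metadata.tsv \
                --metric braycurtis --perms 999 --seed 1 --out beta
haptonet network --table sim/zotu_table.tsv --metadata sim/metadata.tsv \
                --rho 0.6 --alpha 0.01 --out net
haptonet attack --graph net/network.graphml --strategy random --reps 100 \
                --seed 1 --out curve.tsv
```

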