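# ethnophylo

Phylogenetic clustering analysis of ethnomedicinal therapeutic efficacy.

Ethnobotanical compilations record, for each medicinal plant species, which
kinds of ailment it is used to treat. If closely related species tend to
share therapeutic uses — because they share the secondary metabolites that
make them work — then the species treating one disease category should sit
closer together on the phylogeny than a random draw of species would. That
clustering is detectable, and it matters for bioprospecting: a clade
enriched for, say, eye-disease remedies is a rational place to look for new
ones.

`ethnophylo` implements that analysis for binary species × disease-category
data placed on a species-level phylogeny, for ethnobotanists and
phylogeneticists who want the whole pipeline — name matching, tree pruning,
permutation tests, per-clade summaries, iTOL export — as tested, scriptable
Python.

## The statistic

Each disease category defines a *community*: the set of species recorded as
treating it. Two distance summaries are computed from patristic (branch
length) distances among the community's `k` members:

- **MPD**, mean pairwise distance over all `k(k−1)/2` pairs — signal near
  the root of the tree;
- **MNTD**, mean distance of each member to its nearest other member —
  signal near the tips.

Each is standardized against a *taxa-label null*: the tip labels of the
pool's distance matrix are shuffled (equivalently, `k` tips are redrawn
uniformly without replacement), 999 times by default. The indices are the
sign-flipped z-scores

```
NRI = −(MPD_obs − mean MPD_null) / sd MPD_null
NTI = −(MNTD_obs − mean MNTD_null) / sd MNTD_null
```

so **positive values mean phylogenetic clustering** and negative values
overdispersion. The one-tailed p-value is the midrank of the observed value
among {observed} ∪ null, divided by (runs + 1); with 999 runs the smallest
attainable p is 0.001.

## Worked example

Simulate a 200-tip species pool with two planted clustered categories, fit
the model, and print the summary table:

```python
import ethnophylo as ep

cfg = ep.SimConfig(n_tips=200, seed=7,
                   modes=("clustered",) * 2 + ("null",) * 13)
tree, matrix, truth = ep.generate_study(cfg)
model = ep.PhylogeneticDispersionModel(
    tree, matrix, scope=ep.AnalysisScope(pool_policy="medicinal_only"))
res = model.fit(runs=999, seed=1)
print(res.summary())
```

```
Phylogenetic dispersion of therapeutic efficacy [scope: order]
pool = 73 tips, 73 medicinal species, runs = 999, seed = 1, pool policy = medicinal_only

Disease category                     NRI        p       NTI        p     N
Poisoning/intoxication          10.5190*   0.001*   3.0385*   0.002*    14
Circulatory disease              2.9568*   0.020*   2.4272*   0.011*    11
Gastrointestinal disease        -0.3764    0.618   -0.8801    0.806     45
Nervous system disease           0.0435    0.381    1.4514    0.083     10
Eye disease                      1.7569    0.060    1.2538    0.108     15
Other/general disease            1.8777*   0.040*  -0.4960    0.672     58
Hepatobiliary disease            0.2801    0.331    0.5038    0.284     24
Musculoskeletal disease         -0.8354    0.784    0.1103    0.460     52
Oral disease                     0.8786    0.162    0.3263    0.358     17
Ear/nose/throat disease         -1.2281    0.941   -0.9262    0.818     24
Pediatric disease               -0.1681    0.461    0.2340    0.399     10
Reproductive system disease      0.3809    0.286    1.6894    0.050     19
Respiratory disease             -0.6690    0.742    0.8365    0.192     32
Skin disease                    -0.0900    0.501    0.5574    0.279     46
Urinary disease                  1.3042    0.104    1.1772    0.130     16

* p < 0.05 (one-tailed, lower = clustered)
```

The two planted categories (poisoning/intoxication and circulatory) are
recovered with strongly positive, significant NRI and NTI. One of the 13
truly-null categories (other/general) is flagged at p = 0.040 — with 13
tests at the 5% level, about one false positive per table is exactly what a
calibrated test should produce. The `N` column is each category's community
size among the 73 medicinal species.

From the shell, the same pipeline is:

```sh
ethnophylo simulate --config sim.json --out study/
ethnophylo run --tree study/tree.nwk --matrix study/efficacy.csv \
               --runs 999 --seed 20220112 --pool all-tree-tips --out tables/
ethnophylo itol --tree study/tree.nwk --matrix study/efficacy.csv --out itol/
```

`run` writes one CSV summary per scope (the whole tree, then each family),
a multipurpose-species table (species treating ≥ 10 categories), a JSON
manifest with seeds and input digests, and a log. `itol` writes
`DATASET_BINARY` (15 presence rings, inner → outer in canonical category
order) and `TREE_COLORS` (one colored range per family clade) annotation
files for [iTOL](https://itol.embl.de/).

## Analysing real data

`read_efficacy_table` ingests a delimited table with a `species` column, an
optional `family` column, and one 0/1 column per category (the 15 canonical
organ-system categories are bundled; see
`src/ethnophylo/data/categories.json`). Species names are reconciled with
tree tips by `match_taxa` — authority strings stripped, spaces/underscores
unified, infraspecific taxa optionally collapsed onto their parent binomial
— and every run reports exactly which species matched.

Two analyses in the test suite run only when their external inputs are
placed under `data/` (neither file is redistributable here):

- `data/species_efficacy.csv` — a compiled species × 15-category table of
  Chinese Ranunculales ethnomedicine (551 species across five families);
- `data/full_tree_461.tre` — the species-level phylogeny of Chinese
  angiosperms (26,978 tips, darwintree.cn), from which the Ranunculales
  subtree is pruned.

With those present, the suite also checks the published headline numbers
(per-category species counts, multipurpose species, order-level NRI/NTI).

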