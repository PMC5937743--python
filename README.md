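# metacore

Hierarchical analysis of metabolic networks by k-core percolation.

Plant metabolism — and metabolism generally — is organized in layers: a
small set of ubiquitously reused currency metabolites (ATP, H2O, NAD+,
coenzyme A, ...) anchors a shared primary framework, while specialized
secondary pathways sit at the periphery and differ between species.
`metacore` makes that hierarchy measurable. It builds an undirected
**substrate-product network** from a plain-text reaction set (every
substrate of a reaction is linked to every product, duplicates and
self-pairs dismissed), peels the network with the **k-core
decomposition**, and quantifies how metabolite groups distribute over the
resulting layers.

For a graph G with adjacency matrix A (a_ij = 1 iff metabolites i and j
co-occur across a reaction arrow), the k-core is the maximal subgraph of
minimum degree ≥ k, obtained by recursively deleting nodes of degree < k.
A node's shell index is the largest k for which it remains; the k-shells
G_k partition the node set, cores are nested, and the non-empty core at
the largest k = k_max is the network's central core. On top of the
decomposition the package computes:

- **layer profiles** — for each k, the size of the (cumulative) k-core
  and the fraction of it occupied by a target metabolite set (common
  metabolites across species, curated secondary lists, ...);
- **cross-species core composition** — a presence/absence matrix of the
  species' maximum cores and their intersection;
- **reaction coverage** — the fraction of reactions containing at least
  one metabolite of an anchor set (typically the maximum core);
- **class cross-connection** — link counts between metabolic classes
  (lipids, carbohydrates, nucleotides, amino acids, ...) with
  maximum-core members reassigned to a dedicated core class, diagonal +
  upper triangle summing exactly to the edge count.

A seeded synthetic-data generator plants this structure (shared currency
pool, shared primary chains, species-specific secondary chains) so the
whole pipeline is testable end to end with known ground truth.

Intended users: systems biologists and network scientists analyzing
genome-scale reaction sets (e.g. BioCyc-family exports converted to the
package's plain reaction format, or prebuilt networks in GML).

## Worked example

Generate a three-species synthetic reaction set and run the analysis:

```python
from metacore import (SyntheticConfig, generate, build_network, decompose,
                      max_core, layer_profile, common_metabolites,
                      reaction_coverage)

truth = generate(SyntheticConfig(seed=7))
nets = {sp: build_network(r, sp) for sp, r in truth.reactions.items()}
common = common_metabolites(list(nets.values()))
for sp, G in nets.items():
    d = decompose(G)
    cov = reaction_coverage(truth.reactions[sp], max_core(d))
    prof = layer_profile(d, common, "common")
    print(f"{sp}: N={G.number_of_nodes()} E={G.number_of_edges()} "
          f"k_max={d.k_max} |max core|={len(max_core(d))} "
          f"coverage={cov.fraction:.3f} common@kmax={prof.fraction_at(d.k_max):.2f}")
```

prints

```
species0: N=128 E=472 k_max=6 |max core|=10 coverage=0.836 common@kmax=1.00
species1: N=128 E=468 k_max=6 |max core|=10 coverage=0.800 common@kmax=1.00
species2: N=128 E=470 k_max=6 |max core|=10 coverage=0.818 common@kmax=1.00
```

Each species' network of 128 metabolites percolates down to a 10-node
maximum core at k_max = 6 — exactly the planted currency pool — and over
80% of each species' reactions touch that core. The per-layer profile of
the common (all-species intersection) set shows the centralization
pattern: the common fraction rises monotonically from 0.77 in the
outermost layer to 1.00 at the central core, while species-specific
secondary metabolites never reach the inner layers:

```
 k  core_size  shell_size  target_in_core  fraction
 1        128          10              98  0.765625
 2        118          20              98  0.830508
 3         98          16              98  1.000000
 4         82           0              82  1.000000
 5         82          72              82  1.000000
 6         10          10              10  1.000000
```

The same analysis is available from the shell:

```sh
metacore simulate -o fixture --seed 7
metacore report -d fixture -o results
```

which writes GML networks, per-layer metabolite TSVs, layer-profile
tables, the maximum-core presence matrix, and the reaction-coverage
table under `results/`. Individual verbs (`build`, `decompose`,
`layers`, `coverage`, `crossconn`) run each stage separately; options
can be preloaded from a YAML file via `--config`.

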