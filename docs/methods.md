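# Methods

## The substrate-product network model

A reaction set is reduced to an undirected simple graph on metabolites.
For each reaction, every substrate is linked to every product (never
substrate to co-substrate or product to co-product); the same metabolite
appearing on both sides contributes no self-loop; stoichiometric
coefficients are stripped, and repeated metabolites or edges are
dismissed. Reaction direction is discarded entirely — an undirected edge
carries the only information the model uses, namely that two metabolites
stand across a reaction arrow from one another — so reversible and
irreversible reactions contribute identically. The `<-` arrow in the
input grammar is normalized by swapping sides at parse time; nothing
downstream depends on it.

Metabolite identity is exact string match after whitespace normalization
(trim, collapse internal runs), case-sensitive by default: curated
compound vocabularies distinguish chemically distinct species that
differ only in case or punctuation, so case-folding is a deliberate
opt-in (`case_fold=True`) rather than a default. The ` + ` (space, plus,
space) side separator keeps names with internal plus signs — `NAD+`,
`H+` — unambiguous. Every token on a reaction line is treated as a
metabolite; filtering of generic/polymer placeholder names is left to
the user's input preparation, since no principled in-package rule could
distinguish them.

## k-core decomposition

The k-core is the maximal subgraph of minimum internal degree ≥ k; the
shell index of a node is the largest k whose core contains it, and
k_max is the deepest non-empty level. The implementation is the
linear-time bin-peeling scheme of Batagelj and Zaversnik: nodes are bin
sorted by degree, the current minimum-degree node is peeled, and its
remaining neighbours' degrees are decremented in place. Ties are peeled
in arbitrary order; shell indices are provably order-independent and the
tests assert this by shuffling node insertion order. Two independent
routes check the implementation: a naive fixpoint oracle (repeatedly
delete all nodes of degree < k) kept in the package for testing only,
and `networkx.core_number` as a third-party cross-check in the test
suite.

Conventions: isolated nodes get shell 0 and are excluded from the
1-core (layer counting starts at k = 1); an empty graph is a degenerate
input and raises; self-loops are rejected rather than silently counted,
since the model cannot produce them and their degree contribution is
ambiguous.

"Layer k" throughout the analysis code means the **cumulative** k-core,
not the exclusive k-shell: layer statistics such as per-layer target
fractions are computed against the full content of each core, with the
exclusive shells exposed separately (`shell(decomp, k)`). This is the
reading under which the outermost layer of a network equals its whole
connected content and the innermost layer is the maximum core.

## Layer statistics

A layer profile reports, for k = 1..k_max, the core size, exclusive
shell size, the number of target-set members inside the core, and their
fraction of it. Target sets may contain names absent from the network —
curated lists routinely do — and absentees simply count as outside every
core; their tally is reported (`n_absent`) and logged. Common
metabolites are the intersection of all species' node sets; non-common
metabolites are a species' complement of that intersection, so common
and non-common fractions sum to exactly 1 at every layer. The
cross-species presence matrix rows are sorted lexicographically (by
string) for deterministic output.

Reaction coverage counts reactions whose substrate∪product set
intersects an anchor set. It is order-invariant and duplication-
invariant by construction; an empty reaction list is an error rather
than a 0/0.

## Class cross-connection

Classes are user-supplied metabolite lists. Assignment applies maximum-
core precedence: any node of the maximum core is classed `max_core`
regardless of list membership, remaining nodes take their base class,
nodes on several base lists take the first-listed class (logged), and
unlisted nodes become `unclassified`. The two reserved labels may not be
used by base lists. Each undirected edge then increments exactly one
unordered class-pair cell; within-class edges land on the diagonal once
and off-diagonal cells are mirrored so rows read as per-class
connection profiles. Diagonal plus upper triangle equals the edge count
exactly — an invariant the tests enforce on every network they touch.
First-listed-wins overlap resolution is a documented choice; class
lists with genuine overlaps (e.g. nucleotide sugars) should be ordered
by the precedence the analyst intends.

## Synthetic data generator

The generator plants the structure the analysis is meant to detect, so
recovery is a ground-truth test of the whole pipeline:

1. a pool of `n_currency` currency metabolites shared by all species;
2. shared primary pathways: linear chains of `primary_len` reactions
   M_i → M_{i+1}, each side augmented with `currency_per_reaction`
   currency metabolites drawn from a rotating window over the pool;
3. per species, `n_secondary_pathways_per_species` secondary pathways:
   linear chains of `secondary_len` reactions hanging off one randomly
   chosen primary metabolite, each reaction carrying one random currency
   metabolite with probability `secondary_currency_prob`.

Defaults (three species, 10 currency metabolites, 8 primary pathways of
length 10, 6 secondary pathways of length 5 per species, 2 currency
metabolites per reaction side, secondary currency probability 0.3, seed
0) are the study conditions used by the test suite and the acceptance
script: large enough that each species' network has ~130 nodes and a
clear three-tier hierarchy, small enough that a full multi-seed sweep
runs in seconds.

The currency window advances **one position per reaction** (substrate
side takes cyclic positions r..r+c−1, product side r+c..r+2c−1, with
c = `currency_per_reaction`). Over enough primary reactions this links
every currency pair at cyclic offset 1..2c−1, i.e. a circulant graph of
degree 4c−2 within the pool. That floor is the load-bearing choice: a
primary chain interior node has degree 2c+2, and peeling erodes chains
from their endpoints down to shell 2c+1, so for c ≥ 2 the currency pool
(internal degree 4c−2 ≥ 2c+2) strictly outlasts every chain and the
maximum core equals the planted pool exactly, at k_max = 4c−2 = 6 under
the defaults. A window that advanced by its own width instead would
leave the pool a sparser circulant (degree 2c) and let primary
interiors into the maximum core. Uniform random attachment gives the
same expectation but no floor, and fails at these small sizes.

Secondary chains are trees (shell ≤ 2 regardless of currency
attachment), which matches the peripheral placement of specialized
metabolism the model is meant to emulate. One `random.Random(seed)`
instance drives all random choices (secondary anchors and currency
attachment); generation is byte-reproducible per seed.

What the generator does **not** emulate: realistic degree
distributions, reaction sizes beyond binary-plus-currency, shared
secondary pathways between subsets of species, annotation noise, or
missing reactions. Passing recovery tests therefore demonstrates that
the pipeline measures what it claims on a network whose ground truth is
known — not that any particular biological dataset will show a 10-node
core. On real reaction sets the qualitative pattern (currency hubs in
the maximum core, secondary lists vanishing from inner layers) is the
expected signature, with sizes and depths set by the data.

With `secondary_currency_prob` at its default 0.3, a species' secondary
class touches the core through Binomial(n_sec·len, 0.3) attachments,
which can drop below the 6 deterministic secondary-primary anchor
links; the cross-connection "every class connects most heavily to the
core" pattern is therefore structural only when secondary reactions
carry currency deterministically (probability 1.0), and the test suite
asserts it under that condition.

## Pipeline and outputs

The CLI verbs (`simulate`, `build`, `decompose`, `layers`, `coverage`,
`crossconn`, `report`) are thin orchestrations over the library. All
outputs are TSV (with a `#` header line naming the producing command and
parameters) or GML; reruns with identical inputs and seed are
byte-identical. Commands write only under the chosen output directory
and exit non-zero on any error.

## Acceptance measurements

`scripts/acceptance.py --seed S --out F` regenerates everything from
scratch at seed S: 200 seeded Erdős–Rényi graphs (n ≤ 60, edge
probabilities 0.05–0.5) for the oracle-agreement rate, 20 independent
three-species fixtures (60 species-networks) for recovery, separation
and the layer fractions at k_max, a primary-only fixture for reaction
coverage by the recovered core, and the default fixture for the
cross-connection edge-conservation residual and shared-core size. These
problem sizes keep the full run under ten seconds while giving every
rate a denominator of 60–240.

## Known limitations

- The package analyzes plain-text reaction exports and GML networks; it
  does not parse BioCyc attribute-value flat files or query web
  databases.
- Secondary/class metabolite lists are consumed as curated inputs; no
  chemical classification is performed.
- Layer-distribution differences are reported as proportions; no
  statistical testing is attached to them.
- The generator's guarantees are asymptotic in the number of primary
  reactions (the rotating window must wrap the pool at least once:
  n_primary_pathways · primary_len ≥ n_currency).
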