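# Methods

`cigmine` analyses a *population* of modelled diploid 3D genome structures —
one coordinate set per cell-like state, each domain represented as a sphere —
and asks which groups of chromatin domains co-localize recurrently across that
population, what regulatory signals they carry, and how the population
decomposes into structural substates. This note records the models,
assumptions, numerical choices and limitations behind each stage.

## Graph representation of a structure

Each structure of N domains (2N diploid spheres) becomes a chromatin
interaction graph (CIG): nodes are labelled L1–L2–L3 (chromosome index,
domain index within the chromosome, homolog copy A/B), and an edge joins two
nodes whose spheres touch. The contact rule is geometric:

    contact(i, j)  ⇔  ‖p_i − p_j‖ ≤ s · (r_i + r_j)

with contact scale `s = 1.0` by default — touching or overlapping spheres are
in contact, the natural notion for a sphere-packing model. `s` is exposed
because modelling pipelines differ in how generously they call contacts;
everything downstream is monotone in `s`.

Copy labels A/B are arbitrary *per chromosome per structure*: nothing in a
structure population distinguishes "the first" homolog of, say, chromosome 7
between two structures. All downstream code treats per-chromosome A↔B swaps
as the identity; tests enforce this invariance end to end.

## Twin contraction

Mining directly on diploid graphs would require subgraph isomorphism modulo
the copy symmetry ("coupled isomorphism"). Instead, the two copies of each
domain are merged first: the contracted graph (cCIG) has N nodes and an edge
{u, v} iff *any* copy pair of u and v touches. Merging can only add induced
edges, so for every domain subset the contracted induced density is at least
the best density over copy assignments in the diploid graph — a dense pattern
can never be lost by contraction, only over-counted. The over-count is
corrected later by re-examining original CIGs, so contraction is a lossless
search-space reduction for the final counts. Twin–twin edges (homolog
self-contacts) are dropped: a merged pattern never contains one domain twice.

## Frequent dense subgraph mining

A frequent spatial cluster is a set of ≥ `min_size` domains whose induced
cCIG density is ≥ `min_density` in at least a `min_freq` fraction of
structures (defaults 4, 0.6, 1%). The search is a tensor-style relaxation:

    maximize  H(x, y) = Σ_k y_k · (xᵀ A⁽ᵏ⁾ x) / 2
    s.t.      ‖x‖_p = 1, ‖y‖_q = 1, x ≥ 0, y ≥ 0

where x weights nodes and y weights graphs. Block updates: given x, the
y-update `y ∝ g^{1/(q−1)}` with `g_k = xᵀA⁽ᵏ⁾x/2` is the exact Hölder
maximizer; the x-update is the L_p power step `x ∝ (Σ_k y_k A⁽ᵏ⁾x)^{1/(p−1)}`.
Defaults p = 1.5 and q = 1.25: both exponents are sparsity-inducing, and the
sharp graph norm is load-bearing — it concentrates y on the structures that
actually support the current node set, so a pattern recurring in a few
percent of structures is not drowned out by contact structure shared across
the whole population (with q = 2, the y-weights stay spread over all K
graphs and the iterations drift to globally ubiquitous contacts, in
chain-like genomes the consecutive-domain backbone). H is evaluated after
every step; a step that would decrease H is rejected and terminates the run,
so accepted iterations are monotone non-decreasing. Convergence: relative
change of H below `tol = 1e-6` or `max_iter = 500`.

**Restart seeding.** Each restart draws one remaining contact pair,
preferring the *unexplained frontier* — pairs not yet inside any accepted
pattern, weighted by their remaining occurrence count (every tenth restart
draws unrestricted, keeping generic exploration alive). The pair is then
grown greedily inside the graphs holding its edge: repeatedly add the node
that keeps the induced density ≥ `min_density` in the most holder graphs
(ties prefer the candidate contributing more edges within supporting graphs,
then the lowest index), while that count stays above the frequency
threshold. Pairs that cannot grow to `min_size` — scattered background
contacts — are cheap failures that skip the optimization entirely. The grown
set seeds x, its supporting graphs seed y, and the multiplicative updates
refine from there. Plain i.i.d. starts converge to the globally dominant
contact structure and systematically miss low-frequency patterns. Restart
RNG streams are counter-based from the single mining seed, so reruns are
bit-identical. The stop rule is patience: mining ends after `restarts`
(default 1000) consecutive restarts without a new qualifying pattern —
growth-rejected seeds cost microseconds, so a long patience is affordable
and is what makes ~1%-frequency patterns reliably reachable.

**Discretization.** The continuous solution is rounded by scanning nested
top-m node sets for m = `min_size` … m_max and keeping the largest m whose
exact support fraction (graphs at density ≥ `min_density`) reaches
`min_freq`. m_max is the *weight support* of x — nodes holding at least 10%
of the maximum weight — capped at 20 (the downstream 2^|D| enumeration
guard). The support bound matters: multiplicative updates decay weights
geometrically off the dense core, and without the bound the largest-m rule
happily appends one spurious node to an exact pattern (any superset of a
dense clique can stay above threshold), which distorts the pattern's
occurrence statistics. Ties in x break by ascending node index.

**Pattern-set extraction.** Accepted patterns are re-verified against the
exact thresholds on the *unmasked* graphs, de-duplicated by domain set, and
their induced edges removed from their supporting graphs only — patterns
overlapping in membership but occurring in other structures remain
discoverable. Mining stops after `restarts` consecutive failed restarts.
An exhaustive oracle (`brute_force_mine`, guarded to N ≤ 15) enumerates all
maximal qualifying subsets and anchors the correctness tests.

## Coupled-isomorphism counting

Each mined domain set D is restored to the diploid CIGs: all 2^|D| copy
assignments are enumerated per structure (guard: |D| ≤ 20), assignments at
density ≥ `min_density` are kept, and each is collapsed to a canonical *copy
signature* — per chromosome, the unordered bipartition of D's members into
same-copy groups, invariant under A↔B swaps, with no cross-chromosome copy
correspondence encoded (none is identifiable). Each (D, signature) variant
gets a per-structure occurrence vector (a variant occurs if ≥ 1 assignment
with that signature qualifies), and the frequency threshold applies per
variant: the isomorphism class is the countable unit. Frequencies computed
here, on the original CIGs, are the authoritative ones; cCIG support is only
a search heuristic.

## Regulatory-community enrichment

For each cluster × factor, the statistic is the arithmetic mean of the
members' signal; the null re-draws |members| domains uniformly without
replacement from all domains, B = 10,000 times by default (tests use smaller
B; p-values are add-one corrected: p = (1 + #{null ≥ obs}) / (B + 1),
one-sided for enrichment). A constant signal column yields p = 1 by
convention. q-values are Benjamini–Hochberg across the full table; enriched
means q < α (default 0.05); a cluster is a regulatory community iff enriched
for ≥ 1 factor, labelled through a configurable factor → label map
(multi-label allowed). One RNG stream per (cluster, factor) derives from the
global seed, so any evaluation order reproduces identical p-values. The null
pool is deliberately unstratified (simplest defensible null); a
chromosome-stratified alternative would be the first thing to add when
factor signals correlate strongly with chromosome identity.

The permutation p-values are invariant to adding a constant to a factor's
signal, but *not* to monotone transforms (the statistic is an arithmetic
mean, not a rank statistic).

## Spatial statistics

* **Centromeric influence**: proportion of members annotated centromeric;
  ≤ 0.30 is *weak*, above is *strong* (the boundary itself is weak).
* **Radial position** of a cluster: mean over its occurrence structures of
  the mean member-node distance from the nuclear centre, in nuclear-radius
  units, using the copy assignment that realizes the cluster's signature in
  that structure.
* **Centromere distances**: per cluster, the mean pairwise distance between
  the involved chromosomes' centromere reference domains (the
  centromeric-category domain nearest the centromere midpoint), averaged
  over occurrence structures; copy ambiguity resolves to the per-chromosome
  copy choice minimizing the summed pairwise distance (exhaustive over 2^c).
  The random control re-evaluates the same quantity on equally many
  structures sampled from those where the cluster does not occur.
* **Rank tests**: two-sided Mann–Whitney, exact for tie-free samples of
  ≤ 20, tie-corrected normal approximation otherwise.
* **Partial correlation**: first-order formula with the t-test on n − 3 df;
  collinear controls are rejected explicitly.
* **Factor grouping**: binary factor × cluster enrichment profiles, Jaccard
  distances, average-linkage hierarchical clustering cut to `n_groups`
  (default 4); never-enriched factors carry no profile and land in residual
  group 0.
* **Occurrence–distance trend**: per-domain counts over (by default
  inter-chromosomal) clusters, binned into 6 equal-count groups of linear
  distance to the chromosome's centromere midpoint, reported as mean ± sd.

## Substates

Inter-chromosomal clusters' occurrence vectors form a binary M × K matrix;
rows with frequency ≥ 10% are removed first (prevalent clusters carry no
partitioning signal; the boundary is dropped). The matrix is factorized as
C ≈ WH by Frobenius multiplicative updates (Lee–Seung), `k = 8` substates by
default with no automatic rank selection; structure j joins argmax_h H[h, j],
cluster i joins argmax_h W[i, h], ties to the lowest index. The objective is
tracked every iteration and is non-increasing by construction of the updates;
the best of 10 restarts by final objective is kept. Factors are initialized
uniformly at random scaled to the matrix mean; a small ε = 1e−12 guards the
update denominators. Per-substate summaries report the top 20% of
inter-chromosomal pair contact frequencies and radial-position comparisons,
where "the" radial position of a domain in a structure is the minimum of its
two homolog distances (copies are unordered; the interior one represents the
domain for centromere-location questions).

## Synthetic populations

The generator emulates the statistical structure the analyses consume, not
chromatin physics. Chromosomes are confined random chains: successive domain
spheres touch (centre spacing = sum of radii) along uniform random
directions, reflected radially at the unit-sphere envelope; homolog copies
are independent; default geometry is 3 chromosomes × 20 domains of radius
0.03 in nuclear-radius units, K = 500 structures. Planted clusters switch on
i.i.d. per structure at their target frequency; in "on" structures the
members (on copies realizing the configured signature, with a random
per-chromosome orientation flip so A/B stays meaningless) are repositioned
around a random interior point. Each member is *attached* with probability
√p_contact: attached members land in a mutually-touching ball (radius capped
by both the co-localization radius ε and half the smallest pair radius sum),
detached members are displaced beyond contact range — so each member pair is
in contact with probability exactly p_contact and the expected induced
density is ≈ p_contact. An exact independent per-pair Bernoulli is
geometrically unrealizable; this construction keeps the marginal per-pair
probability and is audited post-generation. Substate scenarios split
structures deterministically at the configured fractions (exact counts, not
multinomial — stable fixtures) and drive each substate's planted clusters at
their frequency inside and a background rate (default 2%) outside.

Signals are i.i.d. log-normal(μ = 0, σ = 1) per (domain, factor) — a
heavy-tailed but plain background; enrichment multiplies the members of a
designated cluster by δ on designated factors, and δ = 1 is an exact null.

What the generator does *not* emulate: excluded volume between non-planted
domains, territory formation, distance-decay contact probabilities within
chromosomes beyond chain adjacency, correlated factor signals, or any
coupling between homolog copies. Consequently, passing tests demonstrate
algorithmic correctness (recovery of planted structure under controlled
noise), not biological fidelity of any particular dataset. One deliberate
consequence of the chain packing rule: genomically adjacent domains are
*always* in contact, so unplanted populations still contain recurring
intra-chromosomal chain windows; null-run tests therefore assert the absence
of inter-chromosomal patterns rather than an empty result.

A note on detection power: with the arithmetic-mean statistic, the
all-domain null pool and σ_log = 1 backgrounds, an 8× shift on a 5-member
cluster is detected at p ≤ 0.005 in roughly 85–90% of replicates — the
log-normal mean's heavy right tail occasionally produces null draws beating
an observed mean whose members drew small backgrounds. Detection at p ≤ 0.05
is near-certain, and tighter backgrounds (σ_log ≤ 0.75) push p ≤ 0.005
detection above 99%. The acceptance script reports the measured rate.

## Determinism

Every stochastic stage consumes an explicit integer seed; the pipeline fans
one global seed into fixed per-stage streams (recorded in the manifest), and
restart-level streams are counter-based. Outputs are byte-reproducible:
rerunning a config + seed reproduces cluster JSON and manifest exactly.

## Problem sizes

Default validation sizes were chosen to exercise every guarantee at
comfortable margins: 200 random 8-domain graphs for contraction, 50 planted
instances (10 nodes × 8 graphs) against the exhaustive oracle, full
enumeration on 8 domains × 8 structures for counting equivalence, a
500-structure population for end-to-end recovery, 1,000 simulated clusters
for calibration, n = 10,000 for partial-correlation recovery and a
300-structure scenario for substate recovery.

## Known limitations

* The miner is stochastic: recall guarantees are empirical (validated against
  the exhaustive oracle on small instances and planted populations), not
  worst-case.
* Patterns are limited to ≤ 20 domains by the 2^|D| signature enumeration;
  larger candidates are rejected explicitly rather than silently truncated.
* Copy signatures encode no cross-chromosome copy correspondence, because
  none is identifiable from a single structure's labels.
* The NMF rank k is a user choice; no model-order selection is attempted.
* Structure files are streamed per structure, but the in-memory population
  and graph stacks scale as K·N² — populations of 10⁴ structures at a few
  hundred domains fit in a few GB, but finer resolutions would need a
  sparse-graph backend.
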