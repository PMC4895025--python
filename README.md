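# cigmine

Mining recurrent spatial chromatin clusters from diploid 3D genome structure
populations.

Modelled genome structure populations — thousands of plausible 3D
conformations of one genome, each domain a sphere, two homolog copies per
domain — vary enormously from structure to structure. `cigmine` is for
computational genomicists who want to extract what *recurs*: sets of
chromatin domains that co-localize in a meaningful fraction of structures,
the regulatory signals those clusters carry, the role of centromere
clustering and transcription-factor binding in stabilizing them, and the
decomposition of the population into structural substates.

## Method

Each structure becomes a **chromatin interaction graph** (CIG): 2N nodes
labelled L1–L2–L3 (chromosome, domain index, homolog copy A/B), edges where
spheres touch (‖p_i − p_j‖ ≤ s·(r_i + r_j), s = 1 by default). Homolog
twins are merged into a contracted graph (cCIG) whose edges OR over copy
pairs — merging can only raise induced density, so no frequent dense pattern
is lost. Mining maximizes the tensor objective

    H(x, y) = Σ_k y_k · (xᵀ A⁽ᵏ⁾ x) / 2,   ‖x‖_p = 1, ‖y‖_q = 1, x, y ≥ 0

by monotone multiplicative updates (x over nodes, y over graphs), discretizes
the solution against the exact thresholds — minimum size 4, minimum induced
density 0.6, minimum frequency 1% by default — masks the accepted pattern
and repeats. Patterns are then restored to the diploid graphs, where the
2^|D| copy assignments collapse into canonical **copy signatures** (invariant
under per-chromosome A↔B swaps), and each (domain set, signature) variant is
counted per structure — the "coupled isomorphism" problem reduced to item
counting. Downstream: permutation-test factor enrichment with BH q-values
(regulatory communities at q < 0.05), centromeric-influence and radial
statistics, partial correlation of cluster frequency vs enriched-factor
count, TF grouping by enrichment profiles, and NMF biclustering of the
cluster × structure occurrence matrix into substates.

A seeded synthetic generator (confined diploid sphere chains with planted
co-localizing clusters, planted signal enrichment and planted substates)
provides ground-truthed inputs for every stage; an exhaustive brute-force
miner and a monolithic counting oracle anchor correctness on small instances.
See `docs/methods.md` for assumptions, parameter semantics and limitations.

## Worked example

```python
import numpy as np
from cigmine.simulate import SimulationConfig, PlantedCluster, generate_population
from cigmine.graphs import build_cigs, contract
from cigmine.mining import FrequentClusterMiner
from cigmine.isomorphism import count_variants

cfg = SimulationConfig(
    K=500, seed=7,
    planted_clusters=[PlantedCluster(
        members=((1, 3), (1, 12), (2, 7), (3, 5), (3, 15)),
        frequency=0.06, contact_probability=0.9,
        cross_copy=((3, 15),),   # chr3 domain 15 sits on the other homolog
    )],
)
population, domains, truth = generate_population(cfg)
cigs = build_cigs(population, domains)
miner = FrequentClusterMiner(min_size=4, min_density=0.6, min_freq=0.01, seed=11)
miner.fit([contract(g).adj for g in cigs])
clusters = count_variants(miner.patterns_, cigs, domains, 0.6, 0.01)

planted = set(truth.member_ids[0])
best = max(clusters, key=lambda c: (len(planted & set(c.members)), c.frequency))
print("members  ", best.members)
print("signature", best.signature)
print("frequency", round(best.frequency, 4),
      "realized", round(truth.occurrence[0].mean(), 4))
```

Output:

```
members   ('chr1_d03', 'chr1_d12', 'chr2_d07', 'chr3_d05', 'chr3_d15')
signature chr1:[3,12|-]; chr2:[7|-]; chr3:[5|15]
frequency 0.082 realized 0.084
```

The miner recovers the planted 5-domain inter-chromosomal cluster exactly.
The signature reads: the two chromosome-1 domains share a homolog copy, the
chromosome-3 domains sit on opposite copies, and the chromosome-2 domain's
copy is a singleton. The estimated frequency (8.2% of 500 structures) tracks
the realized planting rate (8.4%): occurrences are counted per signature
variant, and a structure where one member failed to co-localize drops out of
the variant's support.

## Command line

Every stage is a subcommand of `cigmine` (simulate, build-graphs, mine,
count, enrich, analyze, substates, run), driven by files in documented TSV /
JSON formats; `cigmine run --config config.yaml` executes the whole pipeline
and writes a manifest. Runs are byte-reproducible from config + seed.

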