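# metorigin

Predict where the compounds in a host-associated metabolome could have come
from, using KEGG reaction networks.

Untargeted metabolomics of stool, plasma or tissue measures a mixture of
small molecules whose producers are unknown: the host, the microbes living
in it, diet, or the environment. `metorigin` addresses the first two. Given
lists of KO (KEGG Orthology) identifiers predicted to be present in one or
more genomic *sources* — typically a microbiome metagenome predicted from
16S data (PICRUSt, Tax4Fun) or assembled from shotgun reads (HUMAnN), plus
the KO content of the host genome — it derives, for each source, the set of
compounds that source's enzymes could produce, classifies each detected
metabolite by putative origin, and tests KEGG pathways for enrichment of
the origin-specific metabolite sets.

## Method

For a source with KO set $S$, the reachable reaction set is
$R(S) = \bigcup_{k \in S} \mathrm{rxn}(k)$ and the **producible compound
set** (closure) is the union of right-hand sides of those reactions'
equations:

$$P(S) = \bigcup_{r \in R(S)} \mathrm{products}(r).$$

KEGG reaction records do not encode reaction direction, so the primary
direction is assumed to be left-to-right: the compounds on the right side
of each equation are its products (an opt-in flag also counts substrates of
`<=>` reactions). A detected compound $c$ is then categorised by which
sources satisfy $c \in P(S)$: for two sources `microbiome_only`,
`host_only`, `both`, or `neither`.

Pathway enrichment of a query set $Q$ (e.g. detected ∩ microbiome-only)
against a compound universe of size $N$ uses the exact upper-tail
hypergeometric probability

$$p = P[X \ge k], \qquad X \sim \mathrm{Hypergeom}(N, K, n),$$

with $K$ the pathway's compounds in the universe, $n = |Q|$ and $k$ the
overlap; every pathway with $k \ge 1$ is tested and raw p-values are
Benjamini–Hochberg adjusted across the tested pathways.

KEGG records come either from local flat files (for license holders) or
from the public KEGG REST API through a throttled, on-disk-cached client.
A deterministic synthetic-KEGG generator (`metorigin synth`) produces
internally consistent KO/reaction/compound/pathway flat files with recorded
ground truth, so the whole pipeline runs and is tested without any KEGG
download.

## Worked example

The smallest real case: butyrate kinase (K00929) performs reaction R01688,
`C02527 (butanoyl phosphate) <=> C00246 (butyrate)`, so a KO list
containing K00929 can produce butyrate — and never butanoyl phosphate,
which only appears on the left.

A full two-source run on the bundled synthetic universe:

```bash
metorigin synth --out-dir kegg --seed 1
# microbiome.txt / host.txt: overlapping KO subsets; detected.txt: 10 compound ids
metorigin run \
  --ko-list microbiome.txt --label microbiome \
  --ko-list host.txt --label host \
  --detected detected.txt --kegg-dir kegg --out results
```

prints

```
{"both": 8, "microbiome_only": 2}
wrote 6 files to results
```

meaning that of the 10 detected compounds, 8 could have been made by
enzymes present in both KO sets and 2 only by the microbiome set.
`results/origin_table.tsv` holds the per-compound calls:

```
compound_id  compound_name         detected  microbiome  host   category         in_database
C00002       synthetic compound 2  True      True        False  microbiome_only  True
C00003       synthetic compound 3  True      True        True   both             True
C00006       synthetic compound 6  False     False       True   host_only        True
```

`results/enrichment_microbiome_only.tsv` is the hypergeometric table for
the microbiome-only detected compounds (k/K = query/universe hits in the
pathway, n/N = query/universe sizes):

```
pathway_id  pathway_name         k  K  n  N   p_raw               p_adj
map00002    synthetic pathway 2  1  8  2  60  0.25084745762711863 0.376271186440678
map00006    synthetic pathway 6  1  8  2  60  0.25084745762711863 0.376271186440678
```

The bundle also contains `kegg_mapper.txt` (paste into KEGG Mapper "Color"
to paint pathway diagrams: microbiome-only objects blue, host-only yellow,
both green, detected compounds outlined orange), `venn_counts.tsv` +
`venn.png` (exact region counts of detected/producible overlaps) and a
JSON run manifest.

To use the real human genome as the host source:

```bash
metorigin extract-organism --org hsa --use-api --cache-dir kegg_cache -o human_kos.txt
```

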