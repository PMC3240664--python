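# interband-scope

Statistical toolkit for characterizing interband-like open-chromatin loci
from protein-binding interval tracks (ChIP-chip style GFF/BED fragments).
Given a set of anchor coordinates (e.g. mapped transposon insertion
sites), it provides:

- **Anchored window profiling** — per-region bound/unbound calls,
  0.5 kb segment heat-map matrices around anchors, per-protein-class
  profiles, and chromatin-state composition/enrichment ratios
  (`window_profiles`).
- **Weighted-resampling enrichment test** — background regions sampled
  with per-arm weights matching the anchors' arm distribution, empirical
  per-region overlap frequency *p*, and an exact binomial tail P-value
  with a direction-dependent tail rule and significance stars
  (`enrichment_null`).
- **Fragment length-class statistics** — genome-wide 1-3 / 4-6 / 7-9 /
  10-11 kb class counts and one-decimal row percentages
  (`fragment_stats`).
- **Pairwise co-localization** — a similarity rate r = k / min(m′, n′)
  computed after mutual redundancy removal (k provably equals the maximum
  one-to-one overlap pairing), plus a 3 kb-block 2×2 chi-square
  co-occupancy test with expectation en = l·m/n (`colocalization`).
- **Embedding and clustering** — ordinal (non-metric) MDS and
  agglomerative hierarchical clustering of the similarity matrix
  (`embedding_clustering`).
- **Synthetic worlds** — fully seeded generators for genomes with planted
  co-binding loci, anchor sets, and chromatin-state maps, so the entire
  pipeline runs and is tested without any external data
  (`synthetic_data`).

## CLI

```sh
interband-scope simulate --seed 1 --outdir world/
interband-scope validate --genome world/genome.tsv world/track_*.bed
interband-scope profile --genome world/genome.tsv --anchors world/anchors.tsv \
    --states world/states.bed --window 10000 --segment 500 --out profiles/ \
    world/track_*.bed
interband-scope enrich --genome world/genome.tsv --anchors world/anchors.tsv \
    --window 10000 --window 4000 --n 13000 --seed 1 --out enrichment.tsv \
    world/track_*.bed
interband-scope lengths --out lengths.tsv world/track_*.bed
interband-scope coloc --genome world/genome.tsv --out coloc/ world/track_*.bed
interband-scope cluster --matrix coloc/similarity_matrix.tsv --k 2 --out cluster/
```

End-to-end from a YAML config (all stages, JSON manifest, byte-identical
TSVs on rerun):

```sh
interband-scope run-all --config examples/demo.yaml --seed 1
```

## Conventions

Internal coordinates are 0-based half-open; GFF input is 1-based
inclusive and converted on read; BED passes through unchanged. Overlap
means ≥1 shared base pair (touching at a boundary is not overlap).
Strand is ignored throughout.
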