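# riboquant

Ribosome-profiling (Ribo-Seq) quantification for recombinant-protein cell
lines, plus batch-culture bioprocess metrics. The package covers:

- **genome** — GTF/GFF3 parsing into gene/transcript models, longest-CDS
  representative transcript selection, genomic ↔ transcript coordinates.
- **ingest** — strand-aware ribosome 5′-end counting from SAM/BAM
  (5′ end of the alignment for + genes, 3′ end for − genes), read-length
  filtering, per-length end profiles, library bookkeeping.
- **calibration** — per-read-length A-site offset estimation from
  start-codon pile-ups, offset application into occupancy tracks, codon
  (frame) periodicity.
- **metagene** — median-codon-normalized coverage profiles anchored at
  start/stop codons, with the trimmed-median gene filter.
- **quantify** — gene-level counts, rpm, tpm, translation efficiency
  (Ribo tpm / RNA tpm), and category-level occupancy with even allocation
  of a gene's rpm across its homolog IDs.
- **stats** — fold changes, two-tailed t-tests, one-gene-vs-population TE
  deviation test, Benjamini–Hochberg FDR, weighted pre-ranked running-sum
  enrichment with a gene-set permutation null, and ΔΔCt qPCR fold changes.
- **bioprocess** — specific growth rate, integral viable cell density, and
  specific productivity (qp, pg/cell/day) by regression of titer on IVCD.
- **simulate** — a truth-tracked synthetic-data generator (genome + GTF
  with three transgenes, Ribo/RNA SAM alignments with per-read truth,
  category maps, gene sets, two-phase culture CSV), all byte-reproducible
  from a config and seed.

## CLI

```bash
# generate a synthetic dataset
riboquant simulate --out data/ --seed 42 --n-genes 10

# calibrate, quantify, and profile
riboquant run --gtf data/annotation.gtf --ribo data/ribo.sam \
              --rna data/rna.sam --out results/

# growth rate + specific productivity per phase
riboquant bioprocess --culture data/culture.csv --out results/bioprocess.tsv

# pre-ranked enrichment (TSV with gene_id, score columns + GMT gene sets)
riboquant gsea --ranks ranks.tsv --gmt data/gene_sets.gmt \
               --out results/gsea.tsv --seed 1
```

`riboquant run` writes `offsets.tsv`, `gene_quant.tsv` (count/rpm/tpm per
gene and assay), `translation_efficiency.tsv`, `metagene_start.tsv` /
`metagene_stop.tsv`, and `summary.json` (frame fractions, offsets, read
bookkeeping).

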