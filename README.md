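# bivalscan

Consensus chromatin-state classification of promoters from multi-sample
H3K4me3/H3K27me3 ChIP-seq peak calls, with the companion analyses needed to
characterise bivalent promoters end-to-end:

- **genomic_io** — GTF/BED/bedGraph/FASTA I/O, strand-aware promoter windows
  (−1000/+2000 bp by default), and an indexed interval-overlap engine.
- **chromatin_state** — per-sample promoter states (bivalent / active /
  repressed / latent) and high-confidence (HC) consensus classes via a strict
  >70% multi-sample rule, plus detection curves, top-signal overlap,
  mark co-location and sample QC.
- **cpg** — CpG observed/expected ratio, TSS-centred CpG density profiles,
  CGI-overlap percentages per class.
- **signal** — reads-per-million TSS-centred density matrices, deterministic
  k-means clustering (k=4) of promoter profiles, group comparison tests.
- **enrichment** — upper-tail hypergeometric overlap tests, TF density per
  promoter class, expression-by-class summaries, single-cell non-expressing
  fractions, perturbation gene-list overlap.
- **cross_species** — class-overlap matrices over one-to-one orthologs and
  conserved/divergent group labels.
- **motif** — fixed k-mer occurrence fractions and positional density
  profiles around TSSs (double-stranded scan).
- **synthetic_data** — a fully seeded synthetic study generator (genome,
  annotation, CGI track, multi-sample peak calls, factor peaks, expression,
  orthologs) with planted ground truth for every recovery test.

## CLI

All stages are exposed through one executable:

```bash
# generate a synthetic study (sizes via a key=value config file)
bivalscan --out-dir sim --seed 7 simulate

# per-sample states -> consensus classes, detection curves, QC
bivalscan --annotation sim/annotation.gtf --out-dir res \
    classify --pairs sim/chip_a/pairs.tsv
bivalscan --out-dir res consensus --states res/state_matrix.tsv --fraction 0.7

# CpG / clustering / enrichment / expression / cross-species / motif
bivalscan --annotation sim/annotation.gtf --genome sim/genome.fa --out-dir res \
    cpg --cgi sim/cgi.bed --classes res/consensus.tsv
bivalscan --annotation sim/annotation.gtf --out-dir res \
    cluster --signals signals.tsv --k 4
bivalscan --annotation sim/annotation.gtf --out-dir res \
    enrich --factors sim/factors/factors.tsv --classes res/consensus.tsv
bivalscan --out-dir res expression --bulk sim/expression/bulk_fpkm.tsv \
    --sc sim/expression/sc_fpkm.tsv --de-lists sim/expression/de_lists \
    --classes res/consensus_genes.tsv
bivalscan --out-dir res compare-species --classes-a a.tsv --classes-b b.tsv \
    --orthologs sim/orthologs.tsv
bivalscan --annotation sim/annotation.gtf --genome sim/genome.fa --out-dir res \
    motif --motif TCCCC --classes res/consensus.tsv
```

`signals.tsv` lists one signal track per row (`factor`, `path`,
`format` ∈ {bed, bedgraph}); `pairs.tsv` lists one paired sample per row
(`sample_id`, `k4_bed`, `k27_bed`).

## Conventions

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read.  Minus-strand windows mirror plus-strand windows in
transcript-relative coordinates, and all TSS-centred profiles are oriented
5′→3′.  Overlap means ≥1 shared base.  All randomness flows from explicit
seeds via `numpy.random.SeedSequence`, so every simulation is byte-for-byte
reproducible.
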