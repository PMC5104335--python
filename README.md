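# somhub

A tested, reusable pipeline for time-series transcriptome analysis of a
two-genotype developmental design (control vs knockout across five
postnatal timepoints, three replicates each):

1. **Preprocessing** — per-array background cutoffs (mean + 2·sd of
   negative-control probes), probe-quality filtering, cross-timepoint
   presence filtering, probe→gene collapse (highest first-timepoint
   median), quantile normalization and classical MDS for QC.
2. **Stage clustering** — top-30 %-CV gene selection on per-timepoint
   medians, per-gene z-scoring, a 3×6 hexagonal self-organizing map
   (100 iterations, learning rate 0.009→0.006), PCA visualization and
   rule-based stage categorization of the units
   (neonatal / juvenile / adult / atypical).
3. **Co-expression hubs** — per-cluster weighted networks: soft power
   chosen by scale-free fit (target 0.8), powered-|Pearson| adjacency,
   topological overlap matrix (TOM), TOM-based connectivity, and hub
   calling by average connectivity rank over 100 bootstrap resamples of
   the arrays (top 5 % = hubs). Clusters that never satisfy the
   scale-free criterion report "not determined".
4. **Differential expression** — per-timepoint KO-vs-control moderated
   t (empirical-Bayes variance shrinkage with moment-matched prior),
   Benjamini–Hochberg FDR ≤ 0.01 and two-sided 1.5-fold-change calling,
   DE–hub intersection, and cross-age consistency lists.
5. **Enrichment** — hypergeometric gene-set overrepresentation (GMT)
   and PWM promoter-motif enrichment (JASPAR PFM; best log₂-odds score
   per sequence on both strands, quantile threshold + one-sided Fisher
   exact test). Soft-masked (lowercase) and ambiguous bases are never
   scored.
6. **Synthetic data** — a first-class generator producing raw intensity
   matrices (GCT), sample sheets, probe annotation, promoter FASTA and
   ground-truth tables with planted temporal archetypes, latent-factor
   co-expression modules with designated hubs, genotype-specific fold
   changes, negative controls, multi-probe genes, low-quality probes and
   planted motif occurrences — so every stage is testable offline.

## Command-line interface

All stages are exposed through one entry point:

```sh
somhub simulate   --out-dir data --n-genes 1500 --seed 1 [--config cfg.json]
somhub validate   --gct data/control.gct --sample-sheet data/samples.tsv \
                  --annotation data/annotation.tsv
somhub preprocess --gct data/control.gct --gct data/ko.gct \
                  --sample-sheet data/samples.tsv \
                  --annotation data/annotation.tsv --out-dir prep
somhub cluster    --gct prep/control_normalized.gct \
                  --sample-sheet data/samples.tsv --out-dir clust --seed 0
somhub network    --gct prep/control_normalized.gct \
                  --sample-sheet data/samples.tsv \
                  --clusters clust/clusters.tsv --out-dir net
somhub de         --gct prep/control_normalized.gct --gct prep/ko_normalized.gct \
                  --sample-sheet data/samples.tsv --out-dir de
somhub intersect  --de-dir de --network-dir net --out de_hubs.tsv
somhub enrich     --gmt sets.gmt --query query.txt --universe universe.txt --out enr.tsv
somhub motif      --fg fg.fa --bg bg.fa --pfm motif.pfm --out motif.tsv
```

File formats: GCT 1.2 expression matrices, tab-separated sample sheets
(`sample_id  genotype  timepoint  replicate`), tab-separated probe
annotation (`probe_id  gene_symbol  quality  is_negative_control`), GMT
gene sets, JASPAR PFM count matrices (plain 4-row or bracketed), FASTA
(soft-masked lowercase respected) and tab-separated edge lists.

## Package layout

```
src/somhub/
  io_formats.py       # GCT / sample sheet / GMT / JASPAR / FASTA / edge lists
  synthetic.py        # ground-truth data generator + promoter simulator
  preprocess.py       # background & quality filters, collapse, quantile norm, MDS
  som_cluster.py      # CV selection, scaling, PCA, hexagonal SOM, categorizer
  coexpr_network.py   # scale-free fit, adjacency, TOM, bootstrap hub ranking
  diff_expression.py  # moderated t, BH, DE calls, hub intersection, consistency
  enrichment.py       # hypergeometric ORA + PWM motif enrichment
  cli.py              # click entry points
```
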