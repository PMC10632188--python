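# cycflex

Genome-scale analysis of intrinsic DNA mechanical flexibility ("cyclizability").
The package bundles:

- **Predictor** — a trainable sequence→cyclizability regressor (1D conv blocks →
  recurrent layer → dense, pure-numpy implementation trained with Adam on MSE)
  plus a linear dinucleotide surrogate, both behind one contract with exact
  reverse-complement averaging (`predictor`).
- **Null models** — single-base shuffling, exact dinucleotide-preserving
  (Eulerian) shuffling, distance-matched shuffling, and position-specific
  "vertical" mono/dinucleotide samplers (`randomization`).
- **Metaprofiles** — TSS/anchor-centered mean-cyclizability profiles with the
  25th-base window registration, randomized-profile comparisons, dinucleotide
  log-ratio composition profiles, per-position tracks and autocorrelation
  (`profiles`).
- **Genome scan** — genome-wide actual-vs-shuffled differences
  (D = C_actual − C_shuffled) with exon/non-exon style interval stratification
  (`genome_scan`).
- **Feature comparisons** — effect sizes (Cohen's d with pooled s) of window
  sets defined by variants, cytosine methylation contexts (CG/CHG/CHH),
  TF-bound vs unbound motif sites, and per-position track correlation
  (`feature_compare`, `stats`).
- **Synthetic data** — genomes with planted TSS-proximal dinucleotide structure
  (incl. TATAWAWR subsets), loop-seq-style libraries from a linear dinucleotide
  ground truth, and variant/methylation sets with calibrated planted or null
  associations, plus a closed-form expected-profile oracle (`synthetic_data`).

Standard formats are consumed at the boundary: FASTA, GFF3 (1-based), BED
(0-based half-open), bedGraph, and loop-seq TSV (`sequence`, `c0` columns).

## CLI

A single entry point `cycflex` dispatches all subcommands:

```sh
cycflex simulate --preset library --n 20000 --seed 1 --out sim/
cycflex train --library sim/library.tsv --seed 1 --out run/
cycflex evaluate --model run/model.json --library sim/library.tsv
cycflex predict --model run/model.json --fasta probes.fa --out preds.tsv

cycflex simulate --preset tss-profile --seed 1 --out simg/
cycflex tss-profile --fasta simg/genome.fa --gff simg/annotation.gff3 \
    --model simg/truth_model.json --flank 150 --out prof/
cycflex tss-profile ... --mode mono_h --reps 3 --seed 2 --out prof_null/
cycflex dinuc-profile --fasta simg/genome.fa --gff simg/annotation.gff3 \
    --flank 150 --out dinuc.tsv
cycflex acf --fasta simg/genome.fa --model simg/truth_model.json \
    --chrom chr1 --start 0 --end 50000 --max-lag 100 --out acf.tsv
cycflex genome-scan --fasta simg/genome.fa --model simg/truth_model.json \
    --shuffles 5 --seed 1 --out scan/
cycflex shuffle --fasta in.fa --mode dinuc --seed 1 --out shuffled.fa
cycflex variants --fasta g.fa --model m.json --variants v.bed --out v.json
cycflex methylation --fasta g.fa --model m.json --sites meth.tsv \
    --promoters prom.bed --out meth.json
cycflex tf-profile --fasta g.fa --model m.json --sites motifs.bed --out tf/
cycflex correlate-track --fasta g.fa --model m.json --track signal.bedgraph
```

Every analysis writes a run log (parameters, seed, version) beside its
outputs; output directories are never overwritten without `--force`.

## Conventions

- Coordinates are 0-based half-open internally; the window statistic at
  position/offset *p* belongs to the 50-bp window whose 25th base (1-based)
  is *p*.
- Minus-strand anchored regions are reverse-complemented so profile offsets
  run 5′→3′ of the gene.
- All predictions reported by analyses are the mean of the forward and
  reverse-complement scores, which makes them exactly strand-symmetric.
- All generators and analyses are deterministic given their seed (on one
  platform).
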