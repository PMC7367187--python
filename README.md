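# intronclass

Genome-wide classification of spliceosomal introns into **U2-type**
(major spliceosome) and **U12-type** (minor spliceosome) classes, for
researchers studying minor-spliceosome biology and intron evolution.

U12-type introns are rare (typically well under 1% of a genome's
introns) and cannot be identified from terminal dinucleotides alone:
both classes are dominated by GT-AG termini. What distinguishes them is
an extended 5′ splice-site motif and a tightly constrained branch-point
sequence. `intronclass` implements the standard two-dimensional scoring
approach and a calibrated linear SVM on top of it:

1. **Intron extraction.** Introns are interpolated between adjacent
   exon or CDS features of a GFF3/GTF annotation, within the longest
   isoform of each gene. CDS-defined runs carry reading-frame phase;
   exon-defined runs capture UTR and non-coding introns; the two runs
   are merged with CDS records taking precedence.
2. **PWM scoring.** Each intron gets a score vector
   (*s*₅′SS, *s*BPS), where each component is a log-odds score

   *s* = Σᵢ log₂ ( (f U12ᵢ(xᵢ) + c) / (f U2ᵢ(xᵢ) + c) ),

   with position-weight-matrix frequencies *f*, pseudo-count
   *c* = 0.001, the 5′SS window spanning positions −3..+9 around the
   first intron base, and the BPS taken as the best-scoring 12-mer in
   the window −55..−5 upstream of the intron's last base. Because
   U2-type introns have no extended branch-point consensus, the U2 BPS
   matrix is derived *empirically* from the input genome itself: the
   best U12-scored branch-point 12-mers of all introns whose 5′SS score
   falls below the 95th percentile.
3. **Classification.** A linear-kernel SVM is trained on labeled score
   vectors (U2 ≫ U12 imbalance is expected; model selection uses
   balanced accuracy, and the penalty *C* is chosen by an iterative
   cross-validated grid search). Decision values are mapped to U12
   probabilities by a sigmoid calibrated on out-of-fold decision
   values; introns with **p(U12) ≥ 0.90** are called U12-type.

Downstream analyses: phase-distribution chi-squared tests, −1
nucleotide and terminal-dinucleotide tables, alternative-splice-site
deduplication, a binomial test for clustering of U12-type introns
within genes, intron-length/genome-size correlations, the wobble-G
codon-family count, and orthologous-intron grouping from precomputed
protein alignments via maximal-clique listing. A synthetic-genome
module plants known U2/U12 motifs so the entire pipeline is testable
without downloads.

## Worked example

```python
from intronclass.simulate import SimulationConfig, simulate_genome, simulate_training_set
from intronclass.pipeline import classify_genome, extract_all_introns
from intronclass.stats import terminal_dinucleotide_table

cfg = SimulationConfig(seed=7, n_genes=40, introns_per_gene=4, u12_fraction=0.05)
sim = simulate_genome(cfg)
introns = extract_all_introns(sim.gff3, sim.genome, feature="both", assembly="sim1")
u12_txt, u2_txt = simulate_training_set(2000, 200, cfg)
table, model, pwms, u2_bps = classify_genome(introns, u12_txt, u2_txt, seed=7)

print(f"{len(table)} introns; C = {model.C_:.1f}")
print(table[table.call == "U12-type"]
      [["intron_id", "five_ss_bits", "bps_bits", "p_u12_pct"]]
      .round(2).to_string(index=False))
```

prints

```
160 introns; C = 996.0
               intron_id  five_ss_bits  bps_bits  p_u12_pct
sim1:chr1:12441-12511(-)         22.41     10.36      100.0
sim1:chr1:28728-28801(+)         18.23     10.36      100.0
sim1:chr1:30738-30807(+)         17.54     10.36      100.0
sim1:chr1:33725-33794(+)         22.41     10.36      100.0
sim1:chr1:38692-38793(+)         22.41      6.98      100.0
sim1:chr1:42789-42954(-)         22.41      7.24      100.0
sim1:chr1:43862-43987(+)         22.41     10.36      100.0
sim1:chr1:45648-45779(+)         22.14     10.36      100.0
```

All eight planted U12-type introns (5% of 160) are recovered with
positive 5′SS and BPS log-odds scores and probabilities at 100%; no
U2-type intron is miscalled. The large optimized *C* reflects the broad
plateau of equally good penalties on well-separated data. Terminal
dinucleotides of the same run:

```
          GT-AG  GC-AG  AT-AC  other
U12-type  100.0    0.0    0.0    0.0
U2-type    94.1    2.0    1.3    2.6
```

The same pipeline is available from the shell:

```bash
intronclass simulate genome --out fixtures/
intronclass simulate training --out fixtures/ --n-u2 2000 --n-u12 200
intronclass classify --annotation fixtures/annotation.gff3 --genome fixtures/genome.fa \
    --train-u12 fixtures/train_u12.tsv --train-u2 fixtures/train_u2.tsv \
    --feature both --seed 7 --out calls.tsv
intronclass stats --introns calls.tsv --report reports/
```

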