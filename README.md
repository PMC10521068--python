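# exdel

Detection of internal exon-deletion isoforms in targeted genes from RNA-seq.

Focal intragenic deletions matter clinically: in B-cell precursor acute
lymphoblastic leukaemia, deletion of IKZF1 exons 4–7 produces the
dominant-negative IKAROS isoform IK6, which carries prognostic weight. At the
transcript level such a deletion creates a novel splice junction (exon 3
joined directly to exon 8), and reads spanning that junction are direct
RNA-seq evidence for the deletion — without prior knowledge of *which* exons
are lost.

`exdel` turns this into a targeted pipeline:

1. **Deletion transcriptome.** From a BED12 definition of a gene's canonical
   transcript with N exons, generate every transcript lacking one consecutive
   run of *internal* exons (the first and last exon are never deleted). There
   are C(N−1, 2) such transcripts — 6 for a 5-exon gene, 21 for the 8-exon
   IKZF1 — each carrying a unique novel junction.
2. **Pseudoalignment.** Reads are assigned k-mer equivalence classes (ECs)
   against this mutually exclusive reference. A read whose EC is a single
   deletion transcript is junction evidence; it must additionally survive an
   end-to-end alignment check (≤ `mismatch` substitutions, default 2) and a
   *trim test* (re-classification after removing `trim` bases from each end,
   default 5), so a few bases overhanging an exon boundary can never be the
   sole support. For read pairs the smaller (more specific) EC wins.
3. **Counting and scaling.** Robust unique reads accumulate in the deletion's
   unique count (UC); every other mapped read of the gene goes to the total
   count (TC). Each deletion is scored by the **scaled proportion**

   ```
   scaled = (UC / TC) × L_gene / (L_read × (2 if paired else 1))
   ```

   where `L_gene` is the canonical transcript length — the length correction
   accounts for only junction-overlapping reads being eligible as UC.
4. **Cohort scoring.** Scaled proportions across a cohort are standardized to
   per-deletion Z-scores; a sample is an outlier for a deletion when
   z ≥ 3 **and** UC > 10 (the count filter suppresses artefacts in lowly
   expressed genes). Absolute confidence bands use scaled-proportion
   thresholds of 0.1 (high), 0.01 (medium) and 0.001 (low), of the kind
   calibrated on a validated cohort by ROC analysis. A frozen cohort
   background (per-deletion mean/sd + thresholds) can score single new
   samples.

A seeded simulator (`exdel.simulate`) generates random genes, deletion-isoform
read mixtures and analytic junction-read expectations, so the whole pipeline
is testable end to end without any external data.

## Worked example

Simulate an 8-exon gene (200 bp exons, canonical transcript 1600 bp) with a
10% admixture of the exon 4–7 deletion isoform, then index, map and quantify:

```python
import exdel as X

gene, genome = X.random_gene(8, 200, seed=1)
records, dels = X.deletion_transcriptome(gene, genome)   # canonical + 21 deletions
idx = X.build_index(records, k=31)

cfg = X.SimulationConfig(abundances={"tx1": 0.9, "tx1|del4_7": 0.1},
                         n_reads=50_000, read_length=100, seed=7)
reads, truth = X.simulate_reads(cfg, records, deletions=dels)

counts = X.map_reads(reads, idx)
rows = X.quantify(counts["tx1"], gene.canonical_length)
```

Output (top deletions by scaled proportion):

```
expected UC[del4_7]: 649.1
del4_7   UC= 636 TC=49364 scaled=0.2061
del2     UC=   0 TC=49364 scaled=0.0000
band: high
```

Of 50,000 reads, 636 uniquely and robustly span the del4_7 junction, in
agreement with the analytic expectation 649 ± 25 from fragment geometry
(a 100 bp read has 91 start positions covering the junction with ≥ 5 bases
each side). No other deletion collects a single unique read. The scaled
proportion 0.206 lands in the *high* confidence band — the deletion is called
unambiguously at 10% abundance.

The same pipeline runs from the shell:

```sh
exdel build --bed GENE.bed --genome GENOME.fa --out TRANSCRIPTOME.fa
exdel index --transcriptome TRANSCRIPTOME.fa --out GENE.idx
exdel map --index GENE.idx --reads R1.fq [--reads2 R2.fq] --out SAMPLE.csv
exdel cohort --results RESULTS_DIR/ --out PREFIX [--labels LABELS.csv]
exdel compare --background PREFIX_background.json --sample SAMPLE.csv
exdel extract --bam SAMPLE.bam --region chr7:50304716-50405101 --out READS.fq
```

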