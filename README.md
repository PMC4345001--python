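# genemerge

Strategy-aware consensus of gene predictions.

Gene finders fall into two families with complementary failure modes.
*Ab initio* methods (GeneMark, GLIMMER3, AUGUSTUS in its default mode, …)
predict genes from the genome sequence alone: they are sensitive, but they
cannot know whether a gene is expressed and they inherit every bias of
their training data. *Evidence-based* methods (Cufflinks, GIIRA, EST- or
homology-driven pipelines, …) predict only what the external data supports:
they are specific about expression, but ragged at boundaries and blind
wherever coverage is thin. A true gene tends to be found by both families;
a false positive of one method is almost never reproduced independently by
a method of the other family.

`genemerge` exploits exactly that asymmetry. It takes two or more
prediction files, each tagged by the user as `ab_initio` or `evidence`,
walks through the ab initio ("leading") predictions, and keeps each one
only if an evidence-based prediction supports it. Supported predictions are
classified by reliability; everything method-unique is diverted to side
files instead of the consensus. No weighting scheme, no training, no
a-priori knowledge — the combination itself is the filter.

## The acceptance rules

Let *t* be the overlap threshold (default **0.8**, configurable up to 1.0
for perfect-overlap-only merging).

**Prokaryote mode** (single-exon loci). A leading transcript is

- **PERFECT** if some evidence prediction has identical exon boundaries;
- **SUPPORTED** if the best exonic overlap covers *more than* `t` of the
  leading prediction's exonic length (the sum of its exon lengths) —
  strictly greater, so a fraction of exactly 0.8 does not support;
- **UNSUPPORTED** otherwise (emitted to a side file).

**Eukaryote mode** compares *exon chains*, because an overlapping exon only
means agreement when its neighbouring exons agree too — otherwise it
signals an alternative isoform. Each isoform of each leading locus is
tested separately:

- **PERFECT**: all exons boundary-identical in one evidence method;
- **SUPPORTED**: all exons matched, with minor within-`t` boundary
  differences (lower score);
- partial matches trigger conflict resolution: if ≥2 evidence methods agree
  with *each other* but not with the leading transcript, the leading
  prediction is considered wrong and the concordant evidence structure is
  emitted instead; if the evidence disagrees among itself, the leading
  transcript is **PARTIAL_ACCEPTED** only when the matched-exon count *k*
  out of *n* satisfies `k ≥ ⌊t·n⌋` for the leading chain *and* for the
  chosen evidence chain;
- with ≥2 evidence inputs, genes absent from every ab initio output but
  concordantly predicted by ≥2 evidence methods can be reported as
  **NOVEL_EVIDENCE** (`--novel`).

When a reference annotation is available, any prediction set can be
evaluated with Cuffcompare-convention metrics at exon and transcript level:
sensitivity `= TP/(TP+FN)`, "specificity" `= TP/(TP+FP)` (i.e. precision),
and their harmonic mean, the F-measure.

## Worked example

A fully synthetic run (no external tools needed): simulate a 200-gene
prokaryotic annotation where 70% of genes are expressed, an ab initio
finder that sees all genes (5% dropped, 30% spurious extra genes), and an
evidence-based finder that sees only the expressed subset (10% dropped, 30%
spurious), with each method's false positives unique to it:

```
$ genemerge simulate --seed 11 --n-genes 200 -o sim
$ genemerge merge --ab-initio sim/abinit_sim.gtf --evidence sim/evidence_sim.gtf \
      --mode prok -o merged
INFO genemerge: 118 consensus transcripts -> merged/merged.gtf
$ genemerge evaluate merged/merged.gtf sim/truth_expressed.gtf -o merged_accuracy.tsv
$ cat merged_accuracy.tsv
level    tp   fp   fn   sensitivity  specificity  f_measure  missed  novel
exon     118  0    22   0.842857     1.000000     0.914729   22      0
transcript 118 0   22   0.842857     1.000000     0.914729   22      0
```

The ab initio input alone scores specificity 0.524 against the same ground
truth (131 true + 119 false predictions); the consensus removes every false
positive (fp = 0, specificity 1.0) while keeping 118 of the 140 expressed
genes — the 22 missed are genes dropped by at least one of the two input
methods, which no combiner can recover. `merged/merged.gtf` carries the
reliability class and score of each record, and
`merged/merged.tracking.tsv` lists the original predictions behind every
consensus transcript:

```
GM000001  PERFECT  abinit_sim|abinit_sim_gene00001|abinit_sim_gene00001.t1  evidence_sim|evidence_sim_gene00001|evidence_sim_gene00001.t1
```

The same workflow is available as a library (`genemerge.merge.merge`,
`genemerge.evaluate.exon_level`, …); the CLI is a thin wrapper over it.

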