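# Methods

## The consensus model

`genemerge` treats gene-prediction combination as a support-testing
problem, not an averaging problem. Predictions are first categorised by
strategy — *ab initio* (sequence-model driven) or *evidence based*
(expression/homology driven) — because the two families make largely
independent errors: an erroneous call by one method is rarely reproduced by
a method of the other family, while true genes usually are. Combining two
ab initio methods is rejected by the engine, since their training data and
statistical models overlap too much for the independence assumption to
hold; a user who wants such a combination must deliberately re-tag one
input (and accept that "evidence" support then means no external evidence).

The engine iterates over the ab initio transcripts (the *leading*
predictions) and asks whether any evidence-based prediction supports each
one. The unit of measure is always exonic length — the sum of exon lengths,
not the genomic span — so introns never count toward support.

### Thresholds, and a deliberate asymmetry

One tolerance parameter `t` (default 0.8) governs everything, but it is
applied with two different comparison operators, following the way each
rule is stated in the field:

- the **nucleotide-fraction** test is *strict*: an overlap supports only if
  `intersection / exonic_length(leading) > t`. A fraction of exactly `t`
  does not support.
- the **exon-count** test is *inclusive*: a chain with `k` of `n` exons
  matched passes if `k ≥ ⌊t·n⌋`.

The asymmetry is intentional and is covered by boundary tests. The floor is
computed as `floor(t·n + 1e-9)`: binary floating point can place an exact
decimal product one ulp below its true value (`0.7·10 → 6.999…`), and the
epsilon restores the intended integer without affecting any non-degenerate
case.

`PERFECT` requires boundary-identical exon structure, not merely an overlap
fraction of 1.0 — a prediction that *contains* the leading transcript also
reaches fraction 1.0 but is not a perfect agreement, and perfection should
be a symmetric relation.

### Exon-chain matching (eukaryote mode)

Two chains are compared by pairing exons under two constraints: each exon
pairs with at most one exon of the other chain, and pairs never cross (the
pairing respects both chains' 5'→3' order). Among all such pairings the
engine computes, by dynamic programming over the two exon lists, the one
matching the most leading exons, breaking ties toward boundary-exact pairs.
A pair is `EXACT` on boundary identity and `PARTIAL` when the overlap
exceeds `t` of the leading exon's length — the global threshold reused per
exon, so no second tolerance parameter is introduced. The test suite checks
the DP against exhaustive enumeration of all order-consistent pairings.

`all_matched` (every leading exon matched) is what "similar exon chain"
means operationally: an unmatched internal exon indicates an alternative
isoform, and the candidate then does not support this isoform even where
individual exons overlap.

### Conflict resolution

When a leading transcript is only partially matched and at least two
evidence methods overlap it, the engine asks whether the evidence agrees
better with itself than with the leading prediction. If a group of
transcripts from ≥2 distinct evidence methods is pairwise `all_matched` (in
both directions, same `t`) while none of them is `all_matched` against the
leading chain, the leading prediction is regarded as incorrect and the
agreed structure is emitted instead — once, even if it overlaps several
leading transcripts (deduplicated by method and transcript id), with the
superseded leading prediction retained in the provenance. The emitted
coordinates are those of the group member that sorts first by
`(method_name, transcript_id)`; the group members agree within `t`, and a
deterministic representative is required for reproducible output.

If the evidence disagrees among itself, the leading transcript survives as
`PARTIAL_ACCEPTED` when the exon-count rule holds *on both sides* — for the
leading chain against the candidate and for the candidate's own chain
against the leading transcript — so a 5-exon prediction cannot be rescued
by a 20-exon candidate that happens to share four exons. A leading
transcript overlapped by exactly one (disagreeing) evidence transcript is
handled by the same both-sides rule directly; this situation is not covered
by the pairwise-agreement test, which needs two candidates, and the
both-sides rule is its natural single-candidate limit.

Scores encode only the mandated ordering (agreement quality):
`PERFECT = 1.0 > SUPPORTED = 0.75 > PARTIAL_ACCEPTED = NOVEL_EVIDENCE
= 0.5`. The values themselves are conventions and configurable
(`MergeConfig.score_map`); nothing downstream depends on their magnitudes.

### Novel genes

With ≥2 evidence inputs, a transcript that no ab initio prediction covers
beyond `t` (fraction measured against the evidence transcript) and that is
concordantly predicted by ≥ `min_evidence_for_novel` (default 2) distinct
evidence methods is reported as `NOVEL_EVIDENCE`. Mutually supporting
evidence transcripts are collapsed to one record carrying all sources.
Requiring two *different* evidence methods — ideally with different
evidence types — keeps single-method artifacts out.

### Strand policy

Strand handling is configurable because converted prokaryotic input can be
unstranded: `require_match` (default), `ignore_unstranded` (`.` compares
with either strand), `ignore_all`. Cross-strand support under `ignore_all`
is biologically dubious and exists for exploratory use only.

### Determinism

The engine contains no randomness. Outputs are ordered by genomic
coordinate and merged ids (`GM000001`, …) are assigned in that order, so a
merge is byte-reproducible from its inputs and configuration. Evidence-set
order never changes the set of consensus transcripts or their classes,
only the order of source tokens.

## Evaluation

Metrics follow the Cuffcompare convention: sensitivity `TP/(TP+FN)`,
"specificity" `TP/(TP+FP)` — **precision**, not the true-negative rate; a
genome offers no countable negatives — and F-measure as their harmonic mean
(defined as 0 when both are 0). Exon level counts deduplicated exact-
boundary exon matches, so shared exons of multiple isoforms count once per
side. Transcript level requires the full exon chain to match; a terminal
tolerance (default 0 nt) can relax only the outermost 5'/3' ends, because
assemblers that do not model start/stop codons mismatch termini
systematically. `missed`/`novel` count features with no overlap at all, in
either direction. Intron-chain and base-level metrics, Cuffcompare class
codes and locus-fusion heuristics are out of scope.

## The synthetic-data generator

The generator emulates the benchmark conditions the engine is designed
for, entirely in code:

- **truth**: `n_genes` (default 200) non-overlapping loci on one sequence,
  uniform gene lengths 300–3000 nt (prokaryote) or 2–8 exons of 50–400 nt
  separated by introns of 50–2000 nt (eukaryote), random strands, and —
  in eukaryote mode — a second isoform for about half of the ≥3-exon genes,
  formed by skipping one internal exon. Uniform length distributions are
  the least-assumption choice and are configurable; nothing in the engine
  depends on them.
- **expressed subset**: exactly `round(0.7·n)` genes by default, emulating
  that not all genes are transcribed at once. Evidence-style predictions
  derive from this subset; it is also the evaluation ground truth.
- **per-method error profiles**: dropped genes (exact seeded counts),
  Gaussian boundary jitter (clamped to keep exons valid and disjoint),
  per-exon drops (partial transcripts, as low-coverage RNA-seq produces),
  terminal extensions (the spurious first/last exon that ab-initio-leaning
  hybrid finders add), and false-positive genes.
- **method-unique false positives by construction**: FPs are placed only in
  intergenic gaps of the *full* truth (so an evidence FP can never support
  an ab initio prediction of a non-expressed gene), with a 50 nt margin,
  and the gap pool is partitioned round-robin between FP-injecting methods.
  This makes the filtering property exact — merged output provably cannot
  contain any FP — rather than statistical.

Every perturbed gene is recorded in a manifest (`true source gene` or
`FP`), which the tests reconcile against the configured rates. All
randomness flows from one root seed through per-method `SeedSequence`
streams; fixed seed ⇒ bitwise-identical GTF output.

What the generator does **not** emulate: read-level noise and alignment
artifacts, coverage gradients, sequence content, overlapping genes/operons
and origin-spanning ORFs, UTR/CDS substructure. Passing tests therefore
demonstrate the combination logic under clean interval semantics, not
end-to-end performance on real gene-finder output, where error modes are
correlated between methods in ways the independence construction
deliberately excludes.

## Problem sizes

The shipped scenarios use 200 prokaryotic genes (≈2 Mb) and 60–100
eukaryotic genes (1.5–3 Mb) with one to three simulated methods; at these
sizes the complete pipeline runs in about a second, and the brute-force
oracles (position sets, exhaustive pairing enumeration) remain exact and
fast. All components scale to full annotations — the merge is
interval-indexed per sequence — but the validation relies on small
instances where independent oracles are feasible.

## Known limitations

- GTF parsing is restricted to the Cufflinks dialect (exon rows with
  `gene_id`/`transcript_id`); GFF3 generality is out of scope.
- The Glimmer3 converter derives strand from the frame's sign and
  normalises reversed coordinates; wrap-around ORFs crossing the origin are
  not handled.
- UTR/CDS features are neither read nor written; the exon feature is the
  sole coding-structure carrier, which matches the least common denominator
  of gene-finder output formats.
- Transcript-level evaluation is quadratic in transcripts per sequence
  region in the worst case; adequate for annotation-scale inputs, not for
  millions of transcripts.
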