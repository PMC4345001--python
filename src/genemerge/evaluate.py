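"""Cuffcompare-style accuracy evaluation against a reference annotation.

Metrics follow the Cuffcompare convention used throughout transcript-
assembly benchmarking: sensitivity = TP/(TP+FN), "specificity" = TP/(TP+FP)
— i.e. precision, *not* the epidemiological true-negative rate (a genome has
no countable negatives) — and the F-measure is their harmonic mean,
summarising overall prediction accuracy.

Two levels are computed. At the *exon level* a predicted exon is a true
positive iff a reference exon with identical boundaries (and compatible
strand) exists; identical exons shared by several isoforms are deduplicated
on both sides first, so multi-isoform genes do not inflate the counts. At
the *transcript level* a prediction is a true positive iff its full exon
chain matches a reference transcript — all internal boundaries exact, with
a configurable tolerance (default 0) on the outermost 5'/3' ends only,
because some assemblers do not predict start/stop codons and so terminal
mismatches are systematic rather than informative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import PredictionSet, Transcript

__all__ = ["AccuracyReport", "exon_level", "transcript_level", "f_measure",
           "evaluate_both_levels", "write_report"]


@dataclass(frozen=True)
class AccuracyReport:
    level: str
    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    f_measure: float | None
    missed: int   # reference features with no overlap at all
    novel: int    # predicted features with no reference overlap at all

    def row(self) -> list:
        fmt = lambda x: "NA" if x is None else f"{x:.6f}"
        return [self.level, self.tp, self.fp, self.fn,
                fmt(self.sensitivity), fmt(self.specificity),
                fmt(self.f_measure), self.missed, self.novel]


def f_measure(sn: float, sp: float) -> float:
    """Harmonic mean of sensitivity and specificity; 0 when both are 0."""
    if sn + sp == 0:
        return 0.0
    return 2.0 * sn * sp / (sn + sp)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def _report(level: str, tp: int, fp: int, fn: int, missed: int, novel: int
            ) -> AccuracyReport:
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tp, tp + fp)
    f = f_measure(sn, sp) if sn is not None and sp is not None else None
    return AccuracyReport(level, tp, fp, fn, sn, sp, f, missed, novel)


def _unique_exons(pred: PredictionSet) -> set[tuple[str, int, int, str]]:
    return {
        (t.seq_id, e.start, e.end, t.strand)
        for t in pred.transcripts()
        for e in t.exons
    }


def _exon_tp(pred_exons, ref_exons) -> int:
    tp = 0
    ref_by_coord = {}
    for seq, s, e, strand in ref_exons:
        ref_by_coord.setdefault((seq, s, e), set()).add(strand)
    for seq, s, e, strand in pred_exons:
        strands = ref_by_coord.get((seq, s, e))
        if strands and (strand in strands or strand == "." or "." in strands):
            tp += 1
    return tp


def _count_no_overlap(query: set, target: set) -> int:
    """Features in `query` overlapping nothing in `target`.

    Target intervals are first collapsed into a disjoint sorted union per
    sequence, after which each query needs a single bisect.
    """
    import bisect

    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq, s, e, _ in target:
        by_seq.setdefault(seq, []).append((s, e))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for seq, ivs in by_seq.items():
        ivs.sort()
        out: list[list[int]] = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[seq] = ([s for s, _ in out], [e for _, e in out])

    n = 0
    for seq, s, e, _ in query:
        if seq not in merged:
            n += 1
            continue
        starts, ends = merged[seq]
        i = bisect.bisect_left(starts, e) - 1  # rightmost interval starting before e
        if i < 0 or ends[i] <= s:
            n += 1
    return n


def exon_level(pred: PredictionSet, ref: PredictionSet) -> AccuracyReport:
    """Exon-level accuracy: exact-boundary matching on deduplicated exons."""
    if not ref.loci:
        raise ValueError("empty reference annotation")
    pred_exons = _unique_exons(pred)
    ref_exons = _unique_exons(ref)
    tp = _exon_tp(pred_exons, ref_exons)
    fp = len(pred_exons) - tp
    fn = len(ref_exons) - _exon_tp(ref_exons, pred_exons)
    missed = _count_no_overlap(ref_exons, pred_exons)
    novel = _count_no_overlap(pred_exons, ref_exons)
    return _report("exon", tp, fp, fn, missed, novel)


def _chains_match(a: Transcript, b: Transcript, tol: int) -> bool:
    """Exon chains equal, up to ``tol`` nt at the outermost 5'/3' ends."""
    if a.seq_id != b.seq_id:
        return False
    if a.strand != b.strand and "." not in (a.strand, b.strand):
        return False
    ba, bb = a.exon_boundaries(), b.exon_boundaries()
    if len(ba) != len(bb):
        return False
    if tol == 0:
        return ba == bb
    if len(ba) > 2 and ba[1:-1] != bb[1:-1]:
        return False
    # internal boundaries of the first/last exon must still be exact
    if len(ba) > 1 and (ba[0][1] != bb[0][1] or ba[-1][0] != bb[-1][0]):
        return False
    return abs(ba[0][0] - bb[0][0]) <= tol and abs(ba[-1][1] - bb[-1][1]) <= tol


def transcript_level(
    pred: PredictionSet, ref: PredictionSet, terminal_tolerance: int = 0
) -> AccuracyReport:
    """Transcript-level accuracy: full exon-chain matching.

    With the default tolerance 0 a chain must match every boundary exactly;
    a positive tolerance relaxes only the outermost transcript ends.
    """
    if not ref.loci:
        raise ValueError("empty reference annotation")
    pred_ts = list(pred.transcripts())
    ref_ts = list(ref.transcripts())

    ref_matched = [False] * len(ref_ts)
    tp = 0
    for p in pred_ts:
        found = False
        for i, r in enumerate(ref_ts):
            if _chains_match(p, r, terminal_tolerance):
                found = True
                ref_matched[i] = True
        if found:
            tp += 1
    fp = len(pred_ts) - tp
    fn = ref_matched.count(False)

    pred_spans = {(t.seq_id, t.start, t.end, t.strand) for t in pred_ts}
    ref_spans = {(t.seq_id, t.start, t.end, t.strand) for t in ref_ts}
    missed = _count_no_overlap(ref_spans, pred_spans)
    novel = _count_no_overlap(pred_spans, ref_spans)
    return _report("transcript", tp, fp, fn, missed, novel)


def evaluate_both_levels(
    pred: PredictionSet, ref: PredictionSet, terminal_tolerance: int = 0
) -> list[AccuracyReport]:
    return [exon_level(pred, ref),
            transcript_level(pred, ref, terminal_tolerance)]


def write_report(reports: list[AccuracyReport], path) -> None:
    """Write the accuracy reports as a TSV table."""
    header = "level\ttp\tfp\tfn\tsensitivity\tspecificity\tf_measure\tmissed\tnovel"
    lines = [header] + ["\t".join(str(x) for x in r.row()) for r in reports]
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
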