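"""Core annotation model: intervals, exons, transcripts, gene loci.

All coordinates are held internally as 0-based half-open ``[start, end)``;
the GTF readers/writers in :mod:`genemerge.io` convert from/to the 1-based
inclusive convention at the file boundary, so length arithmetic in the rest
of the package is always ``end - start``.

A *gene* here is a locus on the genome; in eukaryotes it may carry several
transcripts (alternative isoforms). The transcribed parts are *exons*; CDS
and UTR sub-features are deliberately out of scope — gene finders disagree
too much on whether they report them, so the consensus engine works on the
exon structure only.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

logger = logging.getLogger("genemerge")

STRANDS = ("+", "-", ".")


class ModelError(ValueError):
    """Raised when an annotation object violates its structural invariants."""


class Strategy(str, enum.Enum):
    """Prediction strategy category a gene finder belongs to."""

    AB_INITIO = "ab_initio"
    EVIDENCE = "evidence"


class SupportClass(str, enum.Enum):
    """Reliability class of a consensus record.

    PERFECT          every exon boundary-identical in another method
    SUPPORTED        every exon matched within the overlap threshold
    PARTIAL_ACCEPTED only a threshold-satisfying subset of exons matched
    NOVEL_EVIDENCE   absent ab initio but concordant in >=2 evidence methods
    UNSUPPORTED      no sufficient cross-strategy support
    """

    PERFECT = "PERFECT"
    SUPPORTED = "SUPPORTED"
    PARTIAL_ACCEPTED = "PARTIAL_ACCEPTED"
    NOVEL_EVIDENCE = "NOVEL_EVIDENCE"
    UNSUPPORTED = "UNSUPPORTED"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one strand of one sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ModelError("seq_id must be non-empty")
        if self.start >= self.end:
            raise ModelError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ModelError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared nucleotide positions (0 if different sequences)."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Exon:
    """One exon, with its 1-based ordinal within the transcript (5'→3' in
    genomic coordinate order)."""

    interval: GenomicInterval
    index_in_transcript: int = 1

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Transcript:
    """An ordered, disjoint exon chain on one strand of one sequence."""

    transcript_id: str
    gene_id: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError(f"transcript {self.transcript_id!r} has no exons")
        seqs = {e.interval.seq_id for e in self.exons}
        if len(seqs) != 1:
            raise ModelError(
                f"transcript {self.transcript_id!r} spans sequences {sorted(seqs)}"
            )
        strands = {e.interval.strand for e in self.exons}
        if len(strands) != 1:
            raise ModelError(
                f"transcript {self.transcript_id!r} mixes strands {sorted(strands)}"
            )
        prev = None
        for e in self.exons:
            if prev is not None and e.start < prev.end:
                raise ModelError(
                    f"transcript {self.transcript_id!r} exons overlap or are "
                    f"unsorted at [{e.start}, {e.end})"
                )
            prev = e

    @property
    def seq_id(self) -> str:
        return self.exons[0].interval.seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end, self.strand)

    def exon_boundaries(self) -> tuple[tuple[int, int], ...]:
        """The exon chain as a tuple of (start, end) pairs."""
        return tuple((e.start, e.end) for e in self.exons)


def make_transcript(
    transcript_id: str,
    gene_id: str,
    seq_id: str,
    strand: str,
    exons: list[tuple[int, int]],
    merge_touching: bool = True,
) -> Transcript:
    """Build a transcript from raw (start, end) pairs.

    Exons are sorted by start; exons that touch or overlap are merged with a
    warning (the consensus engine assumes disjoint exon chains, and some gene
    finders emit fragmented or duplicated exon rows).
    """
    if not exons:
        raise ModelError(f"transcript {transcript_id!r} has no exons")
    pairs = sorted(exons)
    merged: list[list[int]] = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            if not merge_touching:
                raise ModelError(
                    f"transcript {transcript_id!r} has overlapping exons"
                )
            logger.warning(
                "transcript %s: merging touching/overlapping exons [%d,%d) and [%d,%d)",
                transcript_id, merged[-1][0], merged[-1][1], s, e,
            )
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    built = tuple(
        Exon(GenomicInterval(seq_id, s, e, strand), index_in_transcript=i + 1)
        for i, (s, e) in enumerate(merged)
    )
    return Transcript(transcript_id=transcript_id, gene_id=gene_id, exons=built)


@dataclass(frozen=True)
class GeneLocus:
    """A gene: one locus with >=1 transcripts, plus the hull of their exons."""

    gene_id: str
    transcripts: tuple[Transcript, ...]
    span: GenomicInterval = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelError(f"locus {self.gene_id!r} has no transcripts")
        hull = locus_hull(list(self.transcripts))
        if self.span is None:
            object.__setattr__(self, "span", hull)
        elif not (
            self.span.seq_id == hull.seq_id
            and self.span.start <= hull.start
            and self.span.end >= hull.end
        ):
            raise ModelError(f"locus {self.gene_id!r} span does not cover its exons")


@dataclass
class PredictionSet:
    """All gene loci predicted by one method, tagged with its strategy."""

    method_name: str
    loci: list[GeneLocus]
    strategy: Strategy | None = None

    def __post_init__(self) -> None:
        if self.strategy is not None:
            self.strategy = Strategy(self.strategy)
        ids = [l.gene_id for l in self.loci]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ModelError(
                f"prediction set {self.method_name!r} has duplicate gene_ids: {dup[:5]}"
            )

    def transcripts(self):
        for locus in self.loci:
            yield from locus.transcripts

    @property
    def n_transcripts(self) -> int:
        return sum(len(l.transcripts) for l in self.loci)

    def tagged(self, strategy: Strategy | str) -> "PredictionSet":
        return PredictionSet(self.method_name, self.loci, Strategy(strategy))


def exonic_length(t: Transcript) -> int:
    """Transcript length as the sum of its exon lengths, in nucleotides.

    This is the length the supporting-overlap threshold is a fraction of.
    """
    return sum(len(e) for e in t.exons)


def locus_hull(transcripts: list[Transcript]) -> GenomicInterval:
    """Smallest interval covering every exon of every transcript."""
    if not transcripts:
        raise ModelError("locus_hull of empty transcript list")
    seqs = {t.seq_id for t in transcripts}
    if len(seqs) != 1:
        raise ModelError(f"locus_hull across sequences {sorted(seqs)}")
    strands = {t.strand for t in transcripts}
    strand = strands.pop() if len(strands) == 1 else "."
    start = min(e.start for t in transcripts for e in t.exons)
    end = max(e.end for t in transcripts for e in t.exons)
    return GenomicInterval(transcripts[0].seq_id, start, end, strand)


def loci_from_transcripts(transcripts: list[Transcript]) -> list[GeneLocus]:
    """Group transcripts into loci by gene_id, sorted by genomic position."""
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    loci = []
    for gene_id, ts in by_gene.items():
        ts_sorted = tuple(sorted(ts, key=lambda t: (t.start, t.end, t.transcript_id)))
        loci.append(GeneLocus(gene_id=gene_id, transcripts=ts_sorted))
    loci.sort(key=lambda l: (l.span.seq_id, l.span.start, l.span.end, l.gene_id))
    return loci
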