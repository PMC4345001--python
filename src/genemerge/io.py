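"""Readers and writers for the annotation formats the consensus engine speaks.

Natively the package reads and writes GTF in the Cufflinks/Cuffcompare
dialect: 9 tab-separated columns, exon feature rows carrying
``gene_id "…"; transcript_id "…";`` attributes, 1-based inclusive
coordinates. Converters are provided for the AUGUSTUS GFF flavour and the
Glimmer3 ``.predict`` format so those gene finders' raw output can join a
merge without preprocessing.

Per-line parsing of GTF/GFF columns and attributes is delegated to
``gffutils``; grouping into transcripts and loci, coordinate conversion and
line-numbered error reporting happen here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

from .model import (
    GeneLocus,
    ModelError,
    PredictionSet,
    SupportClass,
    Transcript,
    loci_from_transcripts,
    make_transcript,
)

logger = logging.getLogger("genemerge")


class ParseError(ValueError):
    """A malformed input line, reported with file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# GTF (Cufflinks dialect)
# ---------------------------------------------------------------------------

def _iter_feature_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    path, lineno, f"expected 9 tab-separated columns, got {len(cols)}"
                )
            yield lineno, line, cols


def parse_gtf(path, method_name: str | None = None) -> PredictionSet:
    """Read a Cufflinks-dialect GTF file into a :class:`PredictionSet`.

    Exon feature rows are grouped into transcripts by their ``transcript_id``
    attribute and into loci by ``gene_id``; all other feature types are
    ignored (debug-logged). Coordinates are converted from GTF's 1-based
    inclusive convention to the internal 0-based half-open one. The strategy
    tag is left unset; the caller assigns it.
    """
    path = Path(path)
    # transcript key -> (gene_id, seq_id, strand, [(start, end), ...])
    chains: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    for lineno, line, cols in _iter_feature_lines(path):
        if cols[2] != "exon":
            logger.debug("%s:%d: ignoring %s feature", path, lineno, cols[2])
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise ParseError(path, lineno, f"unparseable GTF line ({exc})") from exc
        try:
            gene_id = feat.attributes["gene_id"][0]
            transcript_id = feat.attributes["transcript_id"][0]
        except (KeyError, IndexError):
            raise ParseError(
                path, lineno, "exon line lacks gene_id/transcript_id attribute"
            ) from None
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if end <= start:
            raise ParseError(path, lineno, f"end < start ({feat.start} > {feat.end})")
        entry = chains.setdefault(
            transcript_id, (gene_id, feat.seqid, feat.strand or ".", [])
        )
        if entry[0] != gene_id:
            raise ParseError(
                path, lineno,
                f"transcript {transcript_id!r} assigned to two genes "
                f"({entry[0]!r} and {gene_id!r})",
            )
        entry[3].append((start, end))

    transcripts = [
        make_transcript(tid, gene_id, seq_id, strand, pairs)
        for tid, (gene_id, seq_id, strand, pairs) in chains.items()
    ]
    return PredictionSet(
        method_name=method_name or path.stem,
        loci=loci_from_transcripts(transcripts),
    )


def _gtf_exon_line(
    t: Transcript, exon, source: str, extra_attrs: str = "", score: str = "."
) -> str:
    attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";{extra_attrs}'
    return "\t".join(
        [
            t.seq_id,
            source,
            "exon",
            str(exon.start + 1),  # half-open -> 1-based inclusive
            str(exon.end),
            score,
            t.strand,
            ".",
            attrs,
        ]
    )


def _sorted_transcripts(transcripts: Iterable[Transcript]) -> list[Transcript]:
    return sorted(transcripts, key=lambda t: (t.seq_id, t.start, t.end, t.transcript_id))


def write_gtf(data, path, source: str = "genemerge") -> None:
    """Write a :class:`PredictionSet` or a list of merged records as GTF.

    One exon line per exon, ordered by (seq_id, start, transcript_id) so
    output is deterministic. Merged records additionally carry a
    ``support_class`` attribute and their numeric score in the score column.
    """
    from .merge import MergedRecord  # local import: io must not depend on merge at import time

    path = Path(path)
    lines = ["#gtf produced by genemerge"]
    if isinstance(data, PredictionSet):
        for t in _sorted_transcripts(data.transcripts()):
            for exon in t.exons:
                lines.append(_gtf_exon_line(t, exon, source=data.method_name or source))
    else:
        records: Sequence[MergedRecord] = sorted(
            data, key=lambda r: (r.transcript.seq_id, r.transcript.start,
                                 r.transcript.end, r.merged_id)
        )
        for rec in records:
            extra = f' support_class "{rec.support_class.value}";'
            score = format(rec.score, "g")
            for exon in rec.transcript.exons:
                lines.append(
                    _gtf_exon_line(rec.transcript, exon, source=source,
                                   extra_attrs=extra, score=score)
                )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tracking file
# ---------------------------------------------------------------------------

class TrackingRecord:
    """Provenance of one merged record: which original predictions made it.

    Serialized as a tab-separated row: merged_id, support class, then one
    ``method|gene_id|transcript_id`` token per source prediction.
    """

    __slots__ = ("merged_id", "support_class", "sources")

    def __init__(self, merged_id: str, support_class: SupportClass,
                 sources: list[tuple[str, str, str]]):
        if not sources:
            raise ModelError(f"tracking record {merged_id!r} has no sources")
        self.merged_id = merged_id
        self.support_class = SupportClass(support_class)
        self.sources = list(sources)

    def __eq__(self, other):
        return (self.merged_id, self.support_class, self.sources) == (
            other.merged_id, other.support_class, other.sources)

    def __repr__(self):
        return (f"TrackingRecord({self.merged_id!r}, {self.support_class.value}, "
                f"{len(self.sources)} sources)")


def write_tracking(records: Sequence[TrackingRecord], path) -> None:
    """Write the tracking TSV mapping each merged id to its source predictions."""
    seen = set()
    lines = []
    for rec in records:
        if rec.merged_id in seen:
            raise ModelError(f"duplicate merged_id in tracking: {rec.merged_id!r}")
        seen.add(rec.merged_id)
        tokens = "\t".join(f"{m}|{g}|{t}" for m, g, t in rec.sources)
        lines.append(f"{rec.merged_id}\t{rec.support_class.value}\t{tokens}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def parse_tracking(path) -> list[TrackingRecord]:
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw:
            continue
        cols = raw.split("\t")
        if len(cols) < 3:
            raise ParseError(path, lineno, "tracking row needs >=3 columns")
        sources = []
        for token in cols[2:]:
            parts = token.split("|")
            if len(parts) != 3:
                raise ParseError(path, lineno, f"bad source token {token!r}")
            sources.append((parts[0], parts[1], parts[2]))
        records.append(TrackingRecord(cols[0], SupportClass(cols[1]), sources))
    return records


# ---------------------------------------------------------------------------
# Glimmer3 .predict converter
# ---------------------------------------------------------------------------

def convert_glimmer3(path, method_name: str | None = None) -> PredictionSet:
    """Convert Glimmer3 ``.predict`` output to a prediction set.

    The format is one ``>seqid`` header per sequence followed by rows
    ``orfID  start  end  frame  score``. Each ORF becomes a single-exon,
    single-transcript locus. Strand follows the frame's sign: a negative
    frame means the minus strand, with printed start/end swapped so that the
    stored interval always has start < end. Glimmer3 coordinates are 1-based
    inclusive.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    seq_id: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            seq_id = line[1:].split()[0]
            continue
        if seq_id is None:
            raise ParseError(path, lineno, "ORF row before any >seqid header")
        cols = line.split()
        if len(cols) < 4:
            raise ParseError(path, lineno, "expected: orfID start end frame [score]")
        orf_id = cols[0]
        try:
            start_1, end_1 = int(cols[1]), int(cols[2])
            frame = int(cols[3].replace("+", ""))
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric coordinates/frame in {line!r}") from None
        strand = "-" if frame < 0 else "+"
        lo, hi = min(start_1, end_1), max(start_1, end_1)
        transcripts.append(
            make_transcript(orf_id, orf_id, seq_id, strand, [(lo - 1, hi)])
        )
    return PredictionSet(
        method_name=method_name or path.stem,
        loci=loci_from_transcripts(transcripts),
    )


# ---------------------------------------------------------------------------
# AUGUSTUS GFF converter
# ---------------------------------------------------------------------------

def convert_augustus_gff(path, method_name: str | None = None) -> PredictionSet:
    """Convert AUGUSTUS GFF output to a prediction set.

    Exon rows are grouped per transcript; when a transcript has no exon rows
    at all, its CDS rows stand in (AUGUSTUS emits CDS-only transcripts in
    some configurations — logged). Transcript/gene identity is taken from
    GTF-style ``transcript_id``/``gene_id`` attributes where present, else
    from AUGUSTUS's ``g1.t1`` dotted naming in the attribute column.
    """
    path = Path(path)
    exon_rows: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    cds_rows: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    declared: set[str] = set()
    for lineno, line, cols in _iter_feature_lines(path):
        ftype = cols[2]
        if ftype in ("transcript", "mRNA"):
            try:
                tid, _ = _augustus_ids(feature_from_line(line), cols[8])
            except Exception:
                tid = None
            if tid:
                declared.add(tid)
            continue
        if ftype not in ("exon", "CDS"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise ParseError(path, lineno, f"unparseable GFF line ({exc})") from exc
        tid, gid = _augustus_ids(feat, cols[8])
        if tid is None:
            raise ParseError(path, lineno, "cannot determine transcript id")
        target = exon_rows if ftype == "exon" else cds_rows
        entry = target.setdefault(tid, (gid, feat.seqid, feat.strand or ".", []))
        entry[3].append((feat.start - 1, feat.end))

    transcripts = []
    for tid in list(exon_rows) + [t for t in cds_rows if t not in exon_rows]:
        if tid in exon_rows:
            gid, seq, strand, pairs = exon_rows[tid]
        else:
            gid, seq, strand, pairs = cds_rows[tid]
            logger.warning(
                "transcript %s has no exon rows; using its CDS rows as exons", tid
            )
        transcripts.append(make_transcript(tid, gid, seq, strand, pairs))
    for tid in sorted(declared - set(exon_rows) - set(cds_rows)):
        logger.warning("transcript %s has no exon or CDS rows; skipped", tid)
    return PredictionSet(
        method_name=method_name or path.stem,
        loci=loci_from_transcripts(transcripts),
    )


def _augustus_ids(feat, raw_attrs: str) -> tuple[str | None, str]:
    """Pull (transcript_id, gene_id) out of an AUGUSTUS feature row."""
    attrs = feat.attributes
    tid = attrs["transcript_id"][0] if "transcript_id" in attrs else None
    gid = attrs["gene_id"][0] if "gene_id" in attrs else None
    if tid is None:
        # AUGUSTUS native GFF puts e.g. "g1.t1" or 'Parent=g1.t1' in column 9
        token = raw_attrs.strip().rstrip(";")
        if token.startswith("Parent="):
            token = token.split("Parent=")[1].split(";")[0]
        token = token.strip().strip('"')
        if token and "\t" not in token and " " not in token:
            tid = token
    if tid is None:
        return None, gid or ""
    if gid is None:
        gid = tid.rsplit(".", 1)[0] if "." in tid else tid
    return tid, gid
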