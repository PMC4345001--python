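"""Strategy-aware consensus of ab initio and evidence-based gene predictions.

The engine iterates over the ab initio ("leading") predictions and asks, for
each, whether any evidence-based method supports it. Support is an exonic
overlap question: the default acceptance rule is that a supporting overlap
must cover *more than* a threshold t (default 0.8) of the leading
prediction's exonic length — the sum of its exon lengths, not its genomic
span. Requiring a perfect overlap instead (t = 1.0) is a configuration away;
partial overlaps are accepted by default because evidence-based methods
often predict only part of a gene, e.g. under low RNA-seq coverage.

Prokaryotic mode works at the locus level (single-exon genes); eukaryotic
mode compares *exon chains*: an overlapping exon only counts as support when
it sits inside a similar chain of neighbouring exons, because chain
differences indicate an alternative isoform rather than agreement. When only
part of a chain is matched, conflict resolution asks whether the overlapping
evidence transcripts agree better with each other than with the leading
transcript; if they do, the leading prediction is regarded as incorrect and
the concordant evidence structure replaces it. Otherwise the leading
transcript survives only if the matched-exon count k satisfies k >= floor(t*n)
on both sides of the comparison.

The engine is fully deterministic: no randomness, and outputs are ordered by
genomic coordinates.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io import TrackingRecord
from .model import (
    GeneLocus,
    ModelError,
    PredictionSet,
    Strategy,
    SupportClass,
    Transcript,
    exonic_length,
    loci_from_transcripts,
)

logger = logging.getLogger("genemerge")

DEFAULT_SCORE_MAP = {
    SupportClass.PERFECT: 1.0,
    SupportClass.SUPPORTED: 0.75,
    SupportClass.PARTIAL_ACCEPTED: 0.5,
    SupportClass.NOVEL_EVIDENCE: 0.5,
    SupportClass.UNSUPPORTED: 0.0,
}


class Mode(str, enum.Enum):
    PROKARYOTE = "prokaryote"
    EUKARYOTE = "eukaryote"


class StrandPolicy(str, enum.Enum):
    """How strand disagreement between compared transcripts is handled.

    require_match      strands must be identical to compare at all
    ignore_unstranded  '.' compares with either strand; '+' vs '-' never do
    ignore_all         strand is ignored entirely
    """

    REQUIRE_MATCH = "require_match"
    IGNORE_UNSTRANDED = "ignore_unstranded"
    IGNORE_ALL = "ignore_all"


@dataclass
class MergeConfig:
    """Thresholds and switches of the consensus engine.

    overlap_threshold is the fraction t of the leading prediction's exonic
    length that a supporting overlap must exceed (strict >); the same t
    drives the integer exon-count rule k >= floor(t*n) in eukaryotic mode.
    """

    overlap_threshold: float = 0.8
    mode: Mode = Mode.EUKARYOTE
    include_novel: bool = False
    min_evidence_for_novel: int = 2
    strand_policy: StrandPolicy = StrandPolicy.REQUIRE_MATCH
    score_map: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_MAP))

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        self.strand_policy = StrandPolicy(self.strand_policy)
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError(
                f"overlap_threshold must be in (0, 1], got {self.overlap_threshold}"
            )
        if self.min_evidence_for_novel < 2:
            raise ValueError("min_evidence_for_novel must be >= 2")


class ExonMatch(str, enum.Enum):
    EXACT = "EXACT"
    PARTIAL = "PARTIAL"
    UNMATCHED = "UNMATCHED"


@dataclass(frozen=True)
class ChainMatch:
    """Per-exon comparison of a leading exon chain against a candidate.

    n is the leading transcript's exon count, k the number of its exons
    matched (exactly or within tolerance) by order-consistent candidate
    exons.
    """

    n: int
    k: int
    per_exon: tuple[ExonMatch, ...]
    all_exact: bool
    all_matched: bool

    def __post_init__(self) -> None:
        assert 0 <= self.k <= self.n
        assert not self.all_exact or self.all_matched
        assert not self.all_matched or self.k == self.n


@dataclass(frozen=True)
class MergedRecord:
    """One accepted consensus transcript with its reliability class and
    provenance links back to the source predictions."""

    merged_id: str
    transcript: Transcript
    support_class: SupportClass
    score: float
    sources: tuple[tuple[str, str, str], ...]  # (method, gene_id, transcript_id)

    def __post_init__(self) -> None:
        if not self.sources:
            raise ModelError(f"merged record {self.merged_id} has no sources")
        methods = {m for m, _, _ in self.sources}
        if self.support_class != SupportClass.UNSUPPORTED and len(methods) < 2:
            raise ModelError(
                f"merged record {self.merged_id} ({self.support_class.value}) "
                f"must trace to >=2 methods"
            )


@dataclass
class MergeResult:
    records: list[MergedRecord]
    tracking: list[TrackingRecord]
    unsupported_ab_initio: PredictionSet
    unmatched_evidence: PredictionSet

    def __iter__(self):
        return iter(
            (self.records, self.tracking, self.unsupported_ab_initio,
             self.unmatched_evidence)
        )


# ---------------------------------------------------------------------------
# Overlap primitives
# ---------------------------------------------------------------------------

def strands_compatible(a: str, b: str, policy: StrandPolicy) -> bool:
    if policy == StrandPolicy.IGNORE_ALL:
        return True
    if a == b:
        return True
    if policy == StrandPolicy.IGNORE_UNSTRANDED:
        return a == "." or b == "."
    return False


def _exonic_intersection(a: Transcript, b: Transcript) -> int:
    """Nucleotides covered by exons of both transcripts (sorted sweep)."""
    total = 0
    i = j = 0
    ea, eb = a.exons, b.exons
    while i < len(ea) and j < len(eb):
        lo = max(ea[i].start, eb[j].start)
        hi = min(ea[i].end, eb[j].end)
        if lo < hi:
            total += hi - lo
        if ea[i].end <= eb[j].end:
            i += 1
        else:
            j += 1
    return total


def exonic_overlap_fraction(
    leading: Transcript, other: Transcript,
    policy: StrandPolicy = StrandPolicy.REQUIRE_MATCH,
) -> float:
    """Fraction of the *leading* transcript's exonic length covered by
    exons of ``other``.

    The denominator is always the leading (ab initio) side, so the fraction
    is asymmetric by design: it measures how much of the leading prediction
    the other one supports. Different sequences or incompatible strands give
    0.0 by contract.
    """
    if leading.seq_id != other.seq_id:
        return 0.0
    if not strands_compatible(leading.strand, other.strand, policy):
        return 0.0
    return _exonic_intersection(leading, other) / exonic_length(leading)


def accept_by_exon_count(k: int, n: int, t: float) -> bool:
    """The integer exon-count acceptance rule: k >= floor(t*n).

    The small epsilon keeps floating floor faithful to the exact product
    (e.g. 0.7*10 in binary floats is 6.999...; the rule means floor(7)=7).
    """
    return k >= math.floor(t * n + 1e-9)


# ---------------------------------------------------------------------------
# Exon-chain matching (eukaryotic mode)
# ---------------------------------------------------------------------------

def match_exon_chain(
    leading: Transcript, candidate: Transcript, cfg: MergeConfig
) -> ChainMatch:
    """Compare two exon chains, pairing exons by order-consistent overlap.

    Each leading exon pairs with at most one candidate exon and pairs never
    cross, so the pairing respects the 5'→3' order of both chains. Among all
    such order-consistent pairings the one matching the most leading exons
    wins (ties broken toward more boundary-exact pairs); this is computed
    exactly by dynamic programming over the two exon lists. A pair is EXACT
    when both boundaries coincide and PARTIAL when the overlap covers more
    than t of the *leading exon's* length (the global threshold reused per
    exon — one tolerance governs both the nucleotide and the chain test).

    all_matched requires every leading exon to be matched, i.e. the candidate
    chain supports the full chain of neighbouring exons; a chain with an
    unmatched internal exon is treated as evidence of a different isoform,
    not of agreement.
    """
    n = len(leading.exons)
    if (
        leading.seq_id != candidate.seq_id
        or not strands_compatible(leading.strand, candidate.strand, cfg.strand_policy)
    ):
        per = tuple(ExonMatch.UNMATCHED for _ in leading.exons)
        return ChainMatch(n=n, k=0, per_exon=per,
                          all_exact=False, all_matched=False)

    t = cfg.overlap_threshold
    lead, cand = leading.exons, candidate.exons
    m = len(cand)

    def pair_kind(le, ce) -> ExonMatch | None:
        ov = min(le.end, ce.end) - max(le.start, ce.start)
        if ov <= 0:
            return None
        if (ce.start, ce.end) == (le.start, le.end):
            return ExonMatch.EXACT
        if ov / len(le) > t:
            return ExonMatch.PARTIAL
        return None

    # dp[i][j] = best (k, n_exact) using lead[i:] vs cand[j:]
    dp = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    choice = [[0] * (m + 1) for _ in range(n + 1)]  # 0 skip lead, 1 skip cand, 2 pair
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            best, how = dp[i + 1][j], 0
            if dp[i][j + 1] > best:
                best, how = dp[i][j + 1], 1
            kind = pair_kind(lead[i], cand[j])
            if kind is not None:
                nxt = dp[i + 1][j + 1]
                paired = (nxt[0] + 1, nxt[1] + (1 if kind == ExonMatch.EXACT else 0))
                if paired > best:
                    best, how = paired, 2
            dp[i][j], choice[i][j] = best, how

    per: list[ExonMatch] = [ExonMatch.UNMATCHED] * n
    i = j = 0
    while i < n and j < m:
        how = choice[i][j]
        if how == 2:
            per[i] = pair_kind(lead[i], cand[j])
            i, j = i + 1, j + 1
        elif how == 1:
            j += 1
        else:
            i += 1

    k = dp[0][0][0]
    all_matched = k == n
    all_exact = all_matched and all(x == ExonMatch.EXACT for x in per)
    return ChainMatch(n=n, k=k, per_exon=tuple(per),
                      all_exact=all_exact, all_matched=all_matched)


def _both_sides_accept(leading: Transcript, cand: Transcript, cfg: MergeConfig) -> bool:
    """k >= floor(t*n) must hold for the leading chain *and* for the chosen
    overlapping prediction's own chain."""
    fwd = match_exon_chain(leading, cand, cfg)
    rev = match_exon_chain(cand, leading, cfg)
    t = cfg.overlap_threshold
    return (
        fwd.k > 0
        and accept_by_exon_count(fwd.k, fwd.n, t)
        and accept_by_exon_count(rev.k, rev.n, t)
    )


# ---------------------------------------------------------------------------
# Classification — prokaryotic (locus level)
# ---------------------------------------------------------------------------

def _boundary_identical(a: Transcript, b: Transcript) -> bool:
    return (
        a.seq_id == b.seq_id
        and a.exon_boundaries() == b.exon_boundaries()
    )


def classify_locus_prok(
    leading: Transcript,
    candidates: list[tuple[str, Transcript]],
    cfg: MergeConfig,
) -> tuple[SupportClass, list[tuple[str, Transcript]]]:
    """Classify a leading prokaryotic transcript against evidence candidates.

    PERFECT when some evidence prediction has identical exon boundaries;
    SUPPORTED when the best exonic overlap fraction strictly exceeds t;
    UNSUPPORTED otherwise — a fraction exactly equal to t does not support
    (the rule is "greater than" the threshold). Sources are all evidence
    transcripts above the bar, ties included.
    """
    perfect = [
        (m, c) for m, c in candidates
        if _boundary_identical(leading, c)
        and strands_compatible(leading.strand, c.strand, cfg.strand_policy)
    ]
    supporting = [
        (m, c) for m, c in candidates
        if exonic_overlap_fraction(leading, c, cfg.strand_policy)
        > cfg.overlap_threshold
    ]
    if perfect:
        # perfect matches are also supporting (fraction 1.0 > t for t < 1);
        # report every supporter above the bar plus the perfect ones
        srcs = perfect + [p for p in supporting if p not in perfect]
        return SupportClass.PERFECT, srcs
    if supporting:
        return SupportClass.SUPPORTED, supporting
    return SupportClass.UNSUPPORTED, []


# ---------------------------------------------------------------------------
# Classification — eukaryotic (exon-chain level)
# ---------------------------------------------------------------------------

@dataclass
class EukDecision:
    support_class: SupportClass
    emitted: list[Transcript]            # transcripts to emit (usually [leading])
    sources: list[tuple[str, Transcript]]
    replaced: bool = False               # evidence structure replaced the leading one


def resolve_conflict(
    leading: Transcript,
    overlapping: list[tuple[str, Transcript]],
    cfg: MergeConfig,
) -> tuple[str, list[tuple[str, Transcript]]]:
    """Decide a partial-support conflict between a leading transcript and the
    evidence transcripts overlapping it.

    Returns one of:
      ("replace", group)   — >=2 evidence methods agree with each other
                             (pairwise all_matched at the same t) while none
                             agrees with the leading chain; their concordant
                             structure supersedes it.
      ("keep", [(m, c)])   — the evidence disagrees among itself, but the
                             leading chain meets k>=floor(t*n) on both sides
                             against candidate c.
      ("undecided", [])    — neither holds; the leading transcript is left
                             unsupported.
    """
    if len(overlapping) < 2:
        raise ValueError("conflict resolution needs >=2 overlapping evidence transcripts")

    ordered = sorted(overlapping, key=lambda mc: (mc[0], mc[1].transcript_id))
    # Greedy concordant group: seed with each candidate in turn, extend with
    # any later candidate (from a new method) pairwise all_matched with every
    # member. Deterministic by the sort above.
    for seed_idx, (m0, c0) in enumerate(ordered):
        if match_exon_chain(leading, c0, cfg).all_matched:
            continue  # agrees with leading; not part of a counter-consensus
        group = [(m0, c0)]
        methods = {m0}
        for m1, c1 in ordered[seed_idx + 1:]:
            if m1 in methods:
                continue
            if match_exon_chain(leading, c1, cfg).all_matched:
                continue
            if all(
                match_exon_chain(cg, c1, cfg).all_matched
                and match_exon_chain(c1, cg, cfg).all_matched
                for _, cg in group
            ):
                group.append((m1, c1))
                methods.add(m1)
        if len(methods) >= 2:
            return "replace", group

    for m, c in ordered:
        if _both_sides_accept(leading, c, cfg):
            return "keep", [(m, c)]
    return "undecided", []


def classify_transcript_euk(
    leading: Transcript,
    candidates: list[tuple[str, Transcript]],
    cfg: MergeConfig,
) -> EukDecision:
    """Full eukaryotic support decision for one leading transcript.

    Order of tests: PERFECT (some candidate all_exact) > SUPPORTED (some
    candidate all_matched) > conflict resolution when >=2 evidence methods
    overlap > direct both-sides exon-count acceptance > UNSUPPORTED.
    """
    t = cfg.overlap_threshold
    matches = [(m, c, match_exon_chain(leading, c, cfg)) for m, c in candidates]

    exact = [(m, c) for m, c, cm in matches if cm.all_exact]
    if exact:
        matched = [(m, c) for m, c, cm in matches if cm.all_matched]
        return EukDecision(SupportClass.PERFECT, [leading], matched)

    matched = [(m, c) for m, c, cm in matches if cm.all_matched]
    if matched:
        return EukDecision(SupportClass.SUPPORTED, [leading], matched)

    overlapping = [
        (m, c) for m, c, cm in matches
        if cm.k > 0 or leading.span.overlap_len(c.span) > 0
    ]
    distinct_methods = {m for m, _ in overlapping}
    if len(overlapping) >= 2 and len(distinct_methods) >= 2:
        verdict, chosen = resolve_conflict(leading, overlapping, cfg)
        if verdict == "replace":
            return EukDecision(
                SupportClass.SUPPORTED,
                [c for _, c in chosen],
                chosen,
                replaced=True,
            )
        if verdict == "keep":
            return EukDecision(SupportClass.PARTIAL_ACCEPTED, [leading], chosen)
        return EukDecision(SupportClass.UNSUPPORTED, [leading], [])

    # 0 or 1 overlapping evidence transcripts: apply the both-sides
    # exon-count rule directly.
    for m, c in overlapping:
        if _both_sides_accept(leading, c, cfg):
            return EukDecision(SupportClass.PARTIAL_ACCEPTED, [leading], [(m, c)])
    return EukDecision(SupportClass.UNSUPPORTED, [leading], [])


# ---------------------------------------------------------------------------
# Novel (evidence-only) genes
# ---------------------------------------------------------------------------

def _supports(leading: Transcript, cand: Transcript, cfg: MergeConfig) -> bool:
    """Mode-appropriate 'cand supports leading' test."""
    if cfg.mode == Mode.PROKARYOTE:
        return (
            exonic_overlap_fraction(leading, cand, cfg.strand_policy)
            > cfg.overlap_threshold
        )
    cm = match_exon_chain(leading, cand, cfg)
    return cm.all_matched or _both_sides_accept(leading, cand, cfg)


def find_novel(
    evidence_sets: list[PredictionSet],
    ab_initio_sets: list[PredictionSet],
    cfg: MergeConfig,
) -> list[tuple[Transcript, list[tuple[str, Transcript]]]]:
    """Genes absent from every ab initio output but concordantly predicted by
    at least ``min_evidence_for_novel`` evidence methods.

    Returns (representative transcript, supporting (method, transcript)
    pairs including the representative). A transcript counts as ab initio
    covered — hence not novel — when some ab initio prediction overlaps more
    than t of it; those are the main pass's business. Mutually supporting
    evidence transcripts are collapsed so each novel gene is reported once.
    """
    if len(evidence_sets) < 2:
        raise ValueError(
            "novel-gene detection needs at least two evidence-based prediction outputs"
        )
    ab_index = _TranscriptIndex(
        [(s.method_name, t) for s in ab_initio_sets for t in s.transcripts()]
    )
    ev_pairs = [(s.method_name, t) for s in evidence_sets for t in s.transcripts()]
    ev_pairs.sort(key=lambda mt: (mt[1].seq_id, mt[1].start, mt[1].end,
                                  mt[0], mt[1].transcript_id))
    ev_index = _TranscriptIndex(ev_pairs)

    consumed: set[tuple[str, str]] = set()
    out = []
    for method, t in ev_pairs:
        if (method, t.transcript_id) in consumed:
            continue
        if any(
            exonic_overlap_fraction(t, ab, cfg.strand_policy) > cfg.overlap_threshold
            for _, ab in ab_index.overlapping(t)
        ):
            continue
        supporters = [
            (m2, c) for m2, c in ev_index.overlapping(t)
            if m2 != method and _supports(t, c, cfg)
        ]
        methods = {method} | {m for m, _ in supporters}
        if len(methods) < cfg.min_evidence_for_novel:
            continue
        sources = [(method, t)] + supporters
        out.append((t, sources))
        for m2, c in sources:
            # mutual supporters describe the same gene; report it once
            if _supports(c, t, cfg) or _supports(t, c, cfg):
                consumed.add((m2, c.transcript_id))
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class _TranscriptIndex:
    """Interval index of (method, transcript) pairs keyed by seq_id span."""

    def __init__(self, pairs: list[tuple[str, Transcript]]):
        self._trees: dict[str, IntervalTree] = {}
        for m, t in pairs:
            self._trees.setdefault(t.seq_id, IntervalTree()).addi(
                t.start, t.end, (m, t)
            )

    def overlapping(self, t: Transcript) -> list[tuple[str, Transcript]]:
        tree = self._trees.get(t.seq_id)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(t.start, t.end)]
        hits.sort(key=lambda mt: (mt[1].start, mt[1].end, mt[0], mt[1].transcript_id))
        return hits


def merge(
    ab_initio_sets: list[PredictionSet],
    evidence_sets: list[PredictionSet],
    cfg: MergeConfig | None = None,
) -> MergeResult:
    """Run the full consensus: classify every leading (ab initio) transcript,
    resolve conflicts, optionally append evidence-only novel genes.

    Accepted transcripts become merged records (with tracking provenance);
    unsupported leading transcripts and evidence transcripts that supported
    nothing are returned as side prediction sets so single-strategy genes
    remain available for downstream analysis.
    """
    cfg = cfg or MergeConfig()
    if not evidence_sets or (not ab_initio_sets and not cfg.include_novel):
        if not ab_initio_sets and not evidence_sets:
            raise ValueError("no prediction sets given")
        if not evidence_sets:
            raise ValueError(
                "all inputs are tagged ab_initio; combining ab initio with ab "
                "initio methods is not supported — tag at least one input as "
                "evidence based"
            )
    for s in ab_initio_sets:
        if s.strategy != Strategy.AB_INITIO:
            raise ValueError(f"set {s.method_name!r} not tagged ab_initio")
    for s in evidence_sets:
        if s.strategy != Strategy.EVIDENCE:
            raise ValueError(f"set {s.method_name!r} not tagged evidence")
    if not ab_initio_sets and not cfg.include_novel:
        raise ValueError("no ab initio input and novel-gene detection disabled")
    if not ab_initio_sets:
        logger.warning("no ab initio input; output will contain only novel genes")

    ev_pairs = [(s.method_name, t) for s in evidence_sets for t in s.transcripts()]
    ev_index = _TranscriptIndex(ev_pairs)

    # accepted structures keyed by exon structure for cross-set dedup
    accepted: dict[tuple, dict] = {}
    used_evidence: set[tuple[str, str]] = set()
    unsupported: list[Transcript] = []
    replacement_emitted: set[tuple[str, str]] = set()

    def _register(transcript: Transcript, support: SupportClass,
                  sources: list[tuple[str, str, str]]):
        key = (transcript.seq_id, transcript.strand, transcript.exon_boundaries())
        slot = accepted.get(key)
        rank = list(SupportClass).index(support)
        if slot is None:
            accepted[key] = {"transcript": transcript, "class": support,
                             "rank": rank, "sources": list(sources)}
        else:
            if rank < slot["rank"]:
                slot["class"], slot["rank"] = support, rank
            for s in sources:
                if s not in slot["sources"]:
                    slot["sources"].append(s)

    for ab_set in ab_initio_sets:
        if cfg.mode == Mode.PROKARYOTE:
            for locus in ab_set.loci:
                if len(locus.transcripts) > 1:
                    logger.warning(
                        "prokaryotic mode: locus %s has %d transcripts; "
                        "each is tested separately",
                        locus.gene_id, len(locus.transcripts),
                    )
        for leading in ab_set.transcripts():
            candidates = ev_index.overlapping(leading)
            if cfg.mode == Mode.PROKARYOTE:
                support, srcs = classify_locus_prok(leading, candidates, cfg)
                if support == SupportClass.UNSUPPORTED:
                    unsupported.append(leading)
                    continue
                sources = [(ab_set.method_name, leading.gene_id, leading.transcript_id)]
                sources += [(m, c.gene_id, c.transcript_id) for m, c in srcs]
                for m, c in srcs:
                    used_evidence.add((m, c.transcript_id))
                _register(leading, support, sources)
            else:
                decision = classify_transcript_euk(leading, candidates, cfg)
                if decision.support_class == SupportClass.UNSUPPORTED:
                    unsupported.append(leading)
                    continue
                for m, c in decision.sources:
                    used_evidence.add((m, c.transcript_id))
                if decision.replaced:
                    # evidence consensus supersedes the leading structure;
                    # emit the agreed structure once, never twice for two
                    # different leading transcripts
                    src_list = [(m, c.gene_id, c.transcript_id)
                                for m, c in decision.sources]
                    src_list.append((ab_set.method_name, leading.gene_id,
                                     leading.transcript_id))
                    rep_m, rep_t = decision.sources[0]
                    rep_key = (rep_m, rep_t.transcript_id)
                    if rep_key in replacement_emitted:
                        continue
                    replacement_emitted.add(rep_key)
                    _register(rep_t, decision.support_class, src_list)
                else:
                    sources = [(ab_set.method_name, leading.gene_id,
                                leading.transcript_id)]
                    sources += [(m, c.gene_id, c.transcript_id)
                                for m, c in decision.sources]
                    _register(leading, decision.support_class, sources)

    if cfg.include_novel:
        for t, srcs in find_novel(evidence_sets, ab_initio_sets, cfg):
            for m, c in srcs:
                used_evidence.add((m, c.transcript_id))
            _register(t, SupportClass.NOVEL_EVIDENCE,
                      [(m, c.gene_id, c.transcript_id) for m, c in srcs])

    # deterministic output order and ids
    slots = sorted(
        accepted.values(),
        key=lambda s: (s["transcript"].seq_id, s["transcript"].start,
                       s["transcript"].end, s["transcript"].transcript_id),
    )
    records, tracking = [], []
    for i, slot in enumerate(slots, start=1):
        mid = f"GM{i:06d}"
        t: Transcript = slot["transcript"]
        rec = MergedRecord(
            merged_id=mid,
            transcript=Transcript(
                transcript_id=mid, gene_id=f"{mid}.gene", exons=t.exons
            ),
            support_class=slot["class"],
            score=cfg.score_map[slot["class"]],
            sources=tuple(slot["sources"]),
        )
        records.append(rec)
        tracking.append(TrackingRecord(mid, slot["class"], slot["sources"]))

    unmatched = [
        t for m, t in ev_pairs if (m, t.transcript_id) not in used_evidence
    ]
    unsupported_set = PredictionSet(
        method_name="unsupported_ab_initio",
        loci=loci_from_transcripts(_dedup_transcripts(unsupported)),
        strategy=Strategy.AB_INITIO,
    )
    unmatched_set = PredictionSet(
        method_name="unmatched_evidence",
        loci=loci_from_transcripts(_dedup_transcripts(unmatched)),
        strategy=Strategy.EVIDENCE,
    )
    return MergeResult(records, tracking, unsupported_set, unmatched_set)


def _dedup_transcripts(transcripts: list[Transcript]) -> list[Transcript]:
    """Drop duplicate (gene_id, transcript_id) pairs across input sets while
    keeping the first occurrence; rename clashes from different methods."""
    seen: dict[tuple[str, str], int] = {}
    out = []
    for t in transcripts:
        key = (t.gene_id, t.transcript_id)
        n = seen.get(key, 0)
        seen[key] = n + 1
        if n == 0:
            out.append(t)
        else:
            out.append(
                Transcript(
                    transcript_id=f"{t.transcript_id}.{n}",
                    gene_id=f"{t.gene_id}.{n}",
                    exons=t.exons,
                )
            )
    return out
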