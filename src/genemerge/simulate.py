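"""Seeded synthetic annotations and method-specific perturbed predictions.

The generator builds the study conditions the consensus engine is designed
for, without running any external gene finder: a ground-truth annotation
(prokaryote-style single-exon genes, or eukaryote-style multi-exon genes
with optional shared-exon isoforms), an "expressed" subset (by default 70%
of genes, emulating that not all genes are transcribed at once — the
expressed subset is the ground truth against which evidence-derived
predictions are judged), and per-method predictions derived from the truth
by an error profile: dropped genes, boundary jitter, dropped exons (partial
transcripts, as evidence-based methods produce under low coverage),
terminal extensions (the incorrect first/last exon that ab-initio-leaning
hybrid finders tend to add), and method-unique false-positive genes placed
in intergenic space.

False positives are the load-bearing part: each method draws its spurious
genes from its own pool of intergenic gaps (with a safety margin, default
50 nt), so the FP sets of two methods never overlap each other or any true
gene. That makes the engine's filtering behaviour exact — a method-unique
FP can never find cross-method support — rather than statistical.

Everything is deterministic given the root seed, which is fanned out to one
child stream per method via ``numpy``'s SeedSequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    GeneLocus,
    PredictionSet,
    Strategy,
    Transcript,
    loci_from_transcripts,
    make_transcript,
)

DEFAULT_EXPRESSED_FRACTION = 0.7


@dataclass
class ErrorProfile:
    """Error modes of one simulated gene finder."""

    method_name: str
    strategy: Strategy
    drop_rate: float = 0.0          # fraction of genes missed entirely
    fp_rate: float = 0.0            # spurious genes per true gene, intergenic
    boundary_jitter_sd: float = 0.0  # nt, gaussian shift of exon boundaries
    exon_drop_rate: float = 0.0     # euk: per-exon drop prob (partial transcripts)
    terminal_extension: int = 0     # nt added beyond the true 5'/3' ends

    def __post_init__(self):
        self.strategy = Strategy(self.strategy)
        for name in ("drop_rate", "fp_rate", "exon_drop_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    mode: str = "prokaryote"        # or "eukaryote"
    genome_length: int = 2_000_000
    expressed_fraction: float = DEFAULT_EXPRESSED_FRACTION
    seq_id: str = "chr_sim"
    # prokaryote gene lengths; eukaryote exon/intron lengths (uniform draws)
    prok_gene_length: tuple[int, int] = (300, 3000)
    exon_length: tuple[int, int] = (50, 400)
    intron_length: tuple[int, int] = (50, 2000)
    exons_per_gene: tuple[int, int] = (2, 8)
    isoforms_per_gene: tuple[int, int] = (1, 2)
    min_intergenic_gap: int = 200
    fp_margin: int = 50
    profiles: list[ErrorProfile] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 < self.expressed_fraction <= 1.0):
            raise ValueError("expressed_fraction must be in (0, 1]")
        if self.mode not in ("prokaryote", "eukaryote"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _rng(seed, *branch: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *branch]))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _draw_gene_structure(cfg: SimulationConfig, rng) -> list[tuple[int, int]]:
    """Exon layout of one gene, relative to gene start (offset 0)."""
    if cfg.mode == "prokaryote":
        length = int(rng.integers(cfg.prok_gene_length[0], cfg.prok_gene_length[1] + 1))
        return [(0, length)]
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    pos = 0
    exons = []
    for i in range(n_exons):
        if i > 0:
            pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        exons.append((pos, pos + length))
        pos += length
    return exons


def generate_truth(cfg: SimulationConfig) -> PredictionSet:
    """Deterministic ground-truth annotation: non-overlapping gene loci laid
    along the genome with seeded structures, strands and gaps.

    In eukaryote mode a locus may carry a second isoform sharing a prefix of
    the exon chain but skipping one internal exon, the classic
    alternative-splicing pattern exon-chain comparison has to respect.
    """
    rng = _rng(cfg.seed, 0)
    structures = [_draw_gene_structure(cfg, rng) for _ in range(cfg.n_genes)]
    widths = [s[-1][1] for s in structures]
    needed = sum(widths) + (cfg.n_genes + 1) * cfg.min_intergenic_gap
    if needed > cfg.genome_length:
        raise ValueError(
            f"n_genes={cfg.n_genes} needs ~{needed} nt but genome_length is "
            f"{cfg.genome_length}; enlarge the genome or reduce n_genes"
        )
    # distribute the leftover space over the n_genes+1 gaps
    slack = cfg.genome_length - needed
    weights = rng.dirichlet(np.ones(cfg.n_genes + 1)) if slack > 0 else None
    extra = (np.floor(weights * slack).astype(int)
             if weights is not None else np.zeros(cfg.n_genes + 1, dtype=int))

    transcripts: list[Transcript] = []
    pos = 0
    for i, struct in enumerate(structures):
        pos += cfg.min_intergenic_gap + int(extra[i])
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{i + 1:05d}"
        exons = [(pos + s, pos + e) for s, e in struct]
        transcripts.append(
            make_transcript(f"{gene_id}.t1", gene_id, cfg.seq_id, strand, exons)
        )
        if (
            cfg.mode == "eukaryote"
            and len(exons) >= 3
            and cfg.isoforms_per_gene[1] >= 2
            and rng.random() < 0.5
        ):
            skip = int(rng.integers(1, len(exons) - 1))  # internal exon index
            iso = [e for j, e in enumerate(exons) if j != skip]
            transcripts.append(
                make_transcript(f"{gene_id}.t2", gene_id, cfg.seq_id, strand, iso)
            )
        pos = exons[-1][1]
    return PredictionSet(method_name="truth", loci=loci_from_transcripts(transcripts))


def sample_expressed(
    truth: PredictionSet, fraction: float, seed: int
) -> PredictionSet:
    """Seeded choice of exactly round(fraction*n) genes: the expressed subset
    that evidence generation sees, and the evaluation ground truth."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return PredictionSet("truth_expressed", list(truth.loci))
    rng = _rng(seed, 1)
    n_keep = round(fraction * len(truth.loci))
    keep_idx = set(rng.choice(len(truth.loci), size=n_keep, replace=False).tolist())
    loci = [l for i, l in enumerate(truth.loci) if i in keep_idx]
    return PredictionSet(method_name="truth_expressed", loci=loci)


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------

def intergenic_gaps(
    loci: list[GeneLocus], genome_length: int, margin: int = 50
) -> list[tuple[int, int]]:
    """Free intervals between gene spans, shrunk by ``margin`` on each side."""
    spans = sorted((l.span.start, l.span.end) for l in loci)
    gaps = []
    prev = 0
    for s, e in spans + [(genome_length, genome_length)]:
        lo, hi = prev + margin, s - margin
        if hi - lo > 0:
            gaps.append((lo, hi))
        prev = max(prev, e)
    return gaps


def perturb(
    base: PredictionSet,
    profile: ErrorProfile,
    seed: int,
    genome_length: int | None = None,
    fp_gaps: list[tuple[int, int]] | None = None,
    cfg: SimulationConfig | None = None,
) -> tuple[PredictionSet, dict[str, str]]:
    """Derive one method's prediction set from a base annotation.

    Applies, in order: gene drop (exactly round(drop_rate*n) genes), boundary
    jitter, exon drop, terminal extension, then injects round(fp_rate*n)
    method-unique spurious genes into ``fp_gaps`` (all intergenic gaps of the
    base if not given). Returns the prediction set and a manifest mapping
    every output gene_id to its source truth gene_id, or ``"FP"``.
    """
    rng = _rng(seed, 2)
    cfg = cfg or SimulationConfig()
    n = len(base.loci)
    n_drop = round(profile.drop_rate * n)
    drop_idx = set(
        rng.choice(n, size=n_drop, replace=False).tolist()) if n_drop else set()

    manifest: dict[str, str] = {}
    transcripts: list[Transcript] = []
    for i, locus in enumerate(base.loci):
        if i in drop_idx:
            continue
        for t in locus.transcripts:
            new_t = _perturb_transcript(t, profile, rng, profile.method_name)
            transcripts.append(new_t)
        manifest[f"{profile.method_name}_{locus.gene_id}"] = locus.gene_id

    n_fp = round(profile.fp_rate * n)
    if n_fp:
        gaps = fp_gaps
        if gaps is None:
            if genome_length is None:
                raise ValueError("fp injection needs genome_length or fp_gaps")
            gaps = intergenic_gaps(base.loci, genome_length, cfg.fp_margin)
        fp_ts = _inject_false_positives(n_fp, gaps, profile, rng, cfg)
        for t in fp_ts:
            transcripts.append(t)
            manifest[t.gene_id] = "FP"

    out = PredictionSet(
        method_name=profile.method_name,
        loci=loci_from_transcripts(transcripts),
        strategy=profile.strategy,
    )
    return out, manifest


def _perturb_transcript(
    t: Transcript, profile: ErrorProfile, rng, method: str
) -> Transcript:
    pairs = [list(p) for p in t.exon_boundaries()]

    if profile.exon_drop_rate > 0 and len(pairs) > 1:
        kept = [p for p in pairs if rng.random() >= profile.exon_drop_rate]
        if not kept:
            kept = [pairs[int(rng.integers(len(pairs)))]]
        pairs = kept

    if profile.boundary_jitter_sd > 0:
        jittered = []
        prev_end = -(10 ** 12)
        for s, e in pairs:
            s2 = s + int(round(rng.normal(0.0, profile.boundary_jitter_sd)))
            e2 = e + int(round(rng.normal(0.0, profile.boundary_jitter_sd)))
            s2 = max(s2, prev_end + 1, 0)
            e2 = max(e2, s2 + 1)
            jittered.append([s2, e2])
            prev_end = e2
        pairs = jittered

    if profile.terminal_extension > 0:
        pairs[0][0] = max(0, pairs[0][0] - profile.terminal_extension)
        pairs[-1][1] = pairs[-1][1] + profile.terminal_extension

    gene_id = f"{method}_{t.gene_id}"
    return make_transcript(
        f"{method}_{t.transcript_id}", gene_id, t.seq_id, t.strand,
        [(s, e) for s, e in pairs],
    )


def _inject_false_positives(
    n_fp: int, gaps: list[tuple[int, int]], profile: ErrorProfile,
    rng, cfg: SimulationConfig,
) -> list[Transcript]:
    """Place spurious single-exon (prok) or short multi-exon (euk) genes in
    the given intergenic pool; one FP per gap, largest gaps first."""
    usable = sorted(gaps, key=lambda g: g[1] - g[0], reverse=True)
    out = []
    gi = 0
    for i in range(n_fp):
        placed = False
        while gi < len(usable):
            lo, hi = usable[gi]
            gi += 1
            width = hi - lo
            if cfg.mode == "prokaryote":
                min_len = cfg.prok_gene_length[0]
                if width < min_len:
                    continue
                length = int(rng.integers(min_len, min(cfg.prok_gene_length[1], width) + 1))
                start = lo + int(rng.integers(0, width - length + 1))
                exons = [(start, start + length)]
            else:
                elen = cfg.exon_length
                need = 2 * elen[0] + cfg.intron_length[0]
                if width < elen[0]:
                    continue
                if width >= need:
                    l1 = int(rng.integers(elen[0], min(elen[1], (width - cfg.intron_length[0]) // 2) + 1))
                    l2 = int(rng.integers(elen[0], min(elen[1], width - l1 - cfg.intron_length[0]) + 1))
                    intron_max = width - l1 - l2
                    intron = int(rng.integers(cfg.intron_length[0], intron_max + 1))
                    start = lo + int(rng.integers(0, width - (l1 + intron + l2) + 1))
                    exons = [(start, start + l1),
                             (start + l1 + intron, start + l1 + intron + l2)]
                else:
                    length = int(rng.integers(elen[0], min(elen[1], width) + 1))
                    start = lo + int(rng.integers(0, width - length + 1))
                    exons = [(start, start + length)]
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{profile.method_name}_fp{i + 1:04d}"
            out.append(make_transcript(f"{gid}.t1", gid,
                                       cfg.seq_id, strand, exons))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"no intergenic space left for false positive {i + 1}/{n_fp}; "
                f"lower fp_rate or enlarge the genome"
            )
    return out


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    truth: PredictionSet
    expressed: PredictionSet
    predictions: list[PredictionSet]
    manifests: dict[str, dict[str, str]]


def simulate_predictions(cfg: SimulationConfig) -> SimulationResult:
    """Generate the whole scenario: truth, expressed subset, and one
    perturbed prediction set per error profile.

    Ab initio profiles see the full truth (sequence-based finders do not know
    about expression); evidence profiles see only the expressed subset. The
    intergenic gaps of the truth are partitioned round-robin between the
    FP-injecting methods, which is what makes each method's false positives
    unique to it by construction.
    """
    if not cfg.profiles:
        raise ValueError("SimulationConfig.profiles is empty")
    truth = generate_truth(cfg)
    expressed = sample_expressed(truth, cfg.expressed_fraction, cfg.seed)

    all_gaps = intergenic_gaps(truth.loci, cfg.genome_length, cfg.fp_margin)
    fp_methods = [p.method_name for p in cfg.profiles if p.fp_rate > 0]
    pools: dict[str, list[tuple[int, int]]] = {m: [] for m in fp_methods}
    for i, gap in enumerate(all_gaps):
        if fp_methods:
            pools[fp_methods[i % len(fp_methods)]].append(gap)

    predictions, manifests = [], {}
    for idx, profile in enumerate(cfg.profiles):
        base = truth if profile.strategy == Strategy.AB_INITIO else expressed
        pred, manifest = perturb(
            base, profile,
            seed=cfg.seed + 10_000 + idx,
            fp_gaps=pools.get(profile.method_name, []),
            cfg=cfg,
        )
        predictions.append(pred)
        manifests[profile.method_name] = manifest
    return SimulationResult(truth, expressed, predictions, manifests)


def write_manifest(manifests: dict[str, dict[str, str]], path) -> None:
    Path(path).write_text(json.dumps(manifests, indent=1, sort_keys=True) + "\n")
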