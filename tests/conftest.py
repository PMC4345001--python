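"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation's own code paths: overlap
fractions come from explicit nucleotide position sets, chain matching from
exhaustive enumeration of every order-consistent exon pairing, and interval
properties from pairwise scans.
"""

from __future__ import annotations

import numpy as np
import pytest

from genemerge import (
    ErrorProfile,
    PredictionSet,
    SimulationConfig,
    Strategy,
    Transcript,
    loci_from_transcripts,
    make_transcript,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def positions(pairs) -> set[int]:
    """All nucleotide positions covered by a list of (start, end) pairs."""
    out: set[int] = set()
    for s, e in pairs:
        out.update(range(s, e))
    return out


def overlap_fraction_oracle(lead_pairs, cand_pairs) -> float:
    lead = positions(lead_pairs)
    return len(lead & positions(cand_pairs)) / len(lead)


def chain_match_oracle(lead_pairs, cand_pairs, t) -> tuple[int, int]:
    """(max matched leading exons, max exact pairs at that k) over every
    order-consistent pairing — exhaustive recursion, exponential but tiny."""

    def kind(le, ce):
        ov = min(le[1], ce[1]) - max(le[0], ce[0])
        if ov <= 0:
            return None
        if le == ce:
            return "EXACT"
        if ov / (le[1] - le[0]) > t:
            return "PARTIAL"
        return None

    best = (0, 0)

    def rec(i, j, k, exact):
        nonlocal best
        best = max(best, (k, exact))
        if i >= len(lead_pairs) or j >= len(cand_pairs):
            return
        rec(i + 1, j, k, exact)
        rec(i, j + 1, k, exact)
        kd = kind(lead_pairs[i], cand_pairs[j])
        if kd is not None:
            rec(i + 1, j + 1, k + 1, exact + (kd == "EXACT"))

    rec(0, 0, 0, 0)
    return best


def random_exon_pairs(rng, max_exons=4, max_len=30, max_gap=20, origin_jitter=40):
    """A random disjoint sorted exon list with small coordinates, so random
    transcripts overlap each other often."""
    n = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, origin_jitter))
    pairs = []
    for i in range(n):
        if i > 0:
            pos += int(rng.integers(1, max_gap + 1))
        length = int(rng.integers(1, max_len + 1))
        pairs.append((pos, pos + length))
        pos += length
    return pairs


def tx(exons, tid="t1", gid="g1", seq="chr1", strand="+") -> Transcript:
    return make_transcript(tid, gid, seq, strand, exons)


def pset(transcripts, method="m", strategy=None) -> PredictionSet:
    return PredictionSet(
        method_name=method,
        loci=loci_from_transcripts(list(transcripts)),
        strategy=strategy,
    )


# ---------------------------------------------------------------------------
# Scenario fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def prok_scenario_cfg():
    """The canonical prokaryotic study conditions: 200 genes, 70% expressed,
    disjoint method-unique false-positive pools."""
    return SimulationConfig(
        seed=42,
        n_genes=200,
        mode="prokaryote",
        expressed_fraction=0.7,
        profiles=[
            ErrorProfile("abinit_sim", Strategy.AB_INITIO,
                         drop_rate=0.05, fp_rate=0.3),
            ErrorProfile("evidence_sim", Strategy.EVIDENCE,
                         drop_rate=0.1, fp_rate=0.3),
        ],
    )


@pytest.fixture
def euk_jitter_cfg():
    """Eukaryotic fixture with boundary jitter, for threshold sweeps."""
    return SimulationConfig(
        seed=7,
        n_genes=60,
        mode="eukaryote",
        genome_length=1_500_000,
        expressed_fraction=0.7,
        profiles=[
            ErrorProfile("abinit_sim", Strategy.AB_INITIO,
                         drop_rate=0.05, fp_rate=0.2, boundary_jitter_sd=4.0),
            ErrorProfile("evidence_sim", Strategy.EVIDENCE,
                         drop_rate=0.1, fp_rate=0.2, boundary_jitter_sd=4.0,
                         exon_drop_rate=0.1),
        ],
    )
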