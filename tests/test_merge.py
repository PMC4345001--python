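"""Consensus engine: overlap semantics, chain matching, conflict resolution,
novel genes, and whole-merge invariants."""

import math

import numpy as np
import pytest

from genemerge import (
    ErrorProfile,
    ExonMatch,
    MergeConfig,
    Mode,
    SimulationConfig,
    Strategy,
    SupportClass,
    accept_by_exon_count,
    classify_locus_prok,
    classify_transcript_euk,
    exonic_overlap_fraction,
    find_novel,
    match_exon_chain,
    merge,
    resolve_conflict,
    simulate_predictions,
)
from .conftest import (
    chain_match_oracle,
    overlap_fraction_oracle,
    pset,
    random_exon_pairs,
    tx,
)

EUK = MergeConfig(mode=Mode.EUKARYOTE)
PROK = MergeConfig(mode=Mode.PROKARYOTE)


class TestOverlapFraction:
    def test_identical(self):
        t = tx([(0, 100), (200, 300)])
        assert exonic_overlap_fraction(t, t) == 1.0

    def test_partial(self):
        assert exonic_overlap_fraction(tx([(100, 200)]), tx([(100, 190)])) == 0.9

    def test_disjoint_and_cross_seq(self):
        a = tx([(0, 100)])
        assert exonic_overlap_fraction(a, tx([(200, 300)])) == 0.0
        assert exonic_overlap_fraction(a, tx([(0, 100)], seq="chr2")) == 0.0

    def test_denominator_is_leading_side(self):
        lead = tx([(0, 100)])
        other = tx([(0, 200)])  # contains the leading transcript
        assert exonic_overlap_fraction(lead, other) == 1.0
        assert exonic_overlap_fraction(other, lead) == 0.5

    def test_agrees_with_position_set_oracle(self, rng):
        for _ in range(300):
            a = random_exon_pairs(rng)
            b = random_exon_pairs(rng)
            got = exonic_overlap_fraction(tx(a), tx(b, tid="t2"))
            assert got == pytest.approx(overlap_fraction_oracle(a, b), abs=1e-12)


class TestExonCountRule:
    @pytest.mark.parametrize("t,n,k,expected", [
        (0.8, 5, 4, True),
        (0.8, 5, 3, False),
        (1.0, 7, 7, True),
        (1.0, 7, 6, False),
    ])
    def test_examples(self, t, n, k, expected):
        assert accept_by_exon_count(k, n, t) is expected

    @pytest.mark.parametrize("t", [0.5, 0.7, 0.8, 1.0])
    @pytest.mark.parametrize("n", range(1, 11))
    def test_grid_matches_exact_floor(self, t, n):
        from fractions import Fraction
        exact_floor = math.floor(Fraction(str(t)) * n)  # decimal t, exact arithmetic
        for k in range(0, n + 1):
            assert accept_by_exon_count(k, n, t) == (k >= exact_floor)


class TestChainMatch:
    def test_identical_chains_all_exact(self):
        a = tx([(0, 100), (200, 300), (400, 500)])
        cm = match_exon_chain(a, a, EUK)
        assert cm.all_exact and cm.all_matched and cm.k == cm.n == 3

    def test_missing_terminal_exon(self):
        lead = tx([(0, 100), (200, 300), (400, 500)])
        cand = tx([(0, 100), (200, 300)], tid="c")
        cm = match_exon_chain(lead, cand, EUK)
        assert (cm.k, cm.n, cm.all_matched) == (2, 3, False)
        assert cm.per_exon == (ExonMatch.EXACT, ExonMatch.EXACT, ExonMatch.UNMATCHED)

    def test_extended_first_exon_is_partial_not_exact(self):
        # candidate extends the first exon 10 nt upstream: it fully covers the
        # leading exon (fraction 1.0) but the boundary differs, so the exon is
        # PARTIAL — coverage and boundary identity are different questions
        lead = tx([(100, 200), (300, 400), (500, 600)])
        cand = tx([(90, 200), (300, 400), (500, 600)], tid="c")
        cm = match_exon_chain(lead, cand, EUK)
        assert cm.per_exon == (ExonMatch.PARTIAL, ExonMatch.EXACT, ExonMatch.EXACT)
        assert cm.all_matched and not cm.all_exact

    def test_strand_mismatch_blocks_matching(self):
        a = tx([(0, 100)])
        b = tx([(0, 100)], strand="-", tid="c")
        assert match_exon_chain(a, b, EUK).k == 0
        relaxed = MergeConfig(strand_policy="ignore_all")
        assert match_exon_chain(a, b, relaxed).k == 1

    def test_unstranded_policy(self):
        a = tx([(0, 100)])
        b = tx([(0, 100)], strand=".", tid="c")
        assert match_exon_chain(a, b, EUK).k == 0
        pol = MergeConfig(strand_policy="ignore_unstranded")
        assert match_exon_chain(a, b, pol).all_exact

    @pytest.mark.parametrize("t", [0.5, 0.8, 1.0])
    def test_agrees_with_enumeration_oracle(self, rng, t):
        cfg = MergeConfig(overlap_threshold=t)
        for _ in range(250):
            a = random_exon_pairs(rng)
            b = random_exon_pairs(rng)
            cm = match_exon_chain(tx(a), tx(b, tid="c"), cfg)
            k_best, exact_best = chain_match_oracle(a, b, t)
            assert cm.k == k_best
            n_exact = sum(1 for p in cm.per_exon if p == ExonMatch.EXACT)
            assert n_exact == exact_best


class TestProkClassification:
    def test_identical_evidence_is_perfect(self):
        lead = tx([(0, 1000)])
        support, srcs = classify_locus_prok(
            lead, [("ev", tx([(0, 1000)], tid="e"))], PROK)
        assert support == SupportClass.PERFECT
        assert len(srcs) == 1

    def test_partial_overlap_above_threshold_supported(self):
        lead = tx([(0, 1000)])
        support, _ = classify_locus_prok(
            lead, [("ev", tx([(0, 810)], tid="e"))], PROK)
        assert support == SupportClass.SUPPORTED

    def test_fraction_exactly_at_threshold_unsupported(self):
        # the rule is strictly greater-than: 800/1000 at t=0.8 does not support
        lead = tx([(0, 1000)])
        support, srcs = classify_locus_prok(
            lead, [("ev", tx([(0, 800)], tid="e"))], PROK)
        assert support == SupportClass.UNSUPPORTED and srcs == []

    def test_containing_prediction_is_not_perfect(self):
        lead = tx([(100, 1100)])
        support, _ = classify_locus_prok(
            lead, [("ev", tx([(0, 1200)], tid="e"))], PROK)
        assert support == SupportClass.SUPPORTED

    def test_ties_all_reported_as_sources(self):
        lead = tx([(0, 1000)])
        cands = [("ev1", tx([(0, 900)], tid="a")), ("ev2", tx([(100, 1000)], tid="b"))]
        support, srcs = classify_locus_prok(lead, cands, PROK)
        assert support == SupportClass.SUPPORTED and len(srcs) == 2


class TestEukClassification:
    def test_all_exact_is_perfect(self):
        lead = tx([(0, 100), (200, 300)])
        d = classify_transcript_euk(lead, [("ev", tx([(0, 100), (200, 300)], tid="e"))], EUK)
        assert d.support_class == SupportClass.PERFECT

    def test_minor_boundary_difference_supported_with_lower_score(self):
        lead = tx([(0, 100), (200, 300)])
        cand = tx([(0, 100), (200, 297)], tid="e")  # 97/100 > 0.8, not exact
        d = classify_transcript_euk(lead, [("ev", cand)], EUK)
        assert d.support_class == SupportClass.SUPPORTED
        cfg = MergeConfig()
        assert (cfg.score_map[SupportClass.SUPPORTED]
                < cfg.score_map[SupportClass.PERFECT])

    def test_partial_accepted_requires_rule_on_both_sides(self):
        # 5-exon leading; candidate has 5 exons, 4 matched on each side
        exons = [(i * 200, i * 200 + 100) for i in range(5)]
        lead = tx(exons)
        cand_exons = exons[:4] + [(1200, 1300)]  # last exon elsewhere
        cand = tx(cand_exons, tid="e")
        d = classify_transcript_euk(lead, [("ev", cand)], EUK)
        assert d.support_class == SupportClass.PARTIAL_ACCEPTED

    def test_one_sided_match_insufficient(self):
        # candidate matches 4 of 5 leading exons but carries 8 exons itself:
        # 4 < floor(0.8*8) = 6, so the candidate side fails the rule
        exons = [(i * 200, i * 200 + 100) for i in range(5)]
        lead = tx(exons)
        cand = tx(exons[:4] + [(2000 + i * 200, 2100 + i * 200) for i in range(4)],
                  tid="e")
        d = classify_transcript_euk(lead, [("ev", cand)], EUK)
        assert d.support_class == SupportClass.UNSUPPORTED


class TestConflictResolution:
    # third exon extended well past the agreed boundary: 100/160 = 0.625 < t,
    # so the leading chain is not all_matched by the agreed structure
    lead = staticmethod(lambda: tx([(0, 100), (200, 300), (400, 560)], tid="L"))

    def test_agreeing_evidence_replaces_leading(self):
        agreed = [(0, 100), (200, 300), (400, 500), (600, 700)]
        e1 = tx(agreed, tid="e1")
        e2 = tx(agreed, tid="e2")
        verdict, group = resolve_conflict(
            self.lead(), [("ev1", e1), ("ev2", e2)], EUK)
        assert verdict == "replace"
        assert {m for m, _ in group} == {"ev1", "ev2"}

    def test_disagreeing_evidence_keeps_leading_when_rule_met(self):
        lead = tx([(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)])
        e1 = tx([(0, 100), (200, 300), (400, 500), (600, 700), (1000, 1100)], tid="e1")
        e2 = tx([(0, 50), (150, 160)], tid="e2")
        verdict, chosen = resolve_conflict(lead, [("ev1", e1), ("ev2", e2)], EUK)
        assert verdict == "keep"
        assert chosen[0][0] == "ev1"

    def test_undecided_when_nothing_agrees(self):
        e1 = tx([(0, 30)], tid="e1")
        e2 = tx([(450, 520), (600, 650)], tid="e2")
        verdict, group = resolve_conflict(
            self.lead(), [("ev1", e1), ("ev2", e2)], EUK)
        assert verdict == "undecided" and group == []

    def test_requires_two_candidates(self):
        with pytest.raises(ValueError):
            resolve_conflict(self.lead(), [("ev1", tx([(0, 30)], tid="e"))], EUK)


class TestFindNovel:
    def _sets(self):
        shared = [(5000, 5400)]
        ev1 = pset([tx([(0, 1000)], tid="e1", gid="e1"),
                    tx(shared, tid="n1", gid="n1")],
                   method="ev1", strategy=Strategy.EVIDENCE)
        ev2 = pset([tx(shared, tid="n2", gid="n2"),
                    tx([(9000, 9300)], tid="only2", gid="only2")],
                   method="ev2", strategy=Strategy.EVIDENCE)
        ab = pset([tx([(0, 1000)], tid="a1", gid="a1")],
                  method="ab", strategy=Strategy.AB_INITIO)
        return ev1, ev2, ab

    def test_concordant_evidence_only_gene_reported_once(self):
        ev1, ev2, ab = self._sets()
        cfg = MergeConfig(mode=Mode.PROKARYOTE, include_novel=True)
        novel = find_novel([ev1, ev2], [ab], cfg)
        assert len(novel) == 1
        rep, sources = novel[0]
        assert rep.exon_boundaries() == ((5000, 5400),)
        assert {m for m, _ in sources} == {"ev1", "ev2"}

    def test_single_method_gene_not_reported(self):
        ev1, ev2, ab = self._sets()
        cfg = MergeConfig(mode=Mode.PROKARYOTE, include_novel=True)
        reported = {t.transcript_id for t, _ in find_novel([ev1, ev2], [ab], cfg)}
        assert "only2" not in reported

    def test_ab_initio_covered_gene_not_novel(self):
        # the (0,1000) gene overlaps an ab initio prediction at fraction 1.0:
        # it belongs to the main pass, not the novel pass
        ev1, ev2, ab = self._sets()
        cfg = MergeConfig(mode=Mode.PROKARYOTE, include_novel=True)
        reported = {t.transcript_id for t, _ in find_novel([ev1, ev2], [ab], cfg)}
        assert "e1" not in reported

    def test_single_evidence_set_rejected(self):
        ev1, _, ab = self._sets()
        with pytest.raises(ValueError, match="two evidence"):
            find_novel([ev1], [ab], MergeConfig(include_novel=True))


class TestMerge:
    def test_self_merge_idempotence(self, prok_scenario_cfg):
        sim = simulate_predictions(prok_scenario_cfg)
        base = sim.predictions[0]
        copy = pset(list(base.transcripts()), method="copy",
                    strategy=Strategy.EVIDENCE)
        for t in (0.8, 1.0):
            res = merge([base], [copy],
                        MergeConfig(mode=Mode.PROKARYOTE, overlap_threshold=t))
            assert len(res.records) == base.n_transcripts
            assert all(r.support_class == SupportClass.PERFECT for r in res.records)
            assert res.unsupported_ab_initio.loci == []
            assert res.unmatched_evidence.loci == []

    def test_filtering_removes_method_unique_false_positives(self, prok_scenario_cfg):
        sim = simulate_predictions(prok_scenario_cfg)
        ab, ev = sim.predictions
        res = merge([ab], [ev], MergeConfig(mode=Mode.PROKARYOTE))
        ab_man, ev_man = sim.manifests["abinit_sim"], sim.manifests["evidence_sim"]
        merged_sources = {g for r in res.records for (_, g, _) in r.sources}
        fp_ids = ({g for g, src in ab_man.items() if src == "FP"}
                  | {g for g, src in ev_man.items() if src == "FP"})
        assert merged_sources.isdisjoint(fp_ids)
        # every gene predicted by both strategies is retained
        ab_true = {src for g, src in ab_man.items() if src != "FP"}
        ev_true = {src for g, src in ev_man.items() if src != "FP"}
        expected = ab_true & ev_true
        recovered = {ab_man[g] for r in res.records for (m, g, _) in r.sources
                     if m == "abinit_sim"}
        assert recovered == expected

    def test_threshold_monotonicity(self, euk_jitter_cfg):
        sim = simulate_predictions(euk_jitter_cfg)
        ab, ev = sim.predictions
        counts = []
        for t in np.arange(0.5, 1.01, 0.1):
            res = merge([ab], [ev], MergeConfig(mode=Mode.EUKARYOTE,
                                                overlap_threshold=round(t, 2)))
            counts.append(len(res.records))
        assert counts == sorted(counts, reverse=True)

    def test_evidence_order_invariance(self, euk_jitter_cfg):
        cfg2 = euk_jitter_cfg
        cfg2.profiles.append(
            ErrorProfile("evidence2_sim", Strategy.EVIDENCE,
                         drop_rate=0.15, fp_rate=0.1, boundary_jitter_sd=2.0))
        sim = simulate_predictions(cfg2)
        ab, ev1, ev2 = sim.predictions
        mc = MergeConfig(mode=Mode.EUKARYOTE, include_novel=True)
        res_a = merge([ab], [ev1, ev2], mc)
        res_b = merge([ab], [ev2, ev1], mc)
        key = lambda res: {
            (r.transcript.seq_id, r.transcript.exon_boundaries(),
             r.support_class) for r in res.records}
        assert key(res_a) == key(res_b)

    def test_provenance_spans_strategies(self, euk_jitter_cfg):
        sim = simulate_predictions(euk_jitter_cfg)
        ab, ev = sim.predictions
        res = merge([ab], [ev], MergeConfig(mode=Mode.EUKARYOTE))
        for rec in res.records:
            methods = {m for m, _, _ in rec.sources}
            assert "abinit_sim" in methods and "evidence_sim" in methods

    def test_tracking_matches_records(self, prok_scenario_cfg):
        sim = simulate_predictions(prok_scenario_cfg)
        res = merge([sim.predictions[0]], [sim.predictions[1]],
                    MergeConfig(mode=Mode.PROKARYOTE))
        assert {r.merged_id for r in res.records} == \
            {t.merged_id for t in res.tracking}
        for rec, trk in zip(res.records, res.tracking):
            assert list(rec.sources) == trk.sources

    def test_same_strategy_inputs_rejected(self):
        a = pset([tx([(0, 100)])], method="a", strategy=Strategy.AB_INITIO)
        b = pset([tx([(0, 100)])], method="b", strategy=Strategy.AB_INITIO)
        with pytest.raises(ValueError, match="ab initio"):
            merge([a, b], [], MergeConfig())

    def test_untagged_set_rejected(self):
        a = pset([tx([(0, 100)])], method="a")
        b = pset([tx([(0, 100)])], method="b", strategy=Strategy.EVIDENCE)
        with pytest.raises(ValueError, match="tagged"):
            merge([a], [b], MergeConfig())
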