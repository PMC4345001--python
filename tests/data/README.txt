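conflict_replacement_expected.gtf — hand-derived expected consensus for the
three-method conflict scenario built in tests (leading transcript with an
extended terminal exon vs. two agreeing evidence methods): the agreed
evidence structure is emitted once, classified SUPPORTED, with all three
source predictions tracked.
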