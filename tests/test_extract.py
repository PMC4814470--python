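import numpy as np
import pytest

from spacerkit.extract import (MixedStrandError, collect_internal_repeats,
                               extract_spacers, find_repeat_matches,
                               internal_repeat_table, process_reads, trim_reads)
from spacerkit.seqs import FastqRead, random_dna, revcomp
from spacerkit.simulate import RepeatModel, make_site_pools, simulate_amplicons


def _read(seq, quals=None, rid="r1"):
    return FastqRead(rid, seq, quals if quals is not None else [30] * len(seq))


class TestTrimReads:
    def test_clean_read_unchanged(self):
        kept, stats = trim_reads([_read("ACGT" * 20)])
        assert kept[0].sequence == "ACGT" * 20
        assert stats.kept == 1

    def test_read_with_n_dropped(self):
        kept, stats = trim_reads([_read("ACGTN" + "ACGT" * 20)])
        assert kept == []
        assert stats.dropped_n == 1

    def test_low_quality_tail_trimmed(self):
        seq = "A" * 60 + "C" * 10
        quals = [30] * 60 + [15] * 10
        kept, _ = trim_reads([_read(seq, quals)])
        assert kept[0].sequence == "A" * 60

    def test_trimmed_n_still_dropped(self):
        # the N sits before the low-quality tail, so it survives trimming
        seq = "A" * 30 + "N" + "A" * 30 + "C" * 5
        quals = [30] * 61 + [10] * 5
        kept, stats = trim_reads([_read(seq, quals)])
        assert kept == []
        assert stats.dropped_n == 1

    def test_short_after_trim_dropped(self):
        kept, stats = trim_reads([_read("A" * 60, [30] * 30 + [10] * 30)])
        assert kept == []
        assert stats.dropped_short == 1

    def test_malformed_record_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            trim_reads([FastqRead("bad", "ACGT", [30, 30])])


@pytest.fixture(scope="module")
def repeat36():
    rng = np.random.default_rng(50)
    return RepeatModel(consensus=random_dna(rng, 36))


class TestFindRepeatMatches:
    def test_exact_embedded_repeat(self, repeat36):
        seq = "AAA" + repeat36.consensus + "CCC"
        matches = [m for m in find_repeat_matches(seq, repeat36, max_mismatch=0,
                                                  allow_terminal_partial=False)]
        assert len(matches) == 1
        m = matches[0]
        assert (m.start, m.end, m.strand, m.full) == (3, 39, "+", True)
        assert m.mismatches == 0

    def test_reverse_complement_match(self, repeat36):
        seq = "AAA" + revcomp(repeat36.consensus) + "CCC"
        matches = find_repeat_matches(seq, repeat36, max_mismatch=0,
                                      allow_terminal_partial=False)
        assert len(matches) == 1
        assert matches[0].strand == "-"

    def test_mismatch_threshold_boundary(self, repeat36):
        cons = repeat36.consensus
        mutated = list(cons)
        for i in range(6):  # 6 = max_mismatch + 1
            mutated[i * 5] = "A" if cons[i * 5] != "A" else "C"
        seq = "GGG" + "".join(mutated) + "GGG"
        assert find_repeat_matches(seq, repeat36, max_mismatch=5,
                                   allow_terminal_partial=False) == []
        assert len(find_repeat_matches(seq, repeat36, max_mismatch=6,
                                       allow_terminal_partial=False)) == 1

    def test_monotone_in_max_mismatch(self, repeat36, rng):
        seq = random_dna(rng, 120) + repeat36.consensus + random_dna(rng, 80)
        previous = 0
        for mm in range(0, 8):
            n = len(find_repeat_matches(seq, repeat36, max_mismatch=mm,
                                        allow_terminal_partial=False))
            assert n >= previous
            previous = n

    def test_terminal_partials_found(self, repeat_model):
        spacer = random_dna(np.random.default_rng(51), 30)
        seq = repeat_model.left_terminal + spacer + repeat_model.right_terminal
        matches = find_repeat_matches(seq, repeat_model)
        assert len(matches) == 2
        assert not any(m.full for m in matches)
        assert matches[0].end == len(repeat_model.left_terminal)
        assert matches[1].start == len(seq) - len(repeat_model.right_terminal)

    def test_ambiguous_consensus_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            RepeatModel(consensus="ACGTN" * 6)


class TestExtractSpacers:
    def _two_spacer_read(self, repeat36, rng):
        s1, s2 = random_dna(rng, 30), random_dna(rng, 29)
        cons = repeat36.consensus
        return cons + s1 + cons + s2 + cons, s1, s2

    def test_forced_structure(self, repeat36, rng):
        read, s1, s2 = self._two_spacer_read(repeat36, rng)
        matches = find_repeat_matches(read, repeat36, allow_terminal_partial=False)
        records = extract_spacers(read, matches, repeat=repeat36, read_id="r1")
        assert [r.sequence for r in records] == [s1, s2]
        assert all(r.left_variant == "v1" and r.right_variant == "v1" for r in records)

    def test_short_gap_not_emitted(self, repeat36, rng):
        cons = repeat36.consensus
        read = cons + random_dna(rng, 25) + cons  # 25 < lower bound 26
        matches = find_repeat_matches(read, repeat36, allow_terminal_partial=False)
        assert extract_spacers(read, matches, repeat=repeat36) == []

    def test_strand_normalization(self, repeat36, rng):
        read, s1, s2 = self._two_spacer_read(repeat36, rng)
        rc = revcomp(read)
        matches = find_repeat_matches(rc, repeat36, allow_terminal_partial=False)
        records = extract_spacers(rc, matches, repeat=repeat36)
        assert [r.sequence for r in records] == [s1, s2]

    def test_mixed_strand_rejected(self, repeat36, rng):
        cons = repeat36.consensus
        read = cons + random_dna(rng, 30) + revcomp(cons)
        matches = find_repeat_matches(read, repeat36, allow_terminal_partial=False)
        with pytest.raises(MixedStrandError):
            extract_spacers(read, matches, repeat=repeat36)


class TestInternalRepeats:
    def test_single_spacer_reads_give_empty_table(self, repeat_model):
        pools = make_site_pools(1, [10], [[10]], seed=60)
        reads, _ = simulate_amplicons(pools, repeat_model, 30,
                                      spacers_per_fragment=1, seed=61)
        res = process_reads(reads[pools.site_names[0]], repeat_model)
        assert res.internal_repeats == []
        assert internal_repeat_table([]).empty

    def test_two_spacer_read_counts_one_internal(self, repeat36, rng):
        cons = repeat36.consensus
        s1, s2 = random_dna(rng, 30), random_dna(rng, 28)
        read = cons + s1 + cons + s2 + cons
        matches = find_repeat_matches(read, repeat36, allow_terminal_partial=False)
        internals = collect_internal_repeats(read, matches)
        assert internals == [cons]

    def test_recovered_variant_frequencies(self):
        freqs = (0.656, 0.34, 0.002, 0.002)
        model = RepeatModel.random(seed=62, variant_freqs=freqs)
        pools = make_site_pools(1, [30], [[30]], seed=63)
        n = 4000
        reads, _ = simulate_amplicons(pools, model, n,
                                      spacers_per_fragment=2, seed=64)
        res = process_reads(reads[pools.site_names[0]], model)
        table = internal_repeat_table(res.internal_repeats)
        assert table["count"].sum() == n
        assert abs(table["frequency"].sum() - 1.0) < 1e-9
        by_seq = dict(zip(table["variant_seq"], table["frequency"]))
        for (vid, vseq, f) in model.variant_table[:2]:
            se = (f * (1 - f) / n) ** 0.5
            assert abs(by_seq.get(vseq, 0.0) - f) <= 3 * se


class TestRoundTrip:
    def test_error_free_extraction_equals_truth(self, repeat_model):
        pools = make_site_pools(2, [40, 40], 10, seed=70)
        reads, truth = simulate_amplicons(pools, repeat_model, 500, seed=71)
        for site in pools.site_names:
            res = process_reads(reads[site], repeat_model, site=site)
            assert res.spacer_multiset() == truth.planted_multiset(site)
            assert res.stats["mixed_strand_skipped"] == 0

    def test_conservation_invariant(self, repeat_model):
        pools = make_site_pools(1, [20], [[20]], seed=72)
        reads, _ = simulate_amplicons(pools, repeat_model, 200, seed=73)
        site = pools.site_names[0]
        from spacerkit.extract import find_repeat_matches as frm
        for read in reads[site]:
            matches = frm(read.sequence, repeat_model)
            records = extract_spacers(read.sequence, matches, repeat=repeat_model)
            n_full_internal = len(collect_internal_repeats(read.sequence, matches))
            if records:
                assert len(records) == n_full_internal + 1

    def test_strand_invariance_of_multiset(self, repeat_model):
        pools = make_site_pools(1, [15], [[15]], seed=74)
        reads, _ = simulate_amplicons(pools, repeat_model, 100, seed=75)
        site = pools.site_names[0]
        fwd = process_reads(reads[site], repeat_model)
        flipped = [FastqRead(r.read_id, revcomp(r.sequence), r.qualities[::-1])
                   for r in reads[site]]
        rev = process_reads(flipped, repeat_model)
        assert fwd.spacer_multiset() == rev.spacer_multiset()
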