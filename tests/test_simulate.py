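import numpy as np
import pytest

from spacerkit.seqs import hamming, revcomp
from spacerkit.simulate import (OverlapDesignError, PamSpec, RepeatModel,
                                make_site_pools, make_target_genome,
                                simulate_amplicons)


class TestRepeatModel:
    def test_variant_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="frequencies"):
            RepeatModel(consensus="A" * 30, variants=(("A" * 30, 0.5), ("C" * 30, 0.4)))

    def test_variant_length_must_match(self):
        with pytest.raises(ValueError, match="length"):
            RepeatModel(consensus="A" * 30, variants=(("A" * 29, 1.0),))

    def test_repeat_length_bounds(self):
        with pytest.raises(ValueError, match="repeat length"):
            RepeatModel(consensus="A" * 22)
        with pytest.raises(ValueError, match="repeat length"):
            RepeatModel(consensus="A" * 48)

    def test_primers_anneal_within_repeat(self, repeat_model):
        assert repeat_model.forward_primer in repeat_model.consensus
        assert repeat_model.reverse_primer in revcomp(repeat_model.consensus)

    def test_bad_primer_rejected(self):
        consensus = "ACGT" * 10
        with pytest.raises(ValueError, match="primer"):
            RepeatModel(consensus=consensus, forward_primer="TTTTTTTTTTTTTTTT")

    def test_terminals_are_consensus_suffix_and_prefix(self, repeat_model):
        c = repeat_model.consensus
        assert c.endswith(repeat_model.left_terminal)
        assert c.startswith(repeat_model.right_terminal)

    def test_variants_differ_at_single_positions(self):
        m = RepeatModel.random(seed=3, variant_freqs=(0.656, 0.34, 0.002, 0.002))
        table = m.variant_table
        assert [vid for vid, _, _ in table] == ["v1", "v2", "v3", "v4"]
        assert hamming(table[0][1], table[1][1]) == 1
        assert hamming(table[1][1], table[2][1]) == 1


class TestMakeSitePools:
    def test_single_site(self):
        pools = make_site_pools(1, [10], [[10]], seed=5)
        pool = pools.pool(pools.site_names[0])
        assert len(pool) == 10
        assert len(set(pool)) == 10
        assert all(28 <= len(s) <= 31 for s in pool)

    def test_full_overlap_gives_identical_pools(self):
        pools = make_site_pools(2, [5, 5], 5, seed=6)
        a, b = pools.site_names
        assert set(pools.pool(a)) == set(pools.pool(b))

    def test_three_site_design_realized_exactly(self, three_site_pools):
        regions = three_site_pools.realized_regions()
        names = three_site_pools.site_names
        assert regions[frozenset(names)] == 10
        for i in range(3):
            for j in range(i + 1, 3):
                assert regions[frozenset([names[i], names[j]])] == 20  # 30 - 10 triple
            assert regions[frozenset([names[i]])] == 100 - 2 * 20 - 10

    def test_pairwise_separation_invariant(self, three_site_pools):
        spacers = sorted({s for p in three_site_pools.pools.values() for s in p})
        for i, a in enumerate(spacers):
            for b in spacers[i + 1:]:
                if len(a) == len(b):
                    assert hamming(a, b) > 10

    def test_infeasible_design_raises(self):
        with pytest.raises(OverlapDesignError):
            make_site_pools(3, [10, 10, 10], 5, shared_all=8, seed=1)
        with pytest.raises(OverlapDesignError):
            make_site_pools(2, [3, 3], [[3, 10], [10, 3]], seed=1)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(OverlapDesignError, match="symmetric"):
            make_site_pools(2, [5, 5], [[5, 2], [3, 5]], seed=1)

    def test_deterministic_under_seed(self):
        p1 = make_site_pools(2, [8, 8], 3, seed=42)
        p2 = make_site_pools(2, [8, 8], 3, seed=42)
        assert p1.pools == p2.pools


class TestSimulateAmplicons:
    def test_single_spacer_reads_have_no_internal_repeat(self, single_variant_repeat):
        pools = make_site_pools(1, [10], [[10]], seed=7)
        reads, truth = simulate_amplicons(pools, single_variant_repeat, 50,
                                          spacers_per_fragment=1, seed=8)
        site = pools.site_names[0]
        cons = single_variant_repeat.consensus
        for r in reads[site]:
            assert cons not in r.sequence  # terminals are truncated
        assert all(len(t["spacers"]) == 1 and t["variants"] == [] for t in truth.reads)

    def test_two_spacer_reads_have_one_internal_repeat(self, single_variant_repeat):
        pools = make_site_pools(1, [10], [[10]], seed=7)
        reads, truth = simulate_amplicons(pools, single_variant_repeat, 50,
                                          spacers_per_fragment=2, seed=8)
        site = pools.site_names[0]
        cons = single_variant_repeat.consensus
        for r in reads[site]:
            assert r.sequence.count(cons) == 1

    def test_read_structure_is_derivable_from_truth(self, repeat_model):
        pools = make_site_pools(1, [10], [[10]], seed=7)
        reads, truth = simulate_amplicons(pools, repeat_model, 30, seed=9)
        site = pools.site_names[0]
        variant_seq = {vid: seq for vid, seq, _ in repeat_model.variant_table}
        by_id = {r.read_id: r.sequence for r in reads[site]}
        for entry in truth.reads:
            parts = [repeat_model.left_terminal]
            for i, sp in enumerate(entry["spacers"]):
                parts.append(sp)
                if i < len(entry["spacers"]) - 1:
                    parts.append(variant_seq[entry["variants"][i]])
            parts.append(repeat_model.right_terminal)
            assert by_id[entry["read_id"]] == "".join(parts)

    def test_variant_frequencies_within_three_se(self):
        model = RepeatModel.random(seed=13, variant_freqs=(0.66, 0.34))
        pools = make_site_pools(1, [20], [[20]], seed=14)
        n = 10_000
        reads, truth = simulate_amplicons(pools, model, n,
                                          spacers_per_fragment=2, seed=15)
        drawn = [v for t in truth.reads for v in t["variants"]]
        assert len(drawn) == n
        p_hat = drawn.count("v1") / n
        se = (0.66 * 0.34 / n) ** 0.5
        assert abs(p_hat - 0.66) <= 3 * se

    def test_error_rate_bounds(self, single_variant_repeat):
        pools = make_site_pools(1, [5], [[5]], seed=7)
        with pytest.raises(ValueError, match="error_rate"):
            simulate_amplicons(pools, single_variant_repeat, 5, error_rate=0.1, seed=1)

    def test_byte_identical_under_seed(self, repeat_model):
        pools = make_site_pools(2, [10, 10], 4, seed=30)
        r1, _ = simulate_amplicons(pools, repeat_model, 40, seed=31)
        r2, _ = simulate_amplicons(pools, repeat_model, 40, seed=31)
        assert r1 == r2


class TestMakeTargetGenome:
    def test_planted_protospacer_and_pam_present(self, rng):
        from spacerkit.seqs import random_dna
        spacer = random_dna(rng, 30)
        (_, genome), truth = make_target_genome([spacer], PamSpec("NNAAAG"), 2000, seed=16)
        t = truth[0]
        window = genome[t["start"]:t["end"]]
        if t["strand"] == "+":
            assert window == spacer
            assert genome[t["end"] + 2:t["end"] + 6] == "AAAG"
        else:
            assert window == revcomp(spacer)
            assert revcomp(genome[t["start"] - 6:t["start"] - 2]) == "AAAG"

    def test_zero_protospacers_gives_pure_random_genome(self):
        (_, genome), truth = make_target_genome([], None, 500, seed=17)
        assert truth == []
        assert len(genome) == 500
        assert set(genome) <= set("ACGT")

    def test_motif_beyond_flank_window_rejected(self, rng):
        from spacerkit.seqs import random_dna
        with pytest.raises(ValueError, match="flank"):
            make_target_genome([random_dna(rng, 30)], PamSpec("AAAAAAA", offset=3),
                               2000, seed=18)

    def test_genome_too_small_rejected(self, rng):
        from spacerkit.seqs import random_dna
        with pytest.raises(ValueError, match="genome_length"):
            make_target_genome([random_dna(rng, 30)], None, 40, seed=19)
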