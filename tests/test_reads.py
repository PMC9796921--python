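"""Clone removal, tag rescue, quality filtering, demultiplexing."""

import itertools

import numpy as np
import pytest

from quadchim.reads import (
    DemuxParams,
    ReadError,
    demultiplex_group,
    demultiplex_group_levels,
    demultiplex_run,
    hamming_distance,
    match_tag,
    quality_filter,
    remove_clones,
)
from quadchim.scheme import BarcodeTag
from quadchim.simulate import ReadPair, SimParams, simulate_experiment

Q37 = "F"  # Phred 37 in Phred-33 encoding


def mk_pair(seq1, seq2=None, qual1=None, qual2=None, pf=True, rid="r"):
    seq2 = seq2 if seq2 is not None else seq1
    return ReadPair(
        rid,
        seq1, qual1 or Q37 * len(seq1),
        seq2, qual2 or Q37 * len(seq2),
        pf,
    )


def clean_params(**kw):
    base = dict(
        dup_rate=0.0, pcr_chimera_rate=0.0, seq_chimera_rate=0.0,
        index_hop_rate=0.0, junk_rate=0.0, error_rate=0.0,
        uncalled_rate=0.0, chastity_fail_rate=0.0, seed=0,
    )
    base.update(kw)
    return SimParams(**base)


class TestCloneRemoval:
    def test_no_duplicates_means_nothing_removed(self, demo_scheme):
        run = simulate_experiment(demo_scheme, clean_params(reads_per_sample=40))
        for pairs in run.reads_by_group.values():
            kept, n = remove_clones(pairs)
            assert n == 0 and kept == list(pairs)

    def test_removes_exactly_the_injected_duplicates(self, demo_scheme):
        run = simulate_experiment(
            demo_scheme, clean_params(reads_per_sample=300, dup_rate=0.2, seed=1)
        )
        removed = sum(
            remove_clones(pairs)[1] for pairs in run.reads_by_group.values()
        )
        assert removed == (run.truth["event"] == "pcr_duplicate").sum() > 0

    def test_same_template_different_vbbn_both_kept(self):
        a = mk_pair("CTGTAACG" + "GCGA" + "TGCAG" + "A" * 40, rid="a")
        b = mk_pair("CTGTAACG" + "ATTC" + "TGCAG" + "A" * 40, rid="b")
        kept, n = remove_clones([a, b])
        assert n == 0 and len(kept) == 2

    def test_malformed_read_raises(self):
        with pytest.raises(ReadError):
            remove_clones([mk_pair("ACGT")])


class TestMatchTag:
    TAGS = [BarcodeTag("A", "AAAACCCC"), BarcodeTag("B", "AAAAGGGG")]

    def test_exact_match_at_zero(self):
        m = match_tag("AAAACCCC", self.TAGS, 0)
        assert m.status == "matched" and m.tag.label == "A" and m.distance == 0

    def test_single_substitution_rescued_uniquely(self):
        m = match_tag("AAAACCCA", self.TAGS, 1)
        assert m.status == "matched" and m.tag.label == "A"
        assert match_tag("AAAACCCA", self.TAGS, 0).status == "none"

    def test_midpoint_between_distance_four_tags_is_ambiguous(self):
        # two mismatches to each of the two tags (which differ at 4 positions)
        m = match_tag("AAAACCGG", self.TAGS, 2)
        assert m.status == "ambiguous" and m.distance == 2

    def test_n_counts_as_mismatch(self):
        assert match_tag("AAAACCCN", self.TAGS, 0).status == "none"
        assert match_tag("AAAACCCN", self.TAGS, 1).tag.label == "A"

    def test_empty_tag_list_raises(self):
        with pytest.raises(ReadError):
            match_tag("AAAACCCC", [], 0)

    def test_rescue_never_crosses_distance_four_sets(self, paper_scheme):
        """Exhaustive single-substitution neighbourhoods: with pairwise
        distance >= 4 and k <= 1 a read from a valid tag is never
        reassigned to a different tag."""
        for side in (paper_scheme.i5_tags, paper_scheme.i7_tags):
            tags = list(side.values())
            for tag in tags:
                for pos, base in itertools.product(range(8), "ACGT"):
                    if tag.sequence[pos] == base:
                        continue
                    obs = tag.sequence[:pos] + base + tag.sequence[pos + 1 :]
                    for k in (0, 1):
                        m = match_tag(obs, tags, k)
                        if m.status == "matched":
                            assert m.tag.label == tag.label


class TestQualityFilter:
    def test_high_quality_read_passes(self):
        ok, reason = quality_filter(mk_pair("ACGT" * 10), DemuxParams())
        assert ok and reason is None

    def test_uncalled_base_fails(self):
        ok, reason = quality_filter(
            mk_pair("ACGTNACGT" + "A" * 31), DemuxParams()
        )
        assert not ok and reason == "uncalled"

    def test_uncalled_base_in_tag_region_ignored(self):
        # with payload_start past the tag, an N in the tag does not fail QC
        seq = "NCGTACGTA" + "A" * 31
        ok, _ = quality_filter(mk_pair(seq), DemuxParams(), payload_start=9)
        assert ok

    def test_low_quality_window_mean_fails(self):
        # payload 20 nt -> window = round(0.15*20) = 3; final three bases at
        # Phred (10,10,9) have mean 9.67 < 10 while all other windows pass
        qual = Q37 * 17 + chr(33 + 10) * 2 + chr(33 + 9)
        ok, reason = quality_filter(
            mk_pair("A" * 20, qual1=qual), DemuxParams()
        )
        assert not ok and reason == "low_quality"
        # same read passes with threshold 9
        ok, _ = quality_filter(
            mk_pair("A" * 20, qual1=qual), DemuxParams(quality_threshold=9.0)
        )
        assert ok

    def test_chastity_flag_honoured_and_optional(self):
        failing = mk_pair("ACGT" * 10, pf=False)
        assert quality_filter(failing, DemuxParams()) == (False, "chastity")
        ok, _ = quality_filter(failing, DemuxParams(honor_chastity=False))
        assert ok

    def test_malformed_quality_raises(self):
        bad = mk_pair("ACGT", qual1="\x01\x01\x01\x01")
        with pytest.raises(ReadError):
            quality_filter(bad, DemuxParams())


class TestDemultiplex:
    def test_error_free_reads_all_retained_in_true_combinations(self, demo_scheme):
        run = simulate_experiment(demo_scheme, clean_params(reads_per_sample=50))
        for gid, pairs in run.reads_by_group.items():
            res = demultiplex_group(pairs, demo_scheme, gid, DemuxParams())
            assert res.n_retained == res.n_input
            genuine_combos = demo_scheme.group(gid).pair_labels
            nonzero = res.counts[res.counts["count"] > 0]
            assert set(zip(nonzero["i5"], nonzero["i7"])) <= genuine_combos

    def test_single_tag_error_needs_k_one(self, demo_scheme):
        gid = "mg1"
        pair = demo_scheme.group(gid).inner_pairs[0]
        seq1 = pair.i5.sequence + "GCGA" + "TGCAG" + "A" * 133
        seq1_err = "T" + seq1[1:] if seq1[0] != "T" else "G" + seq1[1:]
        seq2 = pair.i7.sequence + "CTTC" + "TAA" + "C" * 135
        rp = mk_pair(seq1_err, seq2)
        res0 = demultiplex_group([rp], demo_scheme, gid, DemuxParams(max_mismatch=0))
        res1 = demultiplex_group([rp], demo_scheme, gid, DemuxParams(max_mismatch=1))
        assert res0.n_retained == 0 and res0.discards["tag_none"] == 1
        assert res1.n_retained == 1
        combo = res1.counts[res1.counts["count"] == 1]
        assert (combo["i5"].iloc[0], combo["i7"].iloc[0]) == pair.labels

    def test_chimeric_reads_land_in_unused_combinations(self, demo_scheme):
        run = simulate_experiment(
            demo_scheme, clean_params(reads_per_sample=400, seq_chimera_rate=0.05,
                                      seed=3)
        )
        truth_chim = 0
        measured_chim = 0
        for gid, pairs in run.reads_by_group.items():
            res = demultiplex_group(pairs, demo_scheme, gid, DemuxParams())
            genuine = demo_scheme.group(gid).pair_labels
            bad = res.counts[
                ~res.counts.apply(lambda r: (r.i5, r.i7) in genuine, axis=1)
            ]
            measured_chim += bad["count"].sum()
        tr = run.truth
        for _, row in tr[tr["event"] == "seq_chimera"].iterrows():
            grp = demo_scheme.group(row["emitted_group"])
            if (row["apparent_i5"], row["apparent_i7"]) not in grp.pair_labels:
                truth_chim += 1
        assert measured_chim == truth_chim > 0

    def test_accounting_retained_plus_discards_equals_input(self, demo_scheme):
        run = simulate_experiment(
            demo_scheme,
            SimParams(reads_per_sample=200, error_rate=0.01,
                      uncalled_rate=0.002, chastity_fail_rate=0.05,
                      junk_rate=0.01, seed=4),
        )
        for k in (0, 2):
            for gid, pairs in run.reads_by_group.items():
                res = demultiplex_group(
                    pairs, demo_scheme, gid, DemuxParams(max_mismatch=k)
                )
                assert res.n_retained + sum(res.discards.values()) == res.n_input

    def test_retained_reads_monotone_in_k(self, demo_scheme):
        run = simulate_experiment(
            demo_scheme,
            SimParams(reads_per_sample=300, error_rate=0.02, junk_rate=0.01,
                      seed=5),
        )
        for gid, pairs in run.reads_by_group.items():
            results = demultiplex_group_levels(
                pairs, demo_scheme, gid, DemuxParams(), range(5)
            )
            retained = [results[k].n_retained for k in range(5)]
            assert retained == sorted(retained)
            # per-combination counts are non-decreasing too
            for k in range(4):
                delta = (
                    results[k + 1].counts["count"] - results[k].counts["count"]
                )
                assert (delta >= 0).all()

    def test_levels_equal_single_level_runs(self, demo_scheme):
        run = simulate_experiment(
            demo_scheme,
            SimParams(reads_per_sample=100, error_rate=0.02, seed=6),
        )
        gid = "mg2"
        pairs = run.reads_by_group[gid]
        multi = demultiplex_group_levels(
            pairs, demo_scheme, gid, DemuxParams(), (0, 1, 2)
        )
        for k in (0, 1, 2):
            single = demultiplex_group(
                pairs, demo_scheme, gid, DemuxParams(max_mismatch=k)
            )
            assert multi[k].counts.equals(single.counts)
            assert multi[k].discards == single.discards

    def test_truncation_and_tag_stripping(self, demo_scheme):
        run = simulate_experiment(demo_scheme, clean_params(reads_per_sample=5))
        gid = "mg1"
        res = demultiplex_group(
            run.reads_by_group[gid], demo_scheme, gid,
            DemuxParams(truncate_len=136), keep_reads=True,
        )
        for combo, reads in res.bins.items():
            for rp in reads:
                assert len(rp.seq1) == 136  # 150 - 8 - 4 = 138, truncated
                assert rp.seq1.startswith("TGCAG")  # remnant retained

    def test_unknown_group_raises(self, demo_scheme):
        from quadchim.scheme import SchemeError

        with pytest.raises(SchemeError):
            demultiplex_group([], demo_scheme, "nope", DemuxParams())

    def test_run_counts_cover_all_groups(self, demo_scheme):
        run = simulate_experiment(demo_scheme, clean_params(reads_per_sample=10))
        counts, results = demultiplex_run(
            run.reads_by_group, demo_scheme, DemuxParams()
        )
        assert set(counts["group_id"]) == {g.group_id for g in demo_scheme.groups()}
        assert len(counts) == 3 * 16  # 3 groups x 4x4 combinations
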