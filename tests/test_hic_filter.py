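"""Loading, count/span filtering, SD-overlap removal and read-level masking."""

import numpy as np
import pandas as pd
import pytest

from sdspatial import (ContactModel, IntegrityError, ParseError,
                       SyntheticGenomeSpec, bin_and_renormalise,
                       build_unique_mask, filter_count_span,
                       filter_reads_by_mask, filter_sd_overlap,
                       generate_genome, load_interactions, sd_footprint,
                       similarity_class, simulate_read_pairs)
from sdspatial.intervals import overlaps_any

W = 20_000


def sd_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "paralog_chrom",
                                       "paralog_start", "paralog_end", "identity"])


class TestLoad:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "links.tsv"
        p.write_text("")
        assert len(load_interactions(p, W)) == 0

    def test_reversed_pair_is_swapped(self, tmp_path):
        p = tmp_path / "links.tsv"
        p.write_text("400000\t20000\t7\n")
        bis = load_interactions(p, W)
        assert bis.df.iloc[0].tolist() == [20_000, 400_000, 7.0]

    def test_duplicate_unordered_pair_rejected(self, tmp_path):
        p = tmp_path / "links.tsv"
        p.write_text("20000\t400000\t7\n400000\t20000\t3\n")
        with pytest.raises(IntegrityError):
            load_interactions(p, W)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "links.tsv"
        p.write_text("20000\t400000\t7\n20000\tnope\t1\n")
        with pytest.raises(ParseError, match="line 2"):
            load_interactions(p, W)


class TestCountSpan:
    def test_count_threshold_inclusive(self, make_links):
        bis = make_links([(0, 30_000_000, 10), (0, 30_000_000 + W, 15),
                          (0, 30_000_000 + 2 * W, 20)])
        assert len(filter_count_span(bis, 15, 0)) == 2

    def test_span_threshold_inclusive_at_25mb(self, make_links):
        bis = make_links([(0, 25_000_000, 99), (0, 25_000_000 - W, 99)])
        out = filter_count_span(bis, 0, 25_000_000)
        assert out.df["binB_start"].tolist() == [25_000_000]

    def test_random_set_matches_row_scan(self, make_links, rng):
        a = rng.integers(0, 500, 1000) * W
        b = a + rng.integers(1, 1500, 1000) * W
        c = rng.integers(0, 40, 1000)
        df = pd.DataFrame({"binA_start": a, "binB_start": b, "count": c})
        df = df.drop_duplicates(["binA_start", "binB_start"])
        bis = make_links(list(df.itertuples(index=False, name=None)))
        out = filter_count_span(bis, 15, 10_000_000)
        want = {(r.binA_start, r.binB_start) for r in df.itertuples()
                if r.count >= 15 and r.binB_start - r.binA_start >= 10_000_000}
        got = set(zip(out.df["binA_start"], out.df["binB_start"]))
        assert got == want

    def test_monotone_in_thresholds(self, make_links, rng):
        a = rng.integers(0, 200, 300) * W
        b = a + rng.integers(1, 400, 300) * W
        df = pd.DataFrame({"binA_start": a, "binB_start": b,
                           "count": rng.integers(0, 40, 300)})
        bis = make_links(list(df.drop_duplicates(["binA_start", "binB_start"])
                              .itertuples(index=False, name=None)))
        prev = len(bis)
        for mc, ms in [(5, 0), (10, 2_000_000), (20, 4_000_000)]:
            cur = len(filter_count_span(bis, mc, ms))
            assert cur <= prev
            prev = cur


class TestSDOverlap:
    def test_no_sds_is_identity(self, make_links):
        bis = make_links([(0, 30_000_000, 20)])
        out, report = filter_sd_overlap(bis, sd_frame([]), "paralog_pairs")
        assert len(out) == 1 and report.removed_rows == 0

    def test_bridging_link_removed_in_paralog_mode(self, make_links):
        sds = sd_frame([("chrT", 5_000, 15_000, "chrT", 30_005_000, 30_015_000, 0.995)])
        bis = make_links([(0, 30_000_000, 20),      # bridges the two copies
                          (0, 10_000_000, 20)])     # does not
        out, report = filter_sd_overlap(bis, sds, "paralog_pairs")
        assert report.removed_rows == 1
        assert out.df["binB_start"].tolist() == [10_000_000]

    def test_any_sd_superset_of_paralog_pairs(self, make_links, rng):
        sds = sd_frame([("chrT", 100_000, 140_000, "chrT", 28_100_000, 28_140_000, 0.985),
                        ("chrT", 6_000_000, 6_030_000, "chrT", 40_000_000, 40_030_000, 0.97)])
        a = rng.integers(0, 1000, 400) * W
        b = a + rng.integers(1, 1500, 400) * W
        df = pd.DataFrame({"binA_start": a, "binB_start": b, "count": 20})
        bis = make_links(list(df.drop_duplicates(["binA_start", "binB_start"])
                              .itertuples(index=False, name=None)))
        kept_pp, rep_pp = filter_sd_overlap(bis, sds, "paralog_pairs")
        kept_any, rep_any = filter_sd_overlap(bis, sds, "any_sd")
        removed_pp = set(zip(bis.df.binA_start, bis.df.binB_start)) - \
            set(zip(kept_pp.df.binA_start, kept_pp.df.binB_start))
        removed_any = set(zip(bis.df.binA_start, bis.df.binB_start)) - \
            set(zip(kept_any.df.binA_start, kept_any.df.binB_start))
        assert removed_pp <= removed_any
        assert rep_any.removed_rows >= rep_pp.removed_rows

    def test_matches_brute_force_all_pairs_scan(self, make_links, rng):
        sds = sd_frame([("chrT", 90_000, 130_000, "chrT", 24_090_000, 24_130_000, 0.995),
                        ("chrT", 3_000_000, 3_040_000, "chrT", 35_000_000, 35_040_000, 0.97)])
        a = rng.integers(0, 2000, 500) * W
        b = a + rng.integers(1, 800, 500) * W
        df = pd.DataFrame({"binA_start": a, "binB_start": b, "count": 20})
        bis = make_links(list(df.drop_duplicates(["binA_start", "binB_start"])
                              .itertuples(index=False, name=None)))

        def hits(lo, iv):
            return lo < iv[1] and lo + W > iv[0]

        expect_removed = set()
        for r in bis.df.itertuples():
            for sd in sds.itertuples():
                s, p = (sd.start, sd.end), (sd.paralog_start, sd.paralog_end)
                if (hits(r.binA_start, s) and hits(r.binB_start, p)) or \
                        (hits(r.binA_start, p) and hits(r.binB_start, s)):
                    expect_removed.add((r.binA_start, r.binB_start))
        kept, report = filter_sd_overlap(bis, sds, "paralog_pairs")
        got_removed = set(zip(bis.df.binA_start, bis.df.binB_start)) - \
            set(zip(kept.df.binA_start, kept.df.binB_start))
        assert got_removed == expect_removed
        assert report.removed_rows == len(expect_removed)

    def test_filter_composition_commutes(self, make_links, rng):
        sds = sd_frame([("chrT", 90_000, 130_000, "chrT", 24_090_000, 24_130_000, 0.995)])
        a = rng.integers(0, 1500, 300) * W
        b = a + rng.integers(1, 1500, 300) * W
        df = pd.DataFrame({"binA_start": a, "binB_start": b,
                           "count": rng.integers(0, 40, 300)})
        bis = make_links(list(df.drop_duplicates(["binA_start", "binB_start"])
                              .itertuples(index=False, name=None)))
        first, _ = filter_sd_overlap(filter_count_span(bis, 15, 10_000_000),
                                     sds, "any_sd")
        pre, _ = filter_sd_overlap(bis, sds, "any_sd")
        second = filter_count_span(pre, 15, 10_000_000)
        pd.testing.assert_frame_equal(first.df.reset_index(drop=True),
                                      second.df.reset_index(drop=True))


class TestSimilarityClass:
    @pytest.mark.parametrize("identity,cls", [
        (0.90, "lt98"), (0.979, "lt98"), (0.98, "s98to99"),
        (0.99, "s98to99"), (0.991, "gt99"), (1.0, "gt99")])
    def test_boundaries(self, identity, cls):
        assert similarity_class(identity) == cls

    def test_below_definition_floor(self):
        with pytest.raises(ValueError):
            similarity_class(0.85)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestUniqueMask:
    def test_perfect_duplication_gives_empty_mask(self, rng):
        core = _random_seq(rng, 500)
        seq = _random_seq(rng, 200) + core + _random_seq(rng, 300) + core \
            + _random_seq(rng, 200)
        sds = sd_frame([("c", 200, 700, "c", 1000, 1500, 1.0)])
        mask = build_unique_mask(seq, sds, k=30, max_edits=0, chrom="c")
        assert len(mask.unique_intervals) == 0

    def test_single_substitution_marks_covering_windows(self, rng):
        core = _random_seq(rng, 400)
        mutated = core[:150] + ("A" if core[150] != "A" else "C") + core[151:]
        seq = core + _random_seq(rng, 100) + mutated
        sds = sd_frame([("c", 0, 400, "c", 500, 900, 0.9975)])
        k = 30
        mask = build_unique_mask(seq, sds, k=k, max_edits=0, chrom="c")
        # brute-force oracle: every k-mer counted over the whole genome
        from collections import Counter
        counts = Counter(seq[i:i + k] for i in range(len(seq) - k + 1))
        expect = []
        for s, e in sd_footprint(sds, "c"):
            for p in range(s, e - k + 1):
                if counts[seq[p:p + k]] == 1:
                    expect.append(p)
        got = [p for s, e in mask.unique_intervals for p in range(s, e)]
        assert got == expect
        # unique windows are exactly those covering the substitution site
        assert 0 < len(got) <= 2 * k

    def test_random_genome_matches_hamming_brute_force(self, rng):
        seq = _random_seq(rng, 1_500)
        # plant a 120 bp duplication so near-duplicates exist
        seq = seq[:400] + seq[600:720] + seq[520:]
        sds = sd_frame([("c", 380, 540, "c", 580, 740, 0.95)])
        k, e = 20, 1
        mask = build_unique_mask(seq, sds, k=k, max_edits=e, chrom="c")
        got = {p for s, t in mask.unique_intervals for p in range(s, t)}
        expect = set()
        for s, t in sd_footprint(sds, "c"):
            for p in range(s, t - k + 1):
                kmer = seq[p:p + k]
                n_close = sum(
                    1 for q in range(len(seq) - k + 1) if q != p
                    and sum(a != b for a, b in zip(kmer, seq[q:q + k])) <= e)
                if n_close == 0:
                    expect.add(p)
        assert got == expect

    def test_k_larger_than_regions_warns_empty(self, rng):
        seq = _random_seq(rng, 400)
        sds = sd_frame([("c", 10, 30, "c", 200, 220, 0.99)])
        with pytest.warns(UserWarning):
            mask = build_unique_mask(seq, sds, k=50, chrom="c")
        assert len(mask.unique_intervals) == 0


class TestReadFilter:
    @pytest.fixture
    def sim(self):
        spec = SyntheticGenomeSpec(chrom_name="chrT", chrom_length=400_000,
                                   bin_size=W, sd_pairs={"gt99": 1},
                                   sd_length=30_000, seed=11)
        genome = generate_genome(spec)
        model = ContactModel(base_count_at_1bin=30.0)
        reads = simulate_read_pairs(genome, model, 5_000, mismap_fraction=0.1,
                                    seed=12)
        mask = build_unique_mask(genome.sequence, genome.sds, k=30,
                                 max_edits=0, chrom="chrT")
        return genome, reads, mask

    def test_empty_footprint_retains_all(self, sim):
        from sdspatial.hic import UniqueMask
        _, reads, _ = sim
        empty = UniqueMask("chrT", np.empty((0, 2), np.int64),
                           np.empty((0, 2), np.int64))
        retained, excluded = filter_reads_by_mask(reads, empty)
        assert excluded == 0 and len(retained) == len(reads)

    def test_planted_mismaps_in_nonunique_sequence_are_excluded(self, sim):
        genome, reads, mask = sim
        retained, _ = filter_reads_by_mask(reads, mask)
        mism = reads[reads["flag"] == "mismapped"]
        pos = mism["posB"].to_numpy()
        nonunique = (overlaps_any(pos, pos + 1, mask.footprint)
                     & ~overlaps_any(pos, pos + 1, mask.unique_intervals))
        survivors = set(retained["pair_id"])
        assert all(pid not in survivors
                   for pid in mism["pair_id"].to_numpy()[nonunique])

    def test_never_removes_pairs_fully_outside_footprint(self, sim):
        genome, reads, mask = sim
        retained, _ = filter_reads_by_mask(reads, mask)
        outside = (~overlaps_any(reads["posA"].to_numpy(),
                                 reads["posA"].to_numpy() + 1, mask.footprint)
                   & ~overlaps_any(reads["posB"].to_numpy(),
                                   reads["posB"].to_numpy() + 1, mask.footprint))
        survivors = set(retained["pair_id"])
        assert all(pid in survivors for pid in reads["pair_id"].to_numpy()[outside])


class TestRenormalise:
    def test_self_normalisation_uniform(self):
        # one read pair for every bin pair of a 5-bin chromosome
        rows = [(ia * W + 1, ib * W + 1) for ia in range(5) for ib in range(ia, 5)]
        reads = pd.DataFrame({
            "chromA": "c", "posA": [r[0] for r in rows], "strandA": "+",
            "chromB": "c", "posB": [r[1] for r in rows], "strandB": "-",
            "pair_id": range(len(rows)), "flag": "ok"})
        out = bin_and_renormalise(reads, reads, W, 5 * W, chrom="c")
        assert np.allclose(out.df["count"], 1.0)

    def test_single_stratum_closed_form(self):
        # 2-bin chromosome: 4 unfiltered pairs at distance 1, 2 retained
        def mk(n):
            return pd.DataFrame({
                "chromA": "c", "posA": [10] * n, "strandA": "+",
                "chromB": "c", "posB": [W + 10] * n, "strandB": "-",
                "pair_id": range(n), "flag": "ok"})
        out = bin_and_renormalise(mk(2), mk(4), W, 2 * W, chrom="c")
        assert out.df["count"].tolist() == [0.5]

    def test_thinned_reads_renormalise_flat(self, rng):
        spec = SyntheticGenomeSpec(chrom_name="c", chrom_length=800_000,
                                   bin_size=W, seed=3)
        genome = generate_genome(spec)
        model = ContactModel(decay_exponent=1.0, base_count_at_1bin=30.0)
        reads = simulate_read_pairs(genome, model, 60_000, seed=4)
        keep = rng.random(len(reads)) < 0.5
        out = bin_and_renormalise(reads[keep], reads, W, 800_000, chrom="c")
        # uniform thinning: normalised counts are ~0.5 at every distance
        d = (out.df["binB_start"] - out.df["binA_start"]) // W
        by_d = out.df.groupby(d)["count"].mean()
        big = by_d[np.asarray(by_d.index) <= 10]  # well-populated strata
        assert np.allclose(big, 0.5, atol=0.1)
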