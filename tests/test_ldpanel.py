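"""Binning, r², greedy LD grouping and panel selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from allopanel.io import GenomeIndex, Interval
from allopanel.ldpanel import (
    GenomeBin, SelectionParams, bin_index_of, design_score_surrogate,
    greedy_ld_group, panel_stats, partition_bins, r_squared, select_panel,
    site_id, validate_panel,
)
from allopanel.filtering import minor_allele_frequency
from conftest import make_site


class TestBins:
    def test_truncated_last_bin(self):
        bins = partition_bins(GenomeIndex({"c1": 250_000}), 100_000)
        assert len(bins) == 3
        assert (bins[-1].start, bins[-1].end) == (200_000, 250_000)

    def test_exact_multiple(self):
        assert len(partition_bins(GenomeIndex({"c1": 200_000}), 100_000)) == 2

    def test_half_open_boundary(self):
        # 1-based position 100,001 is 0-based 100,000 -> second bin
        assert bin_index_of(100_001) == 1
        assert bin_index_of(100_000) == 0

    def test_bins_tile_without_overlap(self):
        bins = partition_bins(GenomeIndex({"c1": 330_000, "c2": 90_000}), 100_000)
        by_chrom = {}
        for b in bins:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bs in by_chrom.items():
            assert bs[0].start == 0
            for a, b in zip(bs, bs[1:]):
                assert a.end == b.start


class TestRSquared:
    def test_identical_vectors(self):
        d = np.array([0, 1, 2, 1, 0], float)
        assert r_squared(d, d) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        assert r_squared(np.array([0, 0, 2, 2.0]), np.array([2, 2, 0, 0.0])) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            a = rng.integers(0, 3, 100).astype(float)
            b = rng.integers(0, 3, 100).astype(float)
            if a.var() == 0 or b.var() == 0:
                continue
            am, bm = a - a.mean(), b - b.mean()
            oracle = (am * bm).sum() ** 2 / ((am**2).sum() * (bm**2).sum())
            assert r_squared(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared(np.array([1, 1, 1.0]), np.array([0, 1, 2.0]))

    def test_missing_handled_pairwise_complete(self):
        a = np.array([0, 1, 2, np.nan, 2])
        b = np.array([0, 1, 2, 0, np.nan])
        assert r_squared(a, b) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_allele_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, 30).astype(float)
        b = rng.integers(0, 3, 30).astype(float)
        if a.var() == 0 or b.var() == 0:
            return
        assert r_squared(a, b) == pytest.approx(r_squared(b, a))
        assert r_squared(2 - a, b) == pytest.approx(r_squared(a, b))


class TestGreedyGrouping:
    def _sites_from_dosages(self, dosages, positions):
        sites = []
        for d, p in zip(dosages, positions):
            sites.append(make_site("c1", p, dosages=[int(x) for x in d]))
        return sites

    def test_all_linked_one_group(self):
        d = [0, 0, 1, 1, 2, 2, 0, 1, 2, 0]
        sites = self._sites_from_dosages([d, d, d], [100, 200, 300])
        groups = greedy_ld_group(sites, 0.65, "b0")
        assert len(groups) == 1 and len(groups[0].members) == 3

    def test_all_unlinked_singletons(self):
        rng = np.random.default_rng(2)
        dosages = [rng.integers(0, 3, 60) for _ in range(4)]
        sites = self._sites_from_dosages(dosages, [100, 200, 300, 400])
        groups = greedy_ld_group(sites, 0.999, "b0")
        assert len(groups) == 4

    def test_three_site_hand_trace(self):
        """r2(1,2) and r2(2,3) above threshold, r2(1,3) below, MAF order
        1 > 2 > 3: the greedy takes site 1 as representative (capturing
        site 2), leaving site 3 as its own group."""
        d1 = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2]  # MAF .40
        d2 = [0, 0, 0, 0, 0, 1, 1, 1, 2, 2]  # MAF .35
        d3 = [0, 0, 0, 0, 0, 0, 1, 1, 1, 2]  # MAF .25
        sites = self._sites_from_dosages([d1, d2, d3], [100, 200, 300])
        a, b, c = (np.array(d, float) for d in (d1, d2, d3))
        assert r_squared(a, b) >= 0.65 and r_squared(b, c) >= 0.65
        assert r_squared(a, c) < 0.65
        groups = greedy_ld_group(sites, 0.65, "b0")
        assert [sorted(g.members) for g in groups] == [["c1_100", "c1_200"], ["c1_300"]]
        assert groups[0].representative == "c1_100"

    def test_partition_and_representative_r2_on_simulated_bins(self, small_population):
        pop = small_population
        dos = pop.dosage()
        sites = [s for i, s in enumerate(pop.sites) if dos[i].var() > 0]
        by_bin = {}
        for s in sites:
            by_bin.setdefault(bin_index_of(s.pos), []).append(s)
        for bin_idx, members in by_bin.items():
            groups = greedy_ld_group(members, 0.65, f"c1:{bin_idx}")
            all_members = [m for g in groups for m in g.members]
            assert sorted(all_members) == sorted(site_id(s) for s in members)
            assert len(all_members) == len(set(all_members))  # partition
            lookup = {site_id(s): s for s in members}
            for g in groups:
                rep = lookup[g.representative].alt_dosage()
                for m in g.members:
                    if m == g.representative:
                        continue
                    assert r_squared(rep, lookup[m].alt_dosage()) >= 0.65


class TestDesignScore:
    def test_balanced_sequence_scores_one(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 101)])
        assert design_score_surrogate(seq[:50], seq[50], seq[51:]) in (1.0, 0.8)

    def test_polyA_floors_at_zero(self):
        assert design_score_surrogate("A" * 50, "A", "A" * 50) == 0.0

    def test_single_run_with_balanced_gc(self):
        base = ("ACGT" * 12 + "AC")  # 50 bp, GC 0.5
        flank3 = "A" * 6 + ("GTCA" * 11)  # one 6-bp run (with the SNP 'A' it stays one run)
        seq = base + "C" + flank3
        score = design_score_surrogate(base, "C", flank3)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.30 <= gc <= 0.70
        assert score == pytest.approx(0.8)


def _candidate(chrom, pos, maf_carriers, n=40):
    return make_site(chrom, pos, dosages=[1] * maf_carriers + [0] * (n - maf_carriers))


class TestSelectPanel:
    def _bins(self, lengths):
        return partition_bins(GenomeIndex(lengths), 100_000)

    def test_six_groups_top_five_by_maf(self):
        sites = [_candidate("c1", 1_000 + i * 5_000, 6 + i) for i in range(6)]
        scores = {site_id(s): 1.0 for s in sites}
        groups = [  # six singleton groups
            type("G", (), {"members": [site_id(s)], "group_id": f"g{i}"})()
            for i, s in enumerate(sites)
        ]
        manifest, uncovered = select_panel(
            sites, groups, self._bins({"c1": 100_000}), [], SelectionParams(),
            design_scores=scores,
        )
        assert len(manifest) == 5
        mafs = [minor_allele_frequency(s) for s in sites]
        dropped = sites[int(np.argmin(mafs))]
        assert site_id(dropped) not in {r.marker_id for r in manifest.records}

    def test_single_group_yields_one_probe(self):
        sites = [_candidate("c1", 1_000 + i * 5_000, 6 + i) for i in range(6)]
        scores = {site_id(s): 1.0 for s in sites}
        groups = [type("G", (), {"members": [site_id(s) for s in sites],
                                 "group_id": "g0"})()]
        manifest, _ = select_panel(
            sites, groups, self._bins({"c1": 100_000}), [], SelectionParams(),
            design_scores=scores,
        )
        assert len(manifest) == 1
        assert manifest.records[0].marker_id == site_id(sites[-1])  # highest MAF

    def test_golden_three_bin_trace(self):
        """Hand-traced selection over 3 bins with a QTL boost.

        bin0: six singleton groups, all eligible -> top five by MAF.
        bin1: four sites in one group -> one probe (highest MAF).
        bin2 (QTL window): four sites in two groups -> target 3: one per
        group then recycle by MAF.
        """
        b0 = [_candidate("c1", 1_000 + i * 5_000, 6 + i) for i in range(6)]
        b1 = [_candidate("c1", 101_000 + i * 5_000, 8 + i) for i in range(4)]
        b2 = [_candidate("c1", 601_000 + i * 5_000, 10 + i) for i in range(4)]
        sites = b0 + b1 + b2
        scores = {site_id(s): 1.0 for s in sites}
        groups = [type("G", (), {"members": [site_id(s)], "group_id": f"a{i}"})()
                  for i, s in enumerate(b0)]
        groups.append(type("G", (), {"members": [site_id(s) for s in b1],
                                     "group_id": "b"})())
        groups.append(type("G", (), {"members": [site_id(s) for s in b2[:2]],
                                     "group_id": "c0"})())
        groups.append(type("G", (), {"members": [site_id(s) for s in b2[2:]],
                                     "group_id": "c1"})())
        qtl = [Interval("c1", 610_000, 615_000, "q")]  # window spans bins 4-6
        manifest, uncovered = select_panel(
            sites, groups, self._bins({"c1": 700_000}), qtl, SelectionParams(),
            design_scores=scores,
        )
        assert uncovered == ["c1:2", "c1:3", "c1:4", "c1:5"]  # no candidates there
        got = {r.marker_id for r in manifest.records}
        expect = (
            {site_id(s) for s in b0[1:]}          # five highest MAF of six
            | {site_id(b1[-1])}                   # group exhaustion
            # one per group: best of c0 is b2[1], best of c1 is b2[3];
            # recycle adds next-best overall b2[2]
            | {site_id(b2[1]), site_id(b2[3]), site_id(b2[2])}
        )
        assert got == expect
        assert all(r.category == "qtl" for r in manifest.records if r.bin_id == "c1:6")

    def test_validate_panel_passes_on_selected_manifest(self, small_population):
        from allopanel.filtering import filter_resequencing_snps
        from allopanel.ldpanel import greedy_ld_group as group
        pop = small_population
        survivors, _ = filter_resequencing_snps(list(pop.sites), pop.genome)
        bins = partition_bins(pop.genome.index)
        by_bin = {}
        for s in survivors:
            by_bin.setdefault(f"{s.chrom}:{bin_index_of(s.pos)}", []).append(s)
        groups = []
        for b in bins:
            groups.extend(group(by_bin.get(b.bin_id, []), 0.65, b.bin_id))
        manifest, _ = select_panel(survivors, groups, bins, [], SelectionParams())
        assert validate_panel(manifest, SelectionParams(), groups) == []


class TestPanelStats:
    def _manifest(self, positions, chrom="c1"):
        from allopanel.io import ProbeManifest, ProbeRecord
        recs = [
            ProbeRecord(f"m{i}", chrom, p, "A", "T", "", "", 1.0,
                        "background", f"g{i}", "b0")
            for i, p in enumerate(positions)
        ]
        return ProbeManifest(recs)

    def test_regular_spacing(self):
        stats = panel_stats(self._manifest([1, 10_001, 20_001]),
                            GenomeIndex({"c1": 50_000}))
        assert stats.mean_gap == pytest.approx(10_000)
        assert stats.frac_gaps_gt_100kb == 0.0

    def test_single_large_gap(self):
        stats = panel_stats(self._manifest([1, 150_001]),
                            GenomeIndex({"c1": 200_000}))
        assert stats.frac_gaps_gt_100kb == 1.0

    def test_matches_independent_recomputation(self, small_population):
        from allopanel.filtering import filter_resequencing_snps
        pop = small_population
        survivors, _ = filter_resequencing_snps(list(pop.sites), pop.genome)
        bins = partition_bins(pop.genome.index)
        manifest, _ = select_panel(survivors, [], bins, [], SelectionParams())
        stats = panel_stats(manifest, pop.genome.index)
        pos = sorted(r.pos for r in manifest.records)
        gaps = [b - a for a, b in zip(pos, pos[1:])]
        assert stats.mean_gap == pytest.approx(np.mean(gaps))
        assert stats.n_probes == len(manifest.records)
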