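"""Filter cascades: per-rule statistics, boundary strictness, the
uniqueness search against a dense-scan oracle, audits and idempotence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from allopanel.filtering import (
    FilterParams, FlankUniquenessIndex, call_frequency, enforce_min_spacing,
    filter_array_probes, filter_resequencing_snps, flank_is_clean,
    flank_is_unique, minor_allele_frequency, probe_context,
    second_allele_carriers,
)
from allopanel.io import Genome
from conftest import make_site, random_sequence


class TestSiteStatistics:
    def test_maf_all_heterozygous(self):
        assert minor_allele_frequency(make_site("c", 1, dosages=[1] * 10)) == 0.5

    def test_maf_single_het_of_ten(self):
        site = make_site("c", 1, dosages=[0] * 9 + [1])
        assert minor_allele_frequency(site) == pytest.approx(0.05)

    def test_maf_monomorphic_is_zero(self):
        assert minor_allele_frequency(make_site("c", 1, dosages=[0] * 5)) == 0.0

    def test_maf_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            minor_allele_frequency(make_site("c", 1, dosages=[-1, -1]))

    def test_second_allele_carriers_counts_hets_and_homs(self):
        site = make_site("c", 1, dosages=[1, 1, 2, 0, 0])
        assert second_allele_carriers(site) == 3

    @pytest.mark.parametrize(
        "calls,no_calls,expected", [(80, 20, 0.8), (100, 0, 1.0), (0, 5, 0.0)]
    )
    def test_call_frequency(self, calls, no_calls, expected):
        assert call_frequency(calls, no_calls) == pytest.approx(expected)

    def test_call_frequency_undefined(self):
        with pytest.raises(ValueError):
            call_frequency(0, 0)


class TestFlankClean:
    def test_neighbor_at_exact_halfwidth_is_dirty(self):
        a, b = make_site("c", 1000, dosages=[1]), make_site("c", 1050, dosages=[1])
        assert flank_is_clean(a, [a, b], 50) is False

    def test_neighbor_one_past_halfwidth_is_clean(self):
        a, b = make_site("c", 1000, dosages=[1]), make_site("c", 1051, dosages=[1])
        assert flank_is_clean(a, [a, b], 50) is True

    def test_sole_site_is_clean(self):
        a = make_site("c", 1000, dosages=[1])
        assert flank_is_clean(a, [a], 50) is True


def _mutate(seq, positions, rng):
    out = list(seq)
    for i in positions:
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestFlankUnique:
    def test_single_copy_context_is_unique(self, toy_genome):
        ctx = toy_genome.subseq("c1", 5000 - 50, 5000 + 50)
        assert flank_is_unique(ctx[:50], ctx[50], ctx[51:], toy_genome, "c1", 5000)

    def test_exact_duplicate_elsewhere_not_unique(self, toy_genome):
        seq = toy_genome.sequence("c1")
        ctx = seq[4949:5050]
        dup = seq[:60_000] + ctx + seq[60_101:]
        g = Genome({"c1": dup})
        assert not flank_is_unique(ctx[:50], ctx[50], ctx[51:], g, "c1", 5000)

    @pytest.mark.parametrize("n_mut,expect_unique", [(10, False), (20, True)])
    def test_identity_threshold_boundary(self, toy_genome, n_mut, expect_unique):
        # ~90% identity duplicate must be caught; ~80% must not
        rng = np.random.default_rng(3)
        seq = toy_genome.sequence("c1")
        ctx = seq[4949:5050]
        dup = _mutate(ctx, rng.choice(101, n_mut, replace=False), rng)
        g = Genome({"c1": seq[:60_000] + dup + seq[60_101:]})
        assert flank_is_unique(ctx[:50], ctx[50], ctx[51:], g, "c1", 5000) is expect_unique

    def test_agrees_with_dense_scan_oracle_on_planted_duplicates(self):
        """Seeded search vs an exhaustive every-offset sliding comparison
        for 50 planted duplicates straddling the 85% identity boundary."""
        rng = np.random.default_rng(17)
        seq = random_sequence(rng, 100_000)
        probe_starts = (1000 + np.arange(50) * 800).tolist()  # 1-based
        plant_starts = (60_000 + np.arange(50) * 700).tolist()  # 0-based
        seq_l = list(seq)
        n_muts = [int(rng.integers(0, 25)) for _ in range(50)]
        for ps, ds, m in zip(probe_starts, plant_starts, n_muts):
            dup = _mutate(seq[ps - 1 : ps + 100], rng.choice(101, m, replace=False), rng)
            seq_l[ds : ds + 101] = dup
        genome = Genome({"c1": "".join(seq_l)})
        full = genome.sequence("c1")
        arr = np.frombuffer(full.encode(), dtype=np.uint8)
        index = FlankUniquenessIndex(genome)
        assert index.exact
        for ps in probe_starts:
            probe = full[ps - 1 : ps + 100]
            got = index.has_competing_match(probe, "c1", ps)
            # oracle: dense comparison of the probe at every offset
            pv = np.frombuffer(probe.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(arr, 101)
            mism = (windows != pv).sum(axis=1)
            mism[ps - 1] = 101  # own locus excluded
            assert got == bool((mism <= 15).any())

    def test_truncated_flank_rejected_in_cascade(self, toy_genome):
        site = make_site("c1", 10, dosages=[1] * 12 + [0] * 28)
        assert probe_context(site, toy_genome) is None


class TestMinSpacing:
    def _sites(self, spec):
        # spec: list of (pos, maf) with maf encoded via het carriers of 40
        return [
            make_site("c", pos, dosages=[1] * int(maf * 80) + [0] * (40 - int(maf * 80)))
            for pos, maf in spec
        ]

    def test_conflicting_pair_keeps_higher_maf(self):
        sites = self._sites([(1000, 0.3), (1150, 0.2)])
        kept = enforce_min_spacing(sites, 200)
        assert [s.pos for s in kept] == [1000]

    def test_gap_just_over_threshold_keeps_both(self):
        sites = self._sites([(1000, 0.3), (1201, 0.2)])
        assert [s.pos for s in enforce_min_spacing(sites, 200)] == [1000, 1201]

    def test_chain_greedy_trace(self):
        sites = self._sites([(1000, 0.4), (1150, 0.3), (1300, 0.2)])
        assert [s.pos for s in enforce_min_spacing(sites, 200)] == [1000, 1300]

    def test_greedy_contains_brute_force_top_priority_site(self):
        # on small instances the greedy answer always includes the global
        # top-priority site kept by the exhaustive independent-set search
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 8
            positions = np.sort(rng.choice(3000, n, replace=False)) + 1
            mafs = rng.integers(4, 20, n) / 40
            sites = self._sites(list(zip(positions.tolist(), mafs.tolist())))
            kept = enforce_min_spacing(sites, 200)
            # validity: pairwise spacing respected
            ps = [s.pos for s in kept]
            assert all(b - a > 200 for a, b in zip(ps, ps[1:]))
            top = max(sites, key=lambda s: (minor_allele_frequency(s), -s.pos))
            assert top in kept


class TestResequencingCascade:
    def test_empty_input(self, toy_genome):
        survivors, audit = filter_resequencing_snps([], toy_genome)
        assert survivors == []
        assert all(row[1] == row[3] == 0 for row in audit.steps)

    def test_designed_fixture_exact_survivors(self, cascade_fixture):
        sites, genome, expected = cascade_fixture
        survivors, audit = filter_resequencing_snps(sites, genome)
        assert [row[2] for row in audit.steps] == [1, 1, 1, 1, 1]
        assert {s.pos for s in survivors} == expected
        assert audit.n_survivors == 15

    def test_survivors_satisfy_all_predicates(self, cascade_fixture):
        sites, genome, _ = cascade_fixture
        params = FilterParams()
        survivors, _ = filter_resequencing_snps(sites, genome, params)
        for s in survivors:
            assert len(s.alts) == 1
            assert minor_allele_frequency(s) >= params.maf_min
            assert s.mapping_quality >= params.mq_min
            assert second_allele_carriers(s) >= params.min_second_allele_carriers
            assert flank_is_clean(s, sites, params.flank_halfwidth)
            assert len(s.flank5) == len(s.flank3) == 50

    def test_idempotent(self, cascade_fixture):
        sites, genome, _ = cascade_fixture
        survivors, _ = filter_resequencing_snps(sites, genome)
        again, audit2 = filter_resequencing_snps(survivors, genome)
        assert {s.pos for s in again} == {s.pos for s in survivors}
        assert all(row[2] == 0 for row in audit2.steps)

    def test_audit_conservation(self, small_population):
        pop = small_population
        _, audit = filter_resequencing_snps(list(pop.sites), pop.genome)
        for rule, n_in, n_removed, n_out in audit.steps:
            assert n_in == n_removed + n_out
        for prev, nxt in zip(audit.steps, audit.steps[1:]):
            assert prev[3] == nxt[1]


class TestArrayProbeScreen:
    def _stats(self, rows):
        return pd.DataFrame(
            rows, columns=["marker_id", "chrom", "pos", "call_freq",
                           "cluster_sep", "maf", "unique"]
        )

    def test_call_frequency_strictly_greater(self):
        df = self._stats([("m1", "c1", 1000, 0.8, 0.5, 0.3, True)])
        survivors, _ = filter_array_probes(df)
        assert len(survivors) == 0  # 0.8 exactly fails the strict rule

    def test_cluster_sep_boundary_inclusive(self):
        df = self._stats([("m1", "c1", 1000, 0.9, 0.15, 0.3, True)])
        survivors, _ = filter_array_probes(df)
        assert len(survivors) == 1  # 0.15 exactly passes

    def test_ten_marker_fixture_with_four_violations(self):
        rows = [
            ("m0", "c1", 1_000, 0.95, 0.5, 0.30, True),
            ("m1", "c1", 5_000, 0.75, 0.5, 0.30, True),   # call freq fails
            ("m2", "c1", 9_000, 0.95, 0.10, 0.30, True),  # cluster sep fails
            ("m3", "c1", 13_000, 0.95, 0.5, 0.04, True),  # maf fails
            ("m4", "c1", 17_000, 0.95, 0.5, 0.30, False), # uniqueness fails
            ("m5", "c1", 21_000, 0.95, 0.5, 0.30, True),
            ("m6", "c1", 25_000, 0.95, 0.5, 0.30, True),
            ("m7", "c1", 29_000, 0.95, 0.5, 0.30, True),
            ("m8", "c1", 33_000, 0.95, 0.5, 0.30, True),
            ("m9", "c1", 37_000, 0.95, 0.5, 0.30, True),
        ]
        survivors, audit = filter_array_probes(self._stats(rows))
        assert len(survivors) == 6
        assert [row[2] for row in audit.steps] == [1, 1, 1, 1, 0]

    def test_spacing_rule_drops_lower_maf(self):
        rows = [
            ("m0", "c1", 1_000, 0.95, 0.5, 0.30, True),
            ("m1", "c1", 1_150, 0.95, 0.5, 0.20, True),
        ]
        survivors, _ = filter_array_probes(self._stats(rows))
        assert list(survivors["marker_id"]) == ["m0"]

    @given(
        seps=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
    )
    def test_audit_conservation_property(self, seps):
        rows = [
            (f"m{i}", "c1", 1000 + 400 * i, 0.9, s, 0.3, True)
            for i, s in enumerate(seps)
        ]
        survivors, audit = filter_array_probes(self._stats(rows))
        assert audit.steps[0][1] == len(rows)
        for rule, n_in, n_removed, n_out in audit.steps:
            assert n_in == n_removed + n_out
        assert audit.n_survivors == len(survivors)
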