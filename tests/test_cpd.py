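import numpy as np
import pandas as pd
import pytest

import reptimemut as rm
from reptimemut.cpd import AssignedDamage, _bin_sums
from reptimemut.errors import DomainError


class TestAssignLesionPositions:
    def test_both_positions_plus_strand(self):
        genome = rm.GenomeSequence({"chrI": "A" * 10 + "TT" + "A" * 10})
        prof = rm.CpdProfile()
        prof.add("chrI", 10, "+", 3)
        assigned = rm.assign_lesion_positions(prof, genome)
        arr = assigned.per_chrom["chrI"]
        assert arr[10] == 3 and arr[11] == 3 and arr.sum() == 6

    def test_minus_strand_partner_is_previous_position(self):
        # reference purine pair = dipyrimidine on the minus strand; lesion
        # coordinate is its 5' base on the lesion strand (higher ref coord)
        genome = rm.GenomeSequence({"chrI": "T" * 10 + "AG" + "T" * 10})
        prof = rm.CpdProfile()
        prof.add("chrI", 11, "-", 2)
        assigned = rm.assign_lesion_positions(prof, genome)
        arr = assigned.per_chrom["chrI"]
        assert arr[11] == 2 and arr[10] == 2

    def test_empty_profile_all_zero(self, toy_genome):
        assigned = rm.assign_lesion_positions(rm.CpdProfile(), toy_genome)
        assert assigned.total() == 0

    def test_doubling_identity_random_profiles(self):
        rng = np.random.default_rng(2)
        genome = rm.GenomeSequence(
            {"c": "".join(rng.choice(list("ACGT"), size=500))}
        )
        for _ in range(20):
            prof = rm.CpdProfile()
            n = 0
            for pos in rng.choice(np.arange(1, 498), size=30, replace=False):
                c = int(rng.integers(1, 5))
                prof.add("c", int(pos), rng.choice(["+", "-"]), c)
                n += c
            assigned = rm.assign_lesion_positions(prof, genome)
            assert assigned.total() == 2 * n

    def test_chromosome_end_lesion_assigned_once(self):
        genome = rm.GenomeSequence({"c": "TTTT"})
        prof = rm.CpdProfile()
        prof.add("c", 3, "+", 5)  # partner would be position 4: off the end
        assigned = rm.assign_lesion_positions(prof, genome)
        assert assigned.total() == 5
        assert assigned.n_end_clipped == 1


@pytest.fixture(scope="module")
def damage_setup():
    cfg = rm.SimConfig(
        seed=21,
        n_chroms=3,
        chrom_length=20_000,
        cpd_rate=0.04,
        repeat_region=None,
        n_mutations=0,
    )
    genome = rm.gen_genome(cfg)
    tmap = rm.gen_timing_map(cfg, genome)
    bins = rm.compute_bins(tmap)
    census = rm.trinucleotide_bin_census(genome, tmap, bins)
    t0, trep = rm.gen_cpd(cfg, genome, tmap, bins)
    assigned = rm.assign_lesion_positions(t0, genome)
    return genome, tmap, bins, census, t0, trep, assigned


class TestDamageBinSummary:
    def test_percent_sums_to_100(self, damage_setup):
        genome, tmap, bins, census, *_, assigned = damage_setup
        summary = rm.damage_bin_summary(assigned, tmap, bins, census)
        assert summary.table["percent_of_total"].sum() == pytest.approx(100, abs=1e-6)

    def test_matches_per_position_oracle(self, damage_setup):
        genome, tmap, bins, census, *_, assigned = damage_setup
        summary = rm.damage_bin_summary(assigned, tmap, bins, census)
        chrom = genome.chrom_names[0]
        oracle = {"early": 0.0, "middle": 0.0, "late": 0.0}
        for c, arr in assigned.per_chrom.items():
            for pos in np.flatnonzero(arr):
                t = rm.interpolate_time(tmap, c, int(pos))
                if not np.isnan(t):
                    oracle[rm.classify(t, bins)] += arr[pos]
        for lbl, v in oracle.items():
            assert summary.table.loc[lbl, "assigned_count"] == v

    def test_mask_partition_of_totals(self, damage_setup):
        genome, tmap, bins, census, *_, assigned = damage_setup
        region = rm.RegionMask([("chr01", 5_000, 9_000)])
        full = _bin_sums(assigned, tmap, bins, None).sum()
        outside = _bin_sums(assigned, tmap, bins, region).sum()
        # inside contribution measured independently, per position
        inside = 0.0
        arr = assigned.per_chrom["chr01"]
        for pos in range(5_000, 9_000):
            if not np.isnan(rm.interpolate_time(tmap, "chr01", pos)):
                inside += arr[pos]
        assert outside == pytest.approx(full - inside)

    def test_all_damage_one_bin(self, toy_genome):
        # map where every covered time lands in one tercile
        tmap = rm.TimingMap({"chrI": [(2, 5.0), (38, 6.0)]})
        bins = rm.ReplicationBins(10.0, 20.0)
        census = rm.trinucleotide_bin_census(toy_genome, tmap, bins)
        prof = rm.CpdProfile()
        prof.add("chrI", 4, "+", 7)
        assigned = rm.assign_lesion_positions(prof, toy_genome)
        summary = rm.damage_bin_summary(assigned, tmap, bins, census)
        assert list(summary.table["percent_of_total"]) == [100.0, 0.0, 0.0]

    def test_zero_damage_errors(self, damage_setup):
        genome, tmap, bins, census, *_ = damage_setup
        empty = rm.assign_lesion_positions(rm.CpdProfile(), genome)
        with pytest.raises(DomainError):
            rm.damage_bin_summary(empty, tmap, bins, census)


class TestRepairFraction:
    def make_summary(self, counts, label):
        table = pd.DataFrame(
            {
                "assigned_count": counts,
                "percent_of_total": 100 * np.asarray(counts) / sum(counts),
                "dipyrimidine_percent": [33.0, 33.0, 34.0],
            },
            index=["early", "middle", "late"],
        )
        from reptimemut.cpd import DamageBinSummary

        return DamageBinSummary(label, table)

    def test_identical_counts_give_one(self):
        s = self.make_summary([10, 20, 30], "0h")
        t = self.make_summary([10, 20, 30], "2h")
        assert rm.repair_fraction(t, s, "none").tolist() == [1.0, 1.0, 1.0]

    def test_halved_counts_give_half(self):
        s = self.make_summary([10, 20, 30], "0h")
        t = self.make_summary([5, 10, 15], "2h")
        assert rm.repair_fraction(t, s, "none").tolist() == [0.5, 0.5, 0.5]

    def test_library_size_normalisation_cancels_global_downsampling(self):
        s = self.make_summary([100, 200, 300], "0h")
        t = self.make_summary([10, 20, 30], "2h")  # uniform 10x downsample
        np.testing.assert_allclose(
            rm.repair_fraction(t, s, "library_size").to_numpy(), 1.0
        )

    def test_zero_baseline_bin_flagged_nan(self):
        s = self.make_summary([0, 20, 30], "0h")
        t = self.make_summary([5, 10, 15], "2h")
        frac = rm.repair_fraction(t, s, "none")
        assert np.isnan(frac["early"]) and frac["middle"] == 0.5

    def test_thinning_recovers_survival(self, damage_setup):
        genome, tmap, bins, census, t0, trep, assigned = damage_setup
        s0 = rm.damage_bin_summary(assigned, tmap, bins, census, label="0h")
        st = rm.damage_bin_summary(
            rm.assign_lesion_positions(trep, genome), tmap, bins, census, label="2h"
        )
        frac = rm.repair_fraction(st, s0, "none")
        # generator thins with survival 0.3 per bin
        n0 = s0.counts.to_numpy()
        se = 3 * np.sqrt(0.3 * 0.7 / (n0 / 2))  # per-lesion binomial, 3 sigma
        assert np.all(np.abs(frac.to_numpy() - 0.3) < se)


class TestWindowScan:
    def test_tiling_and_last_short_window(self, damage_setup):
        _, tmap, bins, *_ = damage_setup
        assigned = AssignedDamage({"c": np.zeros(2_500)})
        track = rm.window_scan(assigned, tmap, bins, width=1_000)
        assert [(w.start, w.end) for w in track.itertuples()] == [
            (0, 1_000),
            (1_000, 2_000),
            (2_000, 2_500),
        ]

    def test_count_conservation(self, damage_setup):
        genome, tmap, bins, _, _, _, assigned = damage_setup
        track = rm.window_scan(assigned, tmap, bins, width=1_000)
        assert track["count"].sum() == assigned.total()

    def test_uncovered_window_unavailable(self, damage_setup):
        genome, tmap, bins, *_ = damage_setup
        # a chromosome unknown to the timing map is entirely uncovered
        assigned = AssignedDamage({"orphan": np.ones(1_500)})
        track = rm.window_scan(assigned, tmap, bins, width=1_000)
        assert set(track["bin_label"]) == {"unavailable"}

    def test_single_bin_windows_labelled(self, damage_setup):
        genome, tmap, bins, _, _, _, assigned = damage_setup
        track = rm.window_scan(assigned, tmap, bins, width=1_000)
        labels = set(track["bin_label"])
        assert labels <= {"early", "middle", "late", "mixed", "unavailable"}
        # chromosome ends are not timing-covered -> boundary windows mixed
        first = track.iloc[0]
        assert first["bin_label"] in ("mixed", "unavailable")


class TestRepeatCollapseScore:
    def make_track(self, counts, chrom="c", width=100):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(len(counts)) * width,
                "end": (np.arange(len(counts)) + 1) * width,
                "count": counts,
                "bin_label": "early",
            }
        )

    def test_uniform_counts_score_one(self):
        track = self.make_track([5.0] * 20)
        score = rm.repeat_collapse_score(track, rm.RegionMask([("c", 500, 800)]))
        assert score == pytest.approx(1.0)

    def test_tenfold_inside(self):
        counts = [2.0] * 20
        for i in (5, 6, 7):
            counts[i] = 20.0
        track = self.make_track(counts)
        score = rm.repeat_collapse_score(track, rm.RegionMask([("c", 500, 800)]))
        assert score == pytest.approx(10.0)

    def test_no_overlap_errors(self):
        track = self.make_track([1.0] * 5)
        with pytest.raises(DomainError):
            rm.repeat_collapse_score(track, rm.RegionMask([("other", 0, 100)]))

    def test_collapse_recovered_from_generator(self):
        cfg = rm.SimConfig(
            seed=33,
            n_chroms=2,
            chrom_length=40_000,
            cpd_rate=0.05,
            repeat_region=("chr02", 10_000, 14_000),
            copy_number=150,
            reference_copies=2,
            n_mutations=0,
        )
        genome = rm.gen_genome(cfg)
        tmap = rm.gen_timing_map(cfg, genome)
        bins = rm.compute_bins(tmap)
        t0, _ = rm.gen_cpd(cfg, genome, tmap, bins)
        assigned = rm.assign_lesion_positions(t0, genome)
        track = rm.window_scan(assigned, tmap, bins, width=1_000)
        score = rm.repeat_collapse_score(
            track, rm.RegionMask([("chr02", 10_000, 14_000)])
        )
        assert score == pytest.approx(75.0, rel=0.08)
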