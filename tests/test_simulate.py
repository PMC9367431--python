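"""Simulator unit and property tests (determinism, truth bookkeeping)."""

import numpy as np
import pytest

from genomesurvey import simulate
from genomesurvey.simulate import PsmcTruth, SimParams
from genomesurvey.ssr import find_ssrs
from genomesurvey.psmc import parse_psmc_output, scale_trajectory


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestDiploidGenome:
    def test_seed_determinism(self):
        p = SimParams(genome_length=20_000, het_rate=0.005, repeat_fraction=0.2, seed=7)
        g1 = simulate.simulate_diploid_genome(p)
        g2 = simulate.simulate_diploid_genome(p)
        assert g1.hap1 == g2.hap1 and g1.hap2 == g2.hap2
        assert g1.het_sites == g2.het_sites

    def test_zero_het_identity(self):
        p = SimParams(genome_length=10_000, het_rate=0.0, repeat_fraction=0.0, seed=1)
        g = simulate.simulate_diploid_genome(p)
        assert g.hap1 == g.hap2
        assert g.het_sites == []

    def test_het_sites_enumerate_mismatches(self):
        p = SimParams(genome_length=30_000, het_rate=0.01, repeat_fraction=0.0, seed=2)
        g = simulate.simulate_diploid_genome(p)
        mismatches = [i + 1 for i, (a, b) in enumerate(zip(g.hap1, g.hap2)) if a != b]
        assert mismatches == g.het_sites

    def test_het_count_within_binomial_bounds(self):
        # over 20 seeds the site count stays within 4 SD of n*p
        n, p = 50_000, 0.005
        sd = (n * p * (1 - p)) ** 0.5
        for seed in range(20):
            g = simulate.simulate_diploid_genome(
                SimParams(genome_length=n, het_rate=p, repeat_fraction=0.0, seed=seed)
            )
            assert abs(len(g.het_sites) - n * p) < 4 * sd

    def test_repeat_intervals_are_duplicated_blocks(self):
        p = SimParams(
            genome_length=40_000, het_rate=0.0, repeat_fraction=0.3,
            repeat_unit_length=400, seed=3,
        )
        g = simulate.simulate_diploid_genome(p)
        covered = sum(e - s + 1 for s, e in g.repeat_intervals)
        assert covered == pytest.approx(0.3 * 40_000, rel=0.05)
        blocks = sorted(g.hap1[s - 1 : e] for s, e in g.repeat_intervals)
        # every block appears exactly twice
        assert all(blocks[i] == blocks[i + 1] for i in range(0, len(blocks), 2))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(genome_length=100, repeat_unit_length=500)
        with pytest.raises(ValueError):
            SimParams(het_rate=0.2)
        with pytest.raises(ValueError):
            SimParams(repeat_fraction=0.95)


class TestReads:
    def test_read_count_formula(self):
        p = SimParams(genome_length=5_000, het_rate=0.0, repeat_fraction=0.0, seed=4)
        g = simulate.simulate_diploid_genome(p)
        rs = simulate.simulate_reads(g, coverage=30, read_length=150, error_rate=0, seed=5)
        assert len(rs.reads) == round(30 * 5_000 / 150)
        assert all(len(seq) == 150 for _, seq, _ in rs.reads)

    def test_error_free_reads_are_substrings(self):
        p = SimParams(genome_length=4_000, het_rate=0.0, repeat_fraction=0.0, seed=6)
        g = simulate.simulate_diploid_genome(p)
        rs = simulate.simulate_reads(g, coverage=5, read_length=80, error_rate=0, seed=7)
        rc = revcomp(g.hap1)
        for _, seq, _ in rs.reads:
            assert seq in g.hap1 or seq in rc

    def test_seed_determinism(self):
        p = SimParams(genome_length=4_000, het_rate=0.003, repeat_fraction=0.0, seed=8)
        g = simulate.simulate_diploid_genome(p)
        r1 = simulate.simulate_reads(g, coverage=5, read_length=80, error_rate=0.01, seed=9)
        r2 = simulate.simulate_reads(g, coverage=5, read_length=80, error_rate=0.01, seed=9)
        assert r1.reads == r2.reads

    def test_invalid_coverage_rejected(self):
        p = SimParams(genome_length=4_000, het_rate=0.0, repeat_fraction=0.0, seed=1)
        g = simulate.simulate_diploid_genome(p)
        with pytest.raises(ValueError):
            simulate.simulate_reads(g, coverage=0, read_length=80)
        with pytest.raises(ValueError):
            simulate.simulate_reads(g, coverage=5, read_length=5_000)


class TestPlantSsrs:
    def test_empty_spec_is_identity(self):
        seq = simulate.random_dna(1_000, seed=0)
        out, truth = simulate.plant_ssrs(seq, [], seed=1)
        assert out == seq and truth == []

    def test_planted_arrays_recovered_by_scanner(self):
        bg = simulate.random_dna(100_000, seed=10)
        out, truth = simulate.plant_ssrs(bg, [("AC", 8, 10)], seed=11)
        found = {(r.motif, r.repeats, r.start, r.end) for r in find_ssrs(out)}
        assert len(truth) == 10
        for t in truth:
            assert (t.motif, t.repeats, t.start, t.end) in found

    def test_truth_coordinates_match_sequence(self):
        bg = simulate.random_dna(20_000, seed=12)
        out, truth = simulate.plant_ssrs(bg, [("AAAT", 5, 5), ("CAG", 7, 5)], seed=13)
        for t in truth:
            assert out[t.start - 1 : t.end] == t.motif * t.repeats

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            simulate.plant_ssrs("ACGT" * 20, [("AC", 6, 50)], seed=0)

    def test_degenerate_motif_rejected(self):
        with pytest.raises(ValueError):
            simulate.plant_ssrs(simulate.random_dna(1000, 0), [("ATAT", 5, 1)], seed=0)

    def test_random_dna_suppresses_tandems(self):
        seq = simulate.random_dna(30_000, seed=14, max_tandem=3)
        assert not find_ssrs(seq, {p: 4 for p in range(2, 7)})


class TestMitoFixture:
    def test_layout_census(self, mito_fixture):
        types = {}
        strands = {"H": 0, "L": 0}
        for f in mito_fixture.annotation.features:
            types[f.ftype] = types.get(f.ftype, 0) + 1
            strands[f.strand] += 1
        assert types == {"PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1}
        assert strands["L"] == 9  # ND6 plus eight tRNAs

    def test_sequence_length_matches_annotation(self, mito_fixture):
        assert len(mito_fixture.sequence) == mito_fixture.annotation.genome_length
        assert len(mito_fixture.sequence) == 16_532

    def test_expected_codons_recorded(self, mito_fixture):
        exp = mito_fixture.expected_codons
        assert exp["COI"][0] == "GTG"
        assert exp["ATP6"][0] == "ATA"
        assert sum(1 for s, _, _ in exp.values() if s == "ATG") == 11
        assert sum(1 for _, _, c in exp.values() if c == "incomplete") == 6

    def test_determinism(self):
        f1 = simulate.make_mito_fixture(seed=5)
        f2 = simulate.make_mito_fixture(seed=5)
        assert f1.sequence == f2.sequence


class TestPsmcOutput:
    def test_constant_trajectory_writes_unit_lambdas(self):
        truth = PsmcTruth(theta0=0.02, intervals=[(0.0, 1.0), (0.5, 1.0), (1.0, 1.0)])
        text = simulate.make_psmc_output(truth)
        lams = [float(l.split()[3]) for l in text.splitlines() if l.startswith("RS")]
        assert lams == [1.0, 1.0, 1.0]

    def test_round_trip_reproduces_truth(self):
        truth = PsmcTruth(
            theta0=0.0123,
            intervals=[(0.0, 0.7), (0.05, 1.4), (0.3, 0.2), (2.0, 1.1)],
            u=2.5e-8, s=100.0, g=1.0,
        )
        res = parse_psmc_output(simulate.make_psmc_output(truth, n_rounds=4))
        traj = scale_trajectory(res, u=truth.u, s=truth.s, g=truth.g)
        years, ne = truth.ne_trajectory()
        assert np.allclose(traj.years, years, rtol=1e-9)
        assert np.allclose(traj.ne, ne, rtol=1e-9)

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            PsmcTruth(theta0=0.01, intervals=[(0.0, 1.0), (0.5, 1.0), (0.5, 2.0)])
        with pytest.raises(ValueError):
            PsmcTruth(theta0=0.01, intervals=[(0.1, 1.0)])
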