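"""SSR scanner, compound merging and census tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genomesurvey.ssr import (
    SSRRecord,
    canonical_motif,
    find_ssrs,
    merge_compound,
    minimal_period,
    summarize_ssrs,
)
from helpers import brute_force_ssrs, random_ssr_rich_sequence

MIN_REPEATS = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


def revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class TestFindSsrs:
    def test_dinucleotide_run(self):
        recs = find_ssrs("ACACACACACAC")
        assert len(recs) == 1
        r = recs[0]
        assert (r.ssr_type, r.motif, r.repeats, r.start, r.end) == ("p2", "AC", 6, 1, 12)
        assert r.standardized == "(AC)6"

    def test_below_threshold_not_reported(self):
        assert find_ssrs("ATATATATAT") == []  # 5 x AT, below the di threshold of 6

    def test_dominant_tetranucleotide(self):
        recs = find_ssrs("AAATAAATAAATAAATAAAT")
        assert len(recs) == 1
        assert (recs[0].ssr_type, recs[0].motif, recs[0].repeats) == ("p4", "AAAT", 5)

    def test_motif_classified_at_minimal_period(self):
        # (ATAT)x candidates collapse to the dinucleotide record
        recs = find_ssrs("ATATATATATATAT")  # AT x 7
        assert len(recs) == 1
        assert recs[0].ssr_type == "p2" and recs[0].motif == "AT"

    def test_homopolymers_never_reported(self):
        assert find_ssrs("A" * 40) == []

    def test_partial_trailing_copy_excluded(self):
        recs = find_ssrs("ACACACACACACA")  # AC x 6 plus a dangling A
        assert recs[0].end == 12 and recs[0].repeats == 6

    def test_n_breaks_runs(self):
        assert find_ssrs("ACACACACACNACACACACAC") == []  # 5 + 5.x copies, both short
        recs = find_ssrs("ACACACACACACNACAC")
        assert len(recs) == 1 and recs[0].start == 1

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError, match="non-DNA"):
            find_ssrs("ACGTXACGT")

    def test_phase_preserved(self):
        recs = find_ssrs("G" + "CA" * 7)
        assert recs[0].motif == "CA"

    def test_coordinate_validity_and_length_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = random_ssr_rich_sequence(rng)
            for r in find_ssrs(seq):
                assert 1 <= r.start <= r.end <= len(seq)
                assert r.length == len(r.motif) * r.repeats
                assert seq[r.start - 1 : r.end] == r.motif * r.repeats

    def test_oracle_equivalence_sample(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            seq = random_ssr_rich_sequence(rng)
            got = sorted(
                (r.start - 1, r.end - 1, int(r.ssr_type[1]), r.motif, r.repeats)
                for r in find_ssrs(seq, MIN_REPEATS)
            )
            assert got == brute_force_ssrs(seq, MIN_REPEATS)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=200))
    def test_reverse_complement_symmetry(self, seq):
        fwd = find_ssrs(seq)
        rev = find_ssrs(revcomp(seq))
        assert len(fwd) == len(rev)
        # motifs map to reverse-complement phase variants with mirrored coords
        fwd_keys = sorted((canonical_motif(r.motif), r.repeats) for r in fwd)
        rev_keys = sorted((canonical_motif(r.motif), r.repeats) for r in rev)
        assert fwd_keys == rev_keys


class TestMergeCompound:
    def _rec(self, motif, repeats, start, seq_id="seq"):
        end = start + len(motif) * repeats - 1
        return SSRRecord(
            seq_id=seq_id, index=0, ssr_type=f"p{len(motif)}", motif=motif,
            repeats=repeats, start=start, end=end, standardized=f"({motif}){repeats}",
        )

    def test_merge_with_interruption_string(self):
        seq = "ACACACACACAC" + "TT" + "GAGAGAGAGA"
        recs = [self._rec("AC", 6, 1), self._rec("GA", 5, 15)]
        merged = merge_compound(recs, 100, sequence=seq)
        assert len(merged) == 1
        c = merged[0]
        assert (c.ssr_type, c.start, c.end) == ("c", 1, 24)
        assert c.standardized == "(AC)6tt(GA)5"
        assert len(c.constituents) == 2

    def test_single_record_unchanged(self):
        recs = [self._rec("AC", 6, 10)]
        merged = merge_compound(recs, 100)
        assert len(merged) == 1 and merged[0].ssr_type == "p2"

    def test_gap_boundary(self):
        # gap of exactly 100 merges; 101 does not
        r1 = self._rec("AC", 6, 1)
        merged = merge_compound([r1, self._rec("GA", 5, 113)], 100)
        assert merged[0].ssr_type == "c"
        kept = merge_compound([r1, self._rec("GA", 5, 114)], 100)
        assert [r.ssr_type for r in kept] == ["p2", "p2"]

    def test_chained_merge(self):
        recs = [self._rec("AC", 6, 1), self._rec("GA", 5, 20), self._rec("CT", 6, 40)]
        merged = merge_compound(recs, 100)
        assert len(merged) == 1 and len(merged[0].constituents) == 3


class TestSummarize:
    def test_density_formula(self):
        recs = [
            SSRRecord("s", i, "p2", "AC", 6, 1 + 20 * i, 12 + 20 * i, "(AC)6")
            for i in range(10)
        ]
        summary = summarize_ssrs(recs, sequences_examined=1, total_length=2_000_000)
        assert summary.density_per_mb == pytest.approx(5.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(9)
        records = []
        for i in range(200):
            motif = {2: "AC", 3: "AAT", 4: "AAAT", 5: "AACGT", 6: "AACGTT"}[
                int(rng.integers(2, 7))
            ]
            records.append(
                SSRRecord(f"s{i%7}", i, f"p{len(motif)}", motif, 6,
                          1, len(motif) * 6, "")
            )
        summary = summarize_ssrs(records, 7, 10_000_000)
        assert sum(summary.type_percentages.values()) == pytest.approx(100.0, abs=1e-6)
        flat = [v for d in summary.motif_percentages.values() for v in d.values()]
        assert sum(flat) == pytest.approx(100.0, abs=1e-6)
        assert summary.total_ssrs == sum(summary.type_counts.values())

    def test_compound_constituents_counted(self):
        seq = "ACACACACACAC" + "TT" + "GAGAGAGAGA"
        recs = [
            SSRRecord("s", 1, "p2", "AC", 6, 1, 12, "(AC)6"),
            SSRRecord("s", 2, "p2", "GA", 5, 15, 24, "(GA)5"),
        ]
        merged = merge_compound(recs, 100, sequence=seq)
        summary = summarize_ssrs(merged, 1, len(seq))
        assert summary.total_ssrs == 2
        assert summary.compound_ssrs == 2
        assert summary.sequences_with_more_than_one_ssr == 1

    def test_invalid_total_length(self):
        with pytest.raises(ValueError):
            summarize_ssrs([], 1, 0)


def test_minimal_period():
    assert minimal_period("ATAT") == 2
    assert minimal_period("AAAA") == 1
    assert minimal_period("AAT") == 3
    assert minimal_period("ACGTAC") == 6
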