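"""UR complement, labelling, report arithmetic and tandem repeats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arkmito.genome_io import Feature, GenomeRecord, rotate_genome
from arkmito.synthetic_data import SANITIZE_MAX_PERIOD, SANITIZE_MIN_REPEAT_LEN
from arkmito.ur_analysis import (
    extract_urs,
    find_tandem_repeats,
    label_shared_urs,
    repeat_statistics,
    round_pct,
    ur_report,
)

from .oracles import repeat_enumerate


def _genome(length, feats, circular=True):
    return GenomeRecord("G", "sp", "A" * length, circular, feats)


class TestExtractUrs:
    def test_single_feature_complement_wraps(self):
        rec = _genome(100, [Feature("gene", "g", 10, 20)])
        urs = extract_urs(rec)
        assert len(urs) == 1
        assert urs[0].wraps and urs[0].length_nt == 90

    def test_full_tiling_gives_no_urs(self):
        rec = _genome(30, [Feature("gene", "a", 0, 15), Feature("gene", "b", 15, 30)])
        assert extract_urs(rec) == []

    def test_overlapping_features_cannot_create_negative_gaps(self):
        rec = _genome(50, [Feature("gene", "a", 0, 30), Feature("tRNA", "t", 25, 35)])
        urs = extract_urs(rec)
        assert sum(u.length_nt for u in urs) == 15

    def test_zero_length_genome_errors(self):
        with pytest.raises(ValueError):
            extract_urs(_genome(0, []))

    @given(st.integers(2, 40), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_property(self, n_feats, data):
        """Sum of UR lengths + feature-union cover = genome length."""
        length = data.draw(st.integers(50, 400))
        feats = []
        for i in range(n_feats):
            s = data.draw(st.integers(0, length - 1))
            span = data.draw(st.integers(1, length - 1))
            if s + span <= length:
                feats.append(Feature("gene", f"g{i}", s, s + span))
            else:
                feats.append(Feature("gene", f"g{i}", s, (s + span) % length, wraps=True))
        rec = _genome(length, feats)
        covered = set()
        for f in feats:
            covered.update(f.positions(length))
        urs = extract_urs(rec)
        assert sum(u.length_nt for u in urs) + len(covered) == length

    def test_rotation_invariance(self, small_genome):
        rec, _ = small_genome
        base = sorted(u.length_nt for u in extract_urs(rec))
        for k in (1, 137, 4000):
            rot = rotate_genome(rec, k)
            assert sorted(u.length_nt for u in extract_urs(rot)) == base


class TestLabelling:
    def test_ur1_between_cox2b_and_nad6(self, small_genome):
        rec, truth = small_genome
        urs = label_shared_urs(extract_urs(rec), rec)
        ur1 = [u for u in urs if u.label == "UR1"]
        assert len(ur1) == 1
        assert ur1[0].upstream_gene == "cox2-b" and ur1[0].downstream_gene == "nad6"
        assert [ur1[0].start, ur1[0].end] == truth.ur_spans["UR1"][:2]

    def test_ur2_wraps_origin(self, small_genome):
        rec, truth = small_genome
        urs = label_shared_urs(extract_urs(rec), rec)
        ur2 = [u for u in urs if u.label == "UR2"]
        assert len(ur2) == 1 and ur2[0].wraps
        assert ur2[0].upstream_gene == "nad2" and ur2[0].downstream_gene == "cox1"

    def test_missing_flank_leaves_intergenic(self):
        rec = _genome(100, [Feature("gene", "somegene", 10, 20)])
        urs = label_shared_urs(extract_urs(rec), rec)
        assert all(u.label == "intergenic" for u in urs)


class TestReport:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (28908, 44333, 65.21),
            (14034, 46362, 30.27),
            (41101, 56170, 73.17),
            (33004, 48161, 68.53),
            (0, 44333, 0.0),
        ],
    )
    def test_percentages_half_up(self, num, den, expected):
        assert round_pct(num, den) == expected

    def test_report_row_consistency(self, small_genome):
        rec, _ = small_genome
        row = ur_report([rec])[0]
        assert row.total_ur_len == row.ur1_len + row.ur2_len + row.intergenic_len
        assert row.ur_pct == round_pct(row.total_ur_len, row.genome_size)


class TestTandemRepeats:
    def test_simple_run(self):
        reps = find_tandem_repeats("ACGACGACGACG")
        assert len(reps) == 1
        r = reps[0]
        assert (r.period, r.unit, r.copies, r.total_len) == (3, "ACG", 4.0, 12)

    def test_homopolymer_reported_once_at_period_one(self):
        reps = find_tandem_repeats("AAAAAA")
        assert len(reps) == 1
        assert (reps[0].period, reps[0].copies) == (1, 6.0)

    def test_fractional_trailing_copy(self):
        reps = find_tandem_repeats("ACGTACGTACG", min_total_len=8)
        assert any(r.period == 4 and r.copies == pytest.approx(11 / 4) for r in reps)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("")

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 600))
        seq = "".join(rng.choice(list("ACGT"), size=n, p=[0.35, 0.15, 0.15, 0.35]))
        ours = [(r.start, r.period, r.unit, r.copies, r.total_len)
                for r in find_tandem_repeats(seq, max_period=50)]
        assert sorted(ours) == repeat_enumerate(seq, max_period=50)

    def test_planted_mixture_equals_generator_truth(self, small_genome):
        rec, truth = small_genome
        from arkmito.ur_analysis import extract_urs

        found = []
        for u in extract_urs(rec):
            seq = (rec.sequence[u.start :] + rec.sequence[: u.end]
                   if u.wraps else rec.sequence[u.start : u.end])
            for r in find_tandem_repeats(seq, max_period=SANITIZE_MAX_PERIOD,
                                         min_total_len=SANITIZE_MIN_REPEAT_LEN):
                found.append(((u.start + r.start) % rec.length_nt, r.period,
                              r.copies, r.total_len))
        expected = sorted((t["start"], t["period"], t["copies"], t["total_len"])
                          for t in truth.repeats)
        assert sorted(found) == expected

    def test_statistics_pct_of_urs(self, small_genome):
        rec, truth = small_genome
        rows = repeat_statistics([rec], max_period=SANITIZE_MAX_PERIOD,
                                 min_total_len=SANITIZE_MIN_REPEAT_LEN)
        total_planted = sum(t["total_len"] for t in truth.repeats)
        assert rows[0]["repeat_total_len"] == total_planted
        assert rows[0]["repeat_count"] == len(truth.repeats)
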