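import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_ssrs
from capssr.ssr_mining import (DEFAULT_MIN_REPEATS, ESTRecord, build_markers,
                               canonical_motif_class, find_ssrs,
                               motif_summary)
from capssr._seq import revcomp
from capssr.synthetic_data import simulate_ests


def as_tuples(loci):
    return sorted((l.start, l.end, l.unit, l.repeat_count) for l in loci)


class TestFindSSRs:
    def test_perfect_dinucleotide_run(self):
        loci = find_ssrs("ATATATATATAT", {2: 6, 3: 5, 4: 5})
        assert as_tuples(loci) == [(0, 12, "AT", 6)]

    def test_no_qualifying_repeat(self):
        assert find_ssrs("ACGTACCA", {2: 4, 3: 4, 4: 4}) == []

    def test_empty_sequence(self):
        assert find_ssrs("", DEFAULT_MIN_REPEATS) == []

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            find_ssrs("ACGXACGT")

    def test_run_containing_n_not_reported(self):
        clean = "AAG" * 6
        assert find_ssrs(clean, {3: 5}) != []
        broken = clean[:8] + "N" + clean[9:]
        assert find_ssrs(broken, {3: 5}) == []

    def test_homopolymer_never_reported_as_di(self):
        # "AA" is a tandem repeat of "A", so it is not a valid di unit
        assert find_ssrs("A" * 40, {2: 6, 3: 5, 4: 5}) == []

    def test_case_insensitive(self):
        assert as_tuples(find_ssrs("atatatatatat")) == [(0, 12, "AT", 6)]

    def test_planted_loci_recovered_exactly(self):
        ests, truth = simulate_ests(n=100, length=1000,
                                    motif_class_probs={"AAG": 1.0},
                                    planted_per_est=1, seed=7)
        by_est = {l.est_id: l for l in truth}
        for est in ests:
            found = find_ssrs(est.sequence)
            t = by_est[est.id]
            assert as_tuples(found) == [(t.start, t.end, t.unit, t.repeat_count)]
            # full-output agreement with the exhaustive scan oracle
            assert as_tuples(found) == brute_force_ssrs(est.sequence,
                                                        DEFAULT_MIN_REPEATS)

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(11)
        alphabet = np.array(list("ACGTN"))
        # biased alphabet so repeats actually occur
        for _ in range(150):
            seq = "".join(rng.choice(alphabet, size=300,
                                     p=[0.31, 0.31, 0.16, 0.16, 0.06]))
            thresholds = {2: 4, 3: 3, 4: 3}
            assert as_tuples(find_ssrs(seq, thresholds)) == \
                brute_force_ssrs(seq, thresholds)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=80))
    def test_every_locus_reverifies_as_tandem(self, seq):
        thresholds = {2: 3, 3: 3, 4: 3}
        loci = find_ssrs(seq, thresholds)
        assert [l.start for l in loci] == sorted(l.start for l in loci)
        for l in loci:
            assert seq.upper()[l.start:l.end] == l.unit * l.repeat_count
        assert as_tuples(loci) == brute_force_ssrs(seq, thresholds)


class TestCanonicalMotifClass:
    @pytest.mark.parametrize("unit,expected", [
        ("GAA", "AAG"),          # rotation
        ("CTT", "AAG"),          # reverse complement rotation
        ("AT", "AT"), ("TA", "AT"), ("GT", "AC"),
        ("ATC", "ATC"), ("GAT", "ATC"),
    ])
    def test_known_classes(self, unit, expected):
        assert canonical_motif_class(unit) == expected

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            canonical_motif_class("AXG")

    def test_rejects_bad_length(self):
        with pytest.raises(ValueError):
            canonical_motif_class("ACGTA")

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=4))
    def test_idempotent_and_rotation_invariant(self, unit):
        canon = canonical_motif_class(unit)
        assert canonical_motif_class(canon) == canon
        for i in range(len(unit)):
            assert canonical_motif_class(unit[i:] + unit[:i]) == canon
        assert canonical_motif_class(revcomp(unit)) == canon

    @pytest.mark.parametrize("length,expected", [(2, 4), (3, 10)])
    def test_class_counts_over_all_primitive_units(self, length, expected):
        from itertools import product
        units = ["".join(p) for p in product("ACGT", repeat=length)]
        primitive = [u for u in units
                     if not any(length % d == 0 and u == u[:d] * (length // d)
                                for d in range(1, length))]
        assert len({canonical_motif_class(u) for u in primitive}) == expected


class TestBuildMarkers:
    def _est_with_ssr(self, est_id, rng, flank=80, unit="AAG", reps=6):
        left = "".join(rng.choice(list("ACGT"), size=flank))
        right = "".join(rng.choice(list("ACGT"), size=flank))
        return ESTRecord(id=est_id, sequence=left + unit * reps + right)

    def test_exact_duplicate_est_removed(self):
        rng = np.random.default_rng(0)
        est = self._est_with_ssr("e1", rng)
        dup = ESTRecord(id="e2", sequence=est.sequence)
        markers = build_markers([est, dup], flank_len=60, min_flank=20)
        assert len(markers) == 1
        assert markers[0].est_id == "e1"

    def test_reverse_complement_duplicate_removed(self):
        rng = np.random.default_rng(1)
        est = self._est_with_ssr("e1", rng, unit="AAG")
        rc = ESTRecord(id="e2", sequence=revcomp(est.sequence))
        markers = build_markers([est, rc], flank_len=60, min_flank=20)
        assert len(markers) == 1

    def test_short_flank_rejected(self):
        rng = np.random.default_rng(2)
        est = ESTRecord(id="e1", sequence="ACGTACCGTA" + "AAG" * 6 +
                        "".join(rng.choice(list("ACGT"), size=80)))
        assert build_markers([est], flank_len=150, min_flank=50) == []

    def test_names_are_zero_padded_and_unique(self):
        rng = np.random.default_rng(3)
        ests = [self._est_with_ssr(f"e{i}", rng) for i in range(12)]
        markers = build_markers(ests, flank_len=60, min_flank=20)
        names = [m.name for m in markers]
        assert names[:2] == ["CaES0001", "CaES0002"]
        assert len(set(names)) == len(names) == 12

    def test_marker_set_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        ests = [self._est_with_ssr(f"e{i}", rng) for i in range(20)]
        fwd = build_markers(ests, flank_len=60, min_flank=20)
        rev = build_markers(ests[::-1], flank_len=60, min_flank=20)
        assert {(m.left_flank, m.right_flank) for m in fwd} == \
               {(m.left_flank, m.right_flank) for m in rev}

    def test_full_recall_on_planted_ests(self):
        ests, truth = simulate_ests(n=200, length=600, planted_per_est=1,
                                    seed=5)
        markers = build_markers(ests, flank_len=150, min_flank=50)
        assert len(markers) == 200
        mined = {(m.est_id, m.locus.start, m.locus.end) for m in markers}
        assert mined == {(l.est_id, l.start, l.end) for l in truth}


class TestMotifSummary:
    def test_length_shares(self):
        rng = np.random.default_rng(6)
        helper = TestBuildMarkers()
        ests = [helper._est_with_ssr(f"d{i}", rng, unit="AT", reps=7)
                for i in range(3)]
        ests.append(helper._est_with_ssr("t1", rng, unit="AAG", reps=6))
        markers = build_markers(ests, flank_len=60, min_flank=20)
        summary = motif_summary(markers)
        by_len = summary.groupby("unit_length")["percent"].sum()
        assert by_len[2] == pytest.approx(75.0)
        assert by_len[3] == pytest.approx(25.0)
        assert summary["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_class(self):
        rng = np.random.default_rng(7)
        helper = TestBuildMarkers()
        ests = [helper._est_with_ssr(f"x{i}", rng, unit="GAA") for i in range(4)]
        summary = motif_summary(build_markers(ests, flank_len=60, min_flank=20))
        assert list(summary["canonical_class"]) == ["AAG"]
        assert summary["percent"].iloc[0] == pytest.approx(100.0)

    def test_empty_input(self):
        assert motif_summary([]).empty

    def test_observed_shares_track_generating_probabilities(self):
        probs = {"AAG": 0.4, "AT": 0.3, "AAT": 0.3}
        ests, truth = simulate_ests(n=500, length=1000,
                                    motif_class_probs=probs,
                                    planted_per_est=4, seed=9)
        assert len(truth) == 2000
        markers = build_markers(ests, flank_len=60, min_flank=20)
        summary = motif_summary(markers).set_index("canonical_class")
        for cls, p in probs.items():
            assert summary.loc[cls, "percent"] == pytest.approx(100 * p, abs=3.0)
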