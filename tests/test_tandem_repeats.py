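"""Tests of the weighted tandem-array detector and insertion profiling."""

import pytest
from hypothesis import given, settings, strategies as st

from boletax.synthetic_data import (
    DEFAULT_MINISAT_CONSENSUS,
    InsertionSimParams,
    simulate_marker_sequences,
)
from boletax.tandem_repeats import (
    MarkerRecord,
    QualityError,
    WEIGHTS_235,
    WEIGHTS_277,
    best_array_score,
    compare_consensus,
    detect_tandem_repeats,
    infer_insertion_boundaries,
    summarize_species_profiles,
    two_pass_its_scan,
)

from oracles import edit_distance_min_rotation

DNA = st.text(alphabet="ACGT", min_size=0, max_size=50)


class TestDetector:
    def test_two_exact_copies_of_66mer(self, core_66):
        """An exact 2-copy 66-bp minisatellite yields one hit with period
        66, copy number 2.0, 100% matches, 0% indels, score 2*132."""
        hits = detect_tandem_repeats(core_66 * 2)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (0, 132)
        assert h.period == 66
        assert h.copy_number == 2.0
        assert h.percent_matches == 100
        assert h.percent_indels == 0
        assert h.score == 264
        assert h.consensus == core_66

    def test_short_sequence_no_hits(self):
        assert detect_tandem_repeats("ACGT") == []
        assert detect_tandem_repeats("") == []

    @pytest.mark.parametrize("run_len,expect_hit", [(24, False), (26, True)])
    def test_ac_run_detection_floor(self, flanked, run_len, expect_hit):
        """Pure AC runs: 26 bp scores 52 >= 50 and is reported at period
        2 (not a multiple); 24 bp scores 48 and is dropped."""
        seq = flanked("AC" * (run_len // 2))
        hits = detect_tandem_repeats(seq)
        if not expect_hit:
            assert hits == []
        else:
            assert len(hits) == 1
            h = hits[0]
            assert h.period == 2
            assert h.consensus in ("AC", "CA")
            assert h.score == 2 * run_len
            assert h.end - h.start == run_len

    @pytest.mark.parametrize(
        "unit,copies",
        [("ACGGT", 6), ("TAGGCATC", 4), ("ACGGTTAGCATGA", 4)],
    )
    def test_perfect_array_law(self, flanked, unit, copies):
        """An exact k-copy array of period p reports period p, copy
        number k, score match*k*p, 100% matches, 0% indels."""
        p = len(unit)
        seq = flanked(unit * copies)
        hits = detect_tandem_repeats(seq, WEIGHTS_277)
        arrays = [h for h in hits if h.period == p]
        assert len(arrays) == 1
        h = arrays[0]
        assert h.copy_number == float(copies)
        assert h.score == 2 * copies * p
        assert h.percent_matches == 100
        assert h.percent_indels == 0

    def test_quality_screen(self):
        rec = MarkerRecord("bad", "ACGT" * 20 + "N" * 6)
        assert rec.non_atgc_fraction > 0.05
        with pytest.raises(QualityError):
            detect_tandem_repeats(rec)
        # override works and N never matches anything
        detect_tandem_repeats(rec, skip_quality_check=True)

    def test_lower_penalties_never_decrease_best_score(self, rng):
        """2-7-7 -> 2-3-5 can only raise the best array score (the more
        sensitive setting finds repeats the stricter one misses)."""
        for _ in range(30):
            n = int(rng.integers(5, 45))
            seq = "".join(rng.choice(list("ACGT"), n))
            assert best_array_score(seq, WEIGHTS_235, 10) >= best_array_score(
                seq, WEIGHTS_277, 10
            )


class TestTwoPass:
    def test_window_of_scan_equals_scan_of_window(self):
        """A perfect array inside ITS2 is reported by both passes at
        identical lifted coordinates."""
        sims = simulate_marker_sequences(
            InsertionSimParams(
                minis_sub_rate=0.0, minis_copies=2.0, seed=11, n_sequences=1
            )
        )
        rec, truth = sims[0]
        h1, h2 = two_pass_its_scan(rec)
        mini1 = [h for h in h1 if h.period == 80]
        mini2 = [h for h in h2 if h.period == 80]
        assert len(mini1) == 1 and len(mini2) == 1
        assert (mini1[0].start, mini1[0].end) == (mini2[0].start, mini2[0].end)
        assert (mini1[0].start, mini1[0].end) == truth["mini"]

    def test_its1_array_excluded_from_second_pass(self):
        sims = simulate_marker_sequences(
            InsertionSimParams(minis_sub_rate=0.0, seed=3, n_sequences=1)
        )
        rec, truth = sims[0]
        h1, h2 = two_pass_its_scan(rec)
        assert any(h.period == 2 for h in h1)  # ITS1 microsatellite
        assert not any(h.period == 2 for h in h2)
        w0, w1 = rec.annotation["ITS2"]
        assert all(w0 <= h.start and h.end <= w1 for h in h2)

    def test_window_outside_sequence_errors(self):
        rec = MarkerRecord("x", "ACGT" * 30)
        with pytest.raises(ValueError):
            two_pass_its_scan(rec, its2_window=(100, 200))
        with pytest.raises(ValueError):
            two_pass_its_scan(rec)  # no annotation, no window

    def test_mutated_consensus_recovered_within_edit_distance(self):
        """Fuzzy minisatellites (82-bp unit, 2.8 copies, 5% substitutions):
        the pass-2 consensus stays within edit distance 4 of the planted
        unit (up to rotation) in >= 95% of seeded replicates."""
        consensus = DEFAULT_MINISAT_CONSENSUS + "GT"  # 82 bp
        ok = 0
        n_rep = 100
        for rep in range(n_rep):
            sims = simulate_marker_sequences(
                InsertionSimParams(
                    minis_consensus=consensus,
                    minis_copies=2.8,
                    minis_sub_rate=0.05,
                    seed=1000 + rep,
                    n_sequences=1,
                )
            )
            rec, truth = sims[0]
            _h1, h2 = two_pass_its_scan(rec)
            cands = [h for h in h2 if abs(h.period - 82) <= 4]
            if not cands:
                continue
            best = max(cands, key=lambda h: h.score)
            if edit_distance_min_rotation(best.consensus, consensus) <= 4:
                ok += 1
        assert ok >= 0.95 * n_rep


class TestInsertionBoundaries:
    def test_single_gap_block(self):
        aligned = {"t": "AAATTTTAAA", "r": "AAA----AAA"}
        out = infer_insertion_boundaries(aligned, ["t"], ["r"])
        assert out["t"] == ((3, 7), [])

    def test_two_disjoint_blocks_longer_wins(self):
        aligned = {
            "t": "AATTAAGGGAA",
            "r1": "AA--AA---AA",
            "r2": "AA--AA---AA",
        }
        interval, secondary = infer_insertion_boundaries(
            aligned, ["t"], ["r1", "r2"]
        )["t"]
        assert interval == (6, 9)  # the 3-column GGG block
        assert secondary == [(2, 4)]  # the shorter TT block is flagged

    def test_identical_sequences_no_insertion(self):
        aligned = {"t": "ACGTACGT", "r": "ACGTACGT"}
        assert infer_insertion_boundaries(aligned, ["t"], ["r"])["t"] == (
            (0, 0),
            [],
        )

    def test_requires_reference(self):
        with pytest.raises(ValueError):
            infer_insertion_boundaries({"t": "AC"}, ["t"], [])


class TestCompareConsensus:
    def test_identity_and_single_substitution(self):
        a = "ACGT" * 14  # 56-mer
        assert compare_consensus(a, a) == 100.0
        b = a[:10] + ("A" if a[10] != "A" else "C") + a[11:]
        assert compare_consensus(a, b) == pytest.approx(55 / 56 * 100, abs=1e-9)

    def test_rotation_closure(self):
        a = "GGTTGGCTTAGCTATTAGTCGGTCGTGAGG"
        assert compare_consensus(a, a[10:] + a[:10], cyclic=True) == 100.0
        assert compare_consensus(a, a[10:] + a[:10], cyclic=False) < 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compare_consensus("", "ACGT")

    @settings(max_examples=60, deadline=None)
    @given(a=st.text("ACGT", min_size=1, max_size=30),
           b=st.text("ACGT", min_size=1, max_size=30))
    def test_edit_distance_agrees_with_edlib(self, a, b):
        """The alignment underlying the identity is a minimum-edit
        alignment (cross-checked against edlib's NW distance)."""
        import edlib

        ident = compare_consensus(a, b)
        dist = edlib.align(a, b, task="distance")["editDistance"]
        # the reported identity comes from a minimum-edit alignment, so
        # ident = 100*(1 - dist/cols) for an integer column count cols
        # between max(|a|,|b|) and |a|+|b|
        if ident == 100.0:
            assert dist == 0
        else:
            cols = dist / (1 - ident / 100)
            assert abs(cols - round(cols)) < 1e-6
            assert max(len(a), len(b)) <= round(cols) <= len(a) + len(b)


class TestSpeciesProfiles:
    def _hit(self, seq_id, consensus, cn=2.0, pm=100, pi=0, start=0):
        from boletax.tandem_repeats import RepeatHit

        return RepeatHit(
            seq_id=seq_id,
            start=start,
            end=start + int(cn * len(consensus)),
            period=len(consensus),
            copy_number=cn,
            consensus=consensus,
            percent_matches=pm,
            percent_indels=pi,
            score=50,
        )

    def test_identical_hits_degenerate_ranges(self):
        recs = {
            "s1": MarkerRecord("s1", "ACGT" * 50),
            "s2": MarkerRecord("s2", "ACGT" * 50),
        }
        species_of = {"s1": "X", "s2": "X"}
        hits = {
            ("X", "ITS2", "2-7-7"): [
                self._hit("s1", "ACGGTTAG"),
                self._hit("s2", "ACGGTTAG"),
            ]
        }
        (p,) = summarize_species_profiles(hits, recs, species_of)
        assert p.insertion_size_range == (16, 16)
        assert p.copy_number_range == (2.0, 2.0)
        assert p.similarity_range == (100.0, 100.0)
        assert p.consensus_patterns == ["ACGGTTAG"]

    def test_nd_row_for_species_without_hits(self):
        recs = {"s1": MarkerRecord("s1", "ACGT" * 50)}
        hits = {("Y", "ITS2", "2-7-7"): []}
        (p,) = summarize_species_profiles(hits, recs, {"s1": "Y"})
        assert not p.detected
        assert p.insertion_size_range is None
        assert p.consensus_patterns == []

    def test_planted_profile_bracketed(self):
        """Insertion-size range of a simulated 5-sequence species
        brackets the planted array sizes."""
        sims = simulate_marker_sequences(
            InsertionSimParams(minis_sub_rate=0.02, seed=5, n_sequences=5)
        )
        recs = {r.seq_id: r for r, _t in sims}
        species_of = {r.seq_id: "simsp" for r, _t in sims}
        allhits = []
        for rec, _truth in sims:
            _h1, h2 = two_pass_its_scan(rec, WEIGHTS_277, WEIGHTS_235)
            allhits.extend(h for h in h2 if h.period > 10)
        (p,) = summarize_species_profiles(
            {("simsp", "ITS2", "2-3-5"): allhits}, recs, species_of
        )
        lo, hi = p.insertion_size_range
        planted = sims[0][1]["mini_planted_length"]
        assert lo <= planted <= hi + 10  # local alignment may trim edges
        assert p.n_sequences == 5

    def test_mismapped_hit_rejected(self):
        recs = {"s1": MarkerRecord("s1", "ACGT")}
        with pytest.raises(ValueError):
            summarize_species_profiles(
                {("Z", "ITS2", "2-7-7"): [self._hit("s1", "ACGGTTAG")]},
                recs,
                {"s1": "NotZ"},
            )
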