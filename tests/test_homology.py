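"""Alignment, target scoring, origin signatures, and the shuffled null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirsort import hairpin as hp, homology, simulate
from mirsort.errors import ValidationError
from mirsort.sequence import revcomp

from oracles import sw_score_exhaustive, sw_score_oracle

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


class TestSmithWaterman:
    def test_identity_score(self):
        assert homology.smith_waterman("ACGUACGU", "ACGUACGU").score == 40.0

    def test_single_mismatch(self):
        aln = homology.smith_waterman("ACGU", "AGGU")
        assert aln.score == 11.0
        assert len(aln.columns) == 4

    def test_no_similarity_floor(self):
        aln = homology.smith_waterman("AAAA", "CCCC")
        assert aln.score == 0.0 and aln.columns == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            homology.smith_waterman("", "ACGU")

    @settings(max_examples=80, derandomize=True)
    @given(
        st.text(alphabet="ACGU", min_size=1, max_size=8),
        st.text(alphabet="ACGU", min_size=1, max_size=8),
    )
    def test_matches_gap_length_oracle(self, a, b):
        assert homology.smith_waterman(a, b).score == pytest.approx(sw_score_oracle(a, b))

    @settings(max_examples=25, derandomize=True)
    @given(
        st.text(alphabet="ACGU", min_size=1, max_size=5),
        st.text(alphabet="ACGU", min_size=1, max_size=5),
    )
    def test_oracle_agrees_with_exhaustive_enumeration(self, a, b):
        """The gap-length DP oracle itself equals brute-force alignment
        enumeration on tiny inputs."""
        assert sw_score_oracle(a, b) == pytest.approx(sw_score_exhaustive(a, b))

    @settings(max_examples=40, derandomize=True)
    @given(
        st.text(alphabet="ACGU", min_size=4, max_size=30),
        st.text(alphabet="ACGU", min_size=4, max_size=30),
    )
    def test_traceback_score_consistency(self, a, b):
        """Score recomputed from traceback columns equals the DP score."""
        aln = homology.smith_waterman(a, b)
        if aln.columns:
            assert aln.column_score() == pytest.approx(aln.score)


class TestExpectationScore:
    def test_perfect_complement(self):
        assert homology.expectation_score(LET7, revcomp(LET7)) == 0.0

    def test_single_wobble_outside_seed(self):
        guide = list("A" * 22)
        guide[14] = "G"  # position 15 faces a U in the site: G:U wobble
        assert homology.expectation_score("".join(guide), revcomp("A" * 22)) == 0.5

    def test_single_mismatch_in_seed(self):
        guide = list("A" * 22)
        guide[4] = "C"  # position 5: C faces U -> mismatch, seed-weighted
        assert homology.expectation_score("".join(guide), revcomp("A" * 22)) == 1.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            homology.expectation_score("ACGU", "ACG")


class TestPredictTargets:
    def test_exact_complement_reported_at_zero(self):
        tx = {"t1": "G" * 30 + revcomp(LET7) + "G" * 30}
        sites = homology.predict_targets({"m": LET7}, tx)
        assert any(s.score == 0.0 and s.span == (30, 52) for s in sites)

    def test_cutoff_zero_keeps_only_perfect(self):
        tx = {"t1": "G" * 10 + revcomp(LET7) + "G" * 10}
        sites = homology.predict_targets({"m": LET7}, tx, cutoff=0.0)
        assert len(sites) == 1 and sites[0].score == 0.0

    def test_random_transcripts_rarely_hit(self):
        rng = np.random.default_rng(0)
        guides = {"m": LET7}
        hits = 0
        for _ in range(20):
            tx = {"t": "".join(rng.choice(list("ACGU"), size=300))}
            hits += len(homology.predict_targets(guides, tx))
        assert hits <= 1

    def test_pairing_string(self):
        tx = "G" * 5 + revcomp(LET7) + "G" * 5
        sites = homology.predict_targets({"m": LET7}, {"t": tx})
        s = [x for x in sites if x.score == 0.0][0]
        assert s.pairing_string(LET7, tx) == "|" * 22


class TestExtendedGuide:
    def test_coordinate_arithmetic_5p(self):
        # 22-nt guide at precursor positions 8-29 (1-based) on the 5p arm:
        # extended = positions 1-35, i.e. 7 stem-side + guide + 6 loop-side
        seq = "ACGUACG" + LET7 + "CCAACC" + "GGGG"
        h = hp.Hairpin(
            id="x", precursor_seq=seq, guide_span=(7, 29), star_span=(33, 37),
            guide_arm="5p", fold=np.full(len(seq), -1),
        )
        ext = homology.extended_guide(h)
        assert ext.seq == seq[0:35]
        assert (ext.up_len, ext.guide_len, ext.down_len) == (7, 22, 6)
        assert ext.up_side == "stem" and ext.down_side == "loop"
        assert ext.truncated == (False, False)

    def test_arm_mirroring_3p(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=4, guide_arm="3p")
        ext = homology.extended_guide(h)
        assert ext.up_side == "loop" and ext.down_side == "stem"
        assert (ext.up_len, ext.down_len) == (6, 7)
        assert ext.guide_seq == LET7

    def test_truncation_flagged_at_precursor_edge(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=4, pad_len=3)
        ext = homology.extended_guide(h)
        assert ext.truncated[0] and ext.up_len == 3


class TestSignatures:
    def test_planted_loop_run_detected(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=2, hairpin_id="m1")
        tx, truth = simulate.plant_origin_transcripts([h], {"m1": (6, "loop")}, seed=0)
        sites = homology.predict_targets({"m1": LET7}, tx)
        ext = homology.extended_guide(h)
        sig = homology.detect_signature(ext, "t-m1", tx["t-m1"], sites)
        assert sig is not None
        assert sig.flank_side == "loop" and sig.run_length >= 6

    def test_five_nt_run_below_threshold(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=2, hairpin_id="m1")
        tx, _ = simulate.plant_origin_transcripts([h], {"m1": (5, "loop")}, seed=0)
        sites = homology.predict_targets({"m1": LET7}, tx)
        sig = homology.detect_signature(
            homology.extended_guide(h), "t-m1", tx["t-m1"], sites
        )
        assert sig is None

    def test_decoys_yield_no_signature(self, origin_bundle):
        hairpins, transcripts, truth, sites, ext = origin_bundle
        observed, evidence = homology.count_signatures(ext, transcripts, sites)
        planted = {t.mirna_id for t in truth.transcripts.values() if t.planted}
        found = set(evidence["mirna_id"]) if len(evidence) else set()
        assert found == planted
        assert observed == len(planted) == 10

    def test_signature_invariant_to_padding(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=2, hairpin_id="m1")
        tx, _ = simulate.plant_origin_transcripts([h], {"m1": (6, "loop")}, seed=0)
        rng = np.random.default_rng(4)
        padded = {
            "t-m1": "".join(rng.choice(list("ACGU"), 50)) + tx["t-m1"]
            + "".join(rng.choice(list("ACGU"), 50))
        }
        sites = homology.predict_targets({"m1": LET7}, padded)
        sig = homology.detect_signature(
            homology.extended_guide(h), "t-m1", padded["t-m1"], sites
        )
        assert sig is not None and sig.flank_side == "loop"

    def test_dedup_counts_mirna_once(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=2, hairpin_id="m1")
        all_tx = {}
        for k in range(3):
            tx, _ = simulate.plant_origin_transcripts([h], {"m1": (6, "loop")}, seed=k)
            all_tx[f"t{k}"] = tx["t-m1"]
        sites = homology.predict_targets({"m1": LET7}, all_tx)
        count, evidence = homology.count_signatures(
            {"m1": homology.extended_guide(h)}, all_tx, sites
        )
        assert count == 1 and len(evidence) == 3

    def test_no_sites_pair_rejected(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=2)
        with pytest.raises(ValidationError, match="site"):
            homology.detect_signature(
                homology.extended_guide(h), "t", "ACGU" * 30, []
            )


class TestShuffleNull:
    def test_composition_preserved(self, origin_bundle):
        *_, ext = origin_bundle
        rng = np.random.default_rng(0)
        for e in list(ext.values())[:20]:
            s = homology.shuffle_flanks(e, rng)
            assert sorted(s.seq[: s.up_len]) == sorted(e.seq[: e.up_len])
            assert sorted(s.seq[s.up_len + s.guide_len :]) == sorted(
                e.seq[e.up_len + e.guide_len :]
            )
            assert s.guide_seq == e.guide_seq

    def test_dinucleotide_mode_preserves_dinucleotides(self, origin_bundle):
        *_, ext = origin_bundle
        rng = np.random.default_rng(0)
        e = list(ext.values())[0]
        s = homology.shuffle_flanks(e, rng, dinucleotide=True)
        up_old, up_new = e.seq[: e.up_len], s.seq[: s.up_len]
        dinucs = lambda x: sorted(x[i : i + 2] for i in range(len(x) - 1))
        assert dinucs(up_new) == dinucs(up_old)

    def test_null_determinism(self, origin_bundle):
        _, transcripts, _, sites, ext = origin_bundle
        few = dict(list(ext.items())[:15])
        n1 = homology.shuffle_null(few, transcripts, sites, n_lists=5, seed=9)
        n2 = homology.shuffle_null(few, transcripts, sites, n_lists=5, seed=9)
        assert n1.per_list_counts == n2.per_list_counts

    def test_null_far_below_planted_signal(self, origin_bundle):
        _, transcripts, _, sites, ext = origin_bundle
        null = homology.shuffle_null(ext, transcripts, sites, n_lists=20, seed=5)
        assert null.observed == 10
        assert null.max < null.observed
        assert null.mean < null.observed
        # summary statistics consistent with the per-list counts
        assert null.mean == pytest.approx(np.mean(null.per_list_counts))
        assert null.max == max(null.per_list_counts)


class TestREOriginFlags:
    REPEATS = pd.DataFrame(
        [
            {"seqid": "t1", "source": ".", "type": "repeat", "start": 21, "end": 60,
             "score": ".", "strand": "+", "phase": ".", "attributes": "family=LTR-7"},
            {"seqid": "t2", "source": ".", "type": "repeat", "start": 21, "end": 60,
             "score": ".", "strand": "+", "phase": ".", "attributes": "family=DNA-3"},
        ]
    )

    def _sites(self):
        return [
            homology.TargetSite("m1", "t1", (30, 52), 0.0),
            homology.TargetSite("m1", "t2", (30, 52), 0.0),
        ]

    def test_same_family_flagged_and_other_not(self):
        flags = homology.re_origin_flags({"m1": "LTR-7"}, self._sites(), self.REPEATS)
        assert len(flags) == 1
        assert flags.iloc[0]["transcript_id"] == "t1"

    def test_unhosted_precursor_ignored(self):
        flags = homology.re_origin_flags({"m1": None}, self._sites(), self.REPEATS)
        assert flags.empty
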