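"""Synthetic-data generator: construction guarantees, reproducibility,
depth accounting, and parameter monotonicity."""

import numpy as np
import pandas as pd
import pytest

from mirsort import annotation, hairpin as hp, io as mio, simulate
from mirsort.errors import ConstructionError, ValidationError

from conftest import small_design

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


class TestMakeHairpin:
    def test_exact_fold_recovery(self):
        """Folding the constructed core recovers the planted pairing map."""
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=1, verify="fold")
        pad = 10
        core = h.precursor_seq[pad:-pad]
        expected = simulate.planted_fold(len(LET7), 8, [], "5p", 0)
        assert np.array_equal(hp.fold_hairpin(core), expected)

    def test_mismatch_on_overhang_rejected(self):
        with pytest.raises(ConstructionError, match="21"):
            simulate.make_hairpin(LET7, [21], loop_len=8, seed=0)

    def test_central_flag_set(self):
        h = simulate.make_hairpin(LET7, [10, 11], loop_len=8, seed=11)
        assert hp.has_central_mismatch(hp.extract_duplex(h))

    def test_3p_arm_mirrors_spans(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=4, guide_arm="3p")
        assert h.guide_span[0] > h.star_span[0]
        assert h.guide_seq == LET7

    def test_loop_too_short_rejected(self):
        with pytest.raises(ConstructionError):
            simulate.make_hairpin(LET7, [], loop_len=2, seed=0)


class TestGeneratedSet:
    def test_round_trip_all_hairpins(self, annotation_scenario):
        """The folding module recovers every planted duplex (construction/
        fold round trip), including the supplied-fold heavy-mismatch plants."""
        hairpins, _, _, truth = annotation_scenario
        for h in hairpins:
            t = truth.hairpins[h.id]
            d = hp.extract_duplex(h)
            assert d.pairs == simulate.planted_duplex_classes(
                len(h.guide_seq), t.mismatch_positions
            )

    def test_bit_reproducibility(self):
        a = simulate.simulate_annotation_scenario(small_design(), n_failures=2, n_starless=1)
        b = simulate.simulate_annotation_scenario(small_design(), n_failures=2, n_starless=1)
        assert [h.precursor_seq for h in a[0]] == [h.precursor_seq for h in b[0]]
        for pid in a[2]:
            pd.testing.assert_frame_equal(a[2][pid].records, b[2][pid].records)

    def test_depth_respected(self, annotation_scenario):
        _, libraries, stacks, _ = annotation_scenario
        totals = {l.library_id: 0 for l in libraries}
        for stack in stacks.values():
            for lib_id, c in stack.records.groupby("library_id")["count"].sum().items():
                totals[lib_id] += int(c)
        for lib in libraries:
            assert totals[lib.library_id] <= lib.genome_mapped_total

    def test_pure_preference_silences_other_ago(self):
        design = small_design(dispersion=0.0)
        rng = np.random.default_rng(0)
        hairpins, truth = simulate.generate_hairpins(design, rng)
        for t in truth.hairpins.values():
            t.preference_ago1 = 1.0
        _, stacks = simulate.simulate_ip_libraries(design, hairpins, truth, rng)
        for h in hairpins:
            t = truth.hairpins[h.id]
            ago2 = stacks[h.id].span_records(
                t.guide_span, [f"planula_AGO2_IP_rep{r}" for r in (1, 2)]
            )
            assert ago2["count"].sum() == 0

    def test_full_homogeneity_single_offset(self):
        design = small_design(five_prime_homogeneity=1.0)
        rng = np.random.default_rng(1)
        hairpins, truth = simulate.generate_hairpins(design, rng)
        _, stacks = simulate.simulate_ip_libraries(design, hairpins, truth, rng)
        for h in hairpins:
            t = truth.hairpins[h.id]
            ago = stacks[h.id].span_records(
                t.guide_span,
                [f"planula_{p}_rep{r}" for p in ("AGO1_IP", "AGO2_IP") for r in (1, 2)],
            )
            if not ago.empty:
                assert set(ago["offset"]) == {t.guide_span[0]}

    def test_homogeneity_monotone_in_expectation(self):
        """Measured modal-5' fraction increases with the design parameter
        (averaged over many seeds)."""
        means = []
        for target in (0.6, 0.9):
            vals = []
            for seed in range(50):
                design = small_design(
                    n_hairpins=3, five_prime_homogeneity=target, rng_seed=seed
                )
                rng = np.random.default_rng(seed)
                hairpins, truth = simulate.generate_hairpins(design, rng)
                _, stacks = simulate.simulate_ip_libraries(design, hairpins, truth, rng)
                for h in hairpins:
                    t = truth.hairpins[h.id]
                    frac = annotation.five_prime_homogeneity(stacks[h.id], t.guide_span)
                    vals.append(frac)
            means.append(np.mean(vals))
        assert means[0] < means[1]

    def test_zero_depth_rejected(self):
        with pytest.raises(ValidationError):
            small_design(ip_depth=0).validate()


class TestKDLibraries:
    def test_spikeins_present_and_unity_effects(self):
        design = small_design(dispersion=0.0)
        rng = np.random.default_rng(3)
        hairpins, truth = simulate.generate_hairpins(design, rng)
        effects = {h.id: {"KD_AGO1": 1.0, "KD_AGO2": 1.0, "KD_control": 1.0} for h in hairpins}
        libs, stacks = simulate.simulate_kd_libraries(
            design, hairpins, truth, effects, rng=np.random.default_rng(3)
        )
        assert all(len(l.spikein_counts) == 4 for l in libs)
        # unity fold changes: KD and control counts agree in expectation
        # (dispersion 0 still draws Poisson counts)
        ratios = []
        for h in hairpins:
            t = truth.hairpins[h.id]
            per_lib = {
                l.library_id: stacks[h.id].span_records(t.guide_span, [l.library_id])["count"].sum()
                for l in libs
            }
            ctrl = np.mean([per_lib[l.library_id] for l in libs if l.pulldown == "KD_control"])
            kd = np.mean([per_lib[l.library_id] for l in libs if l.pulldown == "KD_AGO1"])
            if ctrl > 0:
                ratios.append(kd / ctrl)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_spikein_normalization_identity(self):
        lib = mio.SmallRNALibrary(
            library_id="x", stage="planula", pulldown="KD_control", replicate=1,
            genome_mapped_total=10**6,
            spikein_counts={"a": 100, "b": 100, "c": 100, "d": 100},
        )
        doubled = mio.SmallRNALibrary(
            library_id="y", stage="planula", pulldown="KD_control", replicate=1,
            genome_mapped_total=10**6,
            spikein_counts={"a": 200, "b": 200, "c": 200, "d": 200},
        )
        assert mio.normalize_spikein(50, lib) == 2 * mio.normalize_spikein(50, doubled)

    def test_missing_kd_effects_rejected(self):
        design = small_design()
        rng = np.random.default_rng(3)
        hairpins, truth = simulate.generate_hairpins(design, rng)
        with pytest.raises(ValidationError, match="kd_effects"):
            simulate.simulate_kd_libraries(design, hairpins, truth, kd_effects={})


class TestOriginTranscripts:
    def test_run_exceeding_flank_rejected(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=2, hairpin_id="m1")
        with pytest.raises(ValidationError, match="flank"):
            simulate.plant_origin_transcripts([h], {"m1": (7, "loop")}, seed=0)

    def test_planted_site_recorded_on_transcript(self):
        h = simulate.make_hairpin(LET7, [], loop_len=8, seed=2, hairpin_id="m1")
        tx, truth = simulate.plant_origin_transcripts([h], {"m1": (6, "loop")}, seed=0)
        t = truth.transcripts["t-m1"]
        from mirsort.sequence import revcomp
        lo, hi = t.site_span
        assert tx["t-m1"][lo:hi] == revcomp(h.guide_seq)
        assert t.homology_run == 6 and t.side == "loop"
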