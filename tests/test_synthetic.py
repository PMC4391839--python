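"""The synthetic-data generators: determinism and construction truth."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from mirscan.folding import fold
from mirscan.homology import hamming_mismatches
from mirscan.seq_io import Origin, SequenceRecord, ValidationError
from mirscan.synthetic import (
    SimulationConfig,
    build_precursor,
    make_background,
    make_ct_table,
    make_transcript_with_site,
    mutate,
    plant_precursor,
    random_rna,
    simulate_discovery_dataset,
)
from mirscan.targets import MATCH, MISMATCH, duplex_penalty, find_sites


class TestBackground:
    def test_same_seed_identical_output(self):
        a = make_background(5, 200, seed=42)
        b = make_background(5, 200, seed=42)
        assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]

    def test_gc_fraction_observed_within_binomial_bound(self):
        (rec,) = make_background(1, 10_000, gc_fraction=0.5, seed=1)
        gc = sum(rec.residues.count(b) for b in "GC") / 10_000
        assert abs(gc - 0.5) < 0.02

    def test_zero_gc_gives_au_only(self):
        (rec,) = make_background(1, 500, gc_fraction=0.0, seed=2)
        assert set(rec.residues) <= {"A", "U"}


class TestMutate:
    def test_zero_mutations_is_identity(self):
        seq = random_rna(np.random.default_rng(0), 30)
        assert mutate(seq, 0, seed=5) == seq

    @pytest.mark.parametrize("k", [1, 3, 7, 21])
    def test_hamming_distance_equals_k(self, k):
        seq = random_rna(np.random.default_rng(1), 21)
        assert hamming_mismatches(seq, mutate(seq, k, seed=k)) == k

    def test_k_beyond_length_rejected(self):
        with pytest.raises(ValidationError):
            mutate("ACGU", 5)

    def test_mutated_positions_uniform(self):
        seq = "A" * 21
        counts = np.zeros(21)
        for draw in range(10_000):
            out = mutate(seq, 1, seed=draw)
            counts[next(i for i, (a, b) in enumerate(zip(seq, out)) if a != b)] += 1
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < scipy_stats.chi2.ppf(0.999, df=20)


class TestPlantPrecursor:
    def _bg(self, seed=0, n=400):
        return SequenceRecord("bg", random_rna(np.random.default_rng(seed), n), Origin.SYNTHETIC)

    def test_perfect_star_satisfies_arm_and_duplex_criteria(self):
        mature = random_rna(np.random.default_rng(3), 21)
        _, truth = plant_precursor(mature, self._bg(), 100, star_mismatches=0, seed=8)
        assert truth["criteria"]["c2"] and truth["criteria"]["c3"]
        assert truth["passed"]

    def test_seven_star_mismatches_fail_duplex_criterion(self):
        mature = random_rna(np.random.default_rng(4), 21)
        _, truth = plant_precursor(mature, self._bg(1), 100, star_mismatches=7, seed=9)
        assert not truth["criteria"]["c3"]

    def test_planting_preserves_length_bookkeeping(self):
        mature = random_rna(np.random.default_rng(5), 21)
        bg = self._bg(2)
        subject, truth = plant_precursor(mature, bg, 250, loop_length=8, flank_length=30, seed=10)
        assert len(subject) == len(bg) + 2 * 30 + 21 + 8 + 21
        assert subject.residues[truth["mature_start"] : truth["mature_end"]] == mature

    def test_deterministic(self):
        mature = random_rna(np.random.default_rng(6), 21)
        a = plant_precursor(mature, self._bg(3), 50, seed=11)
        b = plant_precursor(mature, self._bg(3), 50, seed=11)
        assert a[0].residues == b[0].residues and a[1] == b[1]

    def test_impossible_construction_rejected(self):
        mature = random_rna(np.random.default_rng(7), 21)
        with pytest.raises(ValidationError):
            build_precursor(mature, star_mismatches=20)


class TestTranscriptWithSite:
    def test_all_match_spec_has_zero_expectation(self):
        mir = random_rna(np.random.default_rng(8), 21)
        _, truth = make_transcript_with_site(mir, [MATCH] * 20, seed=12)
        assert truth["expectation"] == 0.0

    def test_seed_mismatch_spec_costs_two(self):
        mir = random_rna(np.random.default_rng(9), 21)
        states = [MATCH] * 4 + [MISMATCH] + [MATCH] * 15
        _, truth = make_transcript_with_site(mir, states, seed=13)
        assert truth["expectation"] == duplex_penalty(states) == 2.0

    def test_scan_finds_site_at_recorded_coordinates(self):
        mir = random_rna(np.random.default_rng(10), 21)
        states = [MATCH] * 10 + [MISMATCH] + [MATCH] * 9
        tr, truth = make_transcript_with_site(mir, states, seed=14)
        (site,) = find_sites(SequenceRecord("m", mir, Origin.REFERENCE), tr)
        assert (site.start, site.end) == (truth["site_start"], truth["site_end"])
        assert site.expectation == truth["expectation"]


class TestCtTable:
    def test_zero_noise_is_exactly_invertible(self):
        from mirscan.expression import ddct_folds

        table, truth = make_ct_table({"a": {"root": 4.0, "fruit": 0.5}}, noise_sd=0.0, seed=15)
        folds = {(r.assay, r.tissue): r.fold for r in ddct_folds(table)}
        assert folds[("a", "root")] == pytest.approx(4.0)
        assert folds[("a", "fruit")] == pytest.approx(0.5)
        assert folds[("a", "leaf")] == pytest.approx(1.0)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValidationError):
            make_ct_table({"a": {"root": 0.0}})

    def test_deterministic_with_noise(self):
        a, _ = make_ct_table({"a": {"root": 2.0}}, noise_sd=0.4, seed=16)
        b, _ = make_ct_table({"a": {"root": 2.0}}, noise_sd=0.4, seed=16)
        assert a.equals(b)


class TestDiscoveryDataset:
    def test_truth_labels_match_designed_construction(self):
        config = SimulationConfig(seed=5, n_subjects=6)
        refs, subjects, truths = simulate_discovery_dataset(config, n_planted=3,
                                                            homolog_mismatches=(2,))
        assert len(refs) == 4 and len(subjects) == 6 and len(truths) == 4
        for truth in truths:
            subject = next(s for s in subjects if s.id == truth["subject_id"])
            planted = subject.residues[truth["mature_start"] : truth["mature_end"]]
            ref = next(r for r in refs if r.id == truth["reference_id"])
            assert hamming_mismatches(planted, ref.residues) == truth["reference_mismatches"]
            hairpin = subject.residues[truth["hairpin_start"] : truth["hairpin_end"]]
            assert fold(hairpin).mfe == truth["mfe"]
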