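"""Complementarity-penalty target scanning against planted and exhaustive truth."""

import numpy as np
import pytest

import mirscan
from mirscan.seq_io import Origin, SequenceRecord, ValidationError, reverse_complement
from mirscan.synthetic import make_transcript_with_site, random_rna
from mirscan.targets import (
    GAP_MIRNA,
    GAP_TARGET,
    MATCH,
    MISMATCH,
    WOBBLE,
    TargetScanConfig,
    duplex_penalty,
    find_sites,
    predict_targets,
    upe_estimate,
)

from conftest import enumerate_best_energy


def _mir(seed=3, length=21):
    return SequenceRecord(f"mir{seed}", random_rna(np.random.default_rng(seed), length),
                          Origin.REFERENCE)


class TestDuplexPenalty:
    def test_perfect_complement_scores_zero(self):
        assert duplex_penalty([MATCH] * 20) == 0.0

    def test_single_wobble_outside_seed(self):
        assert duplex_penalty([MATCH] * 14 + [WOBBLE] + [MATCH] * 5) == 0.5

    def test_single_seed_mismatch_is_doubled(self):
        assert duplex_penalty([MATCH] * 4 + [MISMATCH] + [MATCH] * 15) == 2.0

    def test_gap_penalties(self):
        assert duplex_penalty([MATCH] * 13 + [GAP_TARGET] + [MATCH] * 6) == 2.0
        assert duplex_penalty([MATCH] * 2 + [GAP_TARGET] + [MATCH] * 17) == 4.0

    def test_unknown_state_rejected(self):
        with pytest.raises(ValidationError):
            duplex_penalty(["bogus"])

    def test_matches_per_position_sum_oracle(self, rng):
        states_pool = [MATCH, WOBBLE, MISMATCH, GAP_TARGET, GAP_MIRNA]
        penalties = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0, GAP_TARGET: 2.0, GAP_MIRNA: 2.0}
        for _ in range(1000):
            n = int(rng.integers(1, 25))
            states = [states_pool[int(rng.integers(5))] for _ in range(n)]
            expected, pos = 0.0, 0
            for st in states:
                attributed = pos + 1
                if st != GAP_MIRNA:
                    pos += 1
                    attributed = pos
                expected += penalties[st] * (2.0 if 2 <= attributed <= 13 else 1.0)
            assert duplex_penalty(states) == pytest.approx(expected)


class TestFindSites:
    def test_perfect_site_is_cleavage_with_zero_expectation(self):
        mir = _mir(3)
        tr, truth = make_transcript_with_site(mir.residues, [MATCH] * 20, seed=11)
        (site,) = find_sites(mir, tr)
        assert (site.start, site.end) == (truth["site_start"], truth["site_end"])
        assert site.expectation == 0.0
        assert site.inhibition == "CLEAVAGE"

    def test_central_mismatch_calls_translation(self):
        mir = _mir(3)
        states = [MATCH] * 9 + [MISMATCH] + [MATCH] * 10  # position 10
        tr, truth = make_transcript_with_site(mir.residues, states, seed=12)
        (site,) = find_sites(mir, tr)
        assert site.expectation == truth["expectation"] == 2.0
        assert site.inhibition == "TRANSLATION"

    @pytest.mark.parametrize(
        "states",
        [
            [MATCH] * 13 + [GAP_TARGET] + [MATCH] * 6,
            [MATCH] * 14 + [GAP_MIRNA] + [MATCH] * 6,
            [MATCH] * 15 + [WOBBLE, WOBBLE] + [MATCH] * 3,
        ],
        ids=["target_gap", "mirna_gap", "double_wobble"],
    )
    def test_planted_variant_sites_recovered_with_intended_expectation(self, states):
        mir = _mir(7)
        tr, truth = make_transcript_with_site(mir.residues, states, seed=13)
        (site,) = find_sites(mir, tr)
        assert site.expectation == truth["expectation"]
        assert (site.start, site.end) == (truth["site_start"], truth["site_end"])

    def test_no_sites_in_unplanted_random_transcripts(self):
        mir = _mir(3)
        for seed in range(20):
            tr = SequenceRecord(
                f"t{seed}", random_rna(np.random.default_rng(seed + 100), 2000),
                Origin.TRANSCRIPT,
            )
            assert find_sites(mir, tr) == []

    def test_zero_expectation_equals_exact_string_search(self, rng):
        config = TargetScanConfig(max_expectation=0.0)
        for seed in range(10):
            mir = _mir(seed, length=20)
            tr_seq = random_rna(np.random.default_rng(seed + 700), 600)
            insert_at = int(np.random.default_rng(seed).integers(0, 580))
            rc = reverse_complement(mir.residues, "RNA")
            tr_seq = tr_seq[:insert_at] + rc + tr_seq[insert_at:]
            tr = SequenceRecord("t", tr_seq, Origin.TRANSCRIPT)
            got = {(s.start, s.end) for s in find_sites(mir, tr, config)}
            expected = set()
            pos = tr_seq.find(rc)
            while pos != -1:
                expected.add((pos, pos + 20))
                pos = tr_seq.find(rc, pos + 1)
            assert got == expected

    def test_lowering_max_expectation_never_adds_sites(self):
        mir = _mir(5)
        tr, _ = make_transcript_with_site(
            mir.residues, [MATCH] * 15 + [MISMATCH] + [MATCH] * 4, seed=19
        )
        loose = {(s.start, s.end) for s in find_sites(mir, tr, TargetScanConfig(max_expectation=3.0))}
        tight = {(s.start, s.end) for s in find_sites(mir, tr, TargetScanConfig(max_expectation=0.5))}
        assert tight <= loose

    def test_alignment_text_shapes(self):
        mir = _mir(3)
        tr, _ = make_transcript_with_site(mir.residues, [MATCH] * 20, seed=11)
        (site,) = find_sites(mir, tr)
        target_line, marks, mirna_line = site.alignment.splitlines()
        assert target_line.startswith("target 5'")
        assert mirna_line.startswith("miRNA  3'")
        assert marks.count("|") == 20


class TestUpe:
    def test_unstructured_context_costs_nothing(self):
        tr = SequenceRecord("t", "A" * 60, Origin.TRANSCRIPT)
        site = mirscan.TargetSite("m", "t", 20, 40, 0.0, "CLEAVAGE", "")
        assert upe_estimate(tr, site) == 0.0

    def test_site_inside_hairpin_matches_constrained_enumeration(self):
        # a 14-nt region whose 5' half pairs its 3' half; opening the first
        # 4 nt must cost exactly the enumeration-oracle difference
        region = "GGGGAAAAAACCCC"
        tr = SequenceRecord("t", region, Origin.TRANSCRIPT)
        site = mirscan.TargetSite("m", "t", 0, 4, 0.0, "CLEAVAGE", "")
        config = TargetScanConfig(flank_up=0, flank_down=20)
        expected = enumerate_best_energy(region, blocked=(0, 1, 2, 3)) - enumerate_best_energy(region)
        assert upe_estimate(tr, site, config) == pytest.approx(expected)
        assert upe_estimate(tr, site, config) > 0

    def test_inaccessible_sites_excluded_when_upe_enabled(self):
        mir = _mir(3)
        tr, truth = make_transcript_with_site(mir.residues, [MATCH] * 20, seed=11)
        # embed the site's own reverse complement right downstream, making a
        # perfect long stem over the site
        seq = tr.residues
        site_seq = seq[truth["site_start"] : truth["site_end"]]
        stem = site_seq + "AAAA" + reverse_complement(site_seq, "RNA")
        tr2 = SequenceRecord(
            "t2", seq[: truth["site_start"]] + stem + seq[truth["site_end"] :],
            Origin.TRANSCRIPT,
        )
        open_cfg = TargetScanConfig(compute_upe=True, max_upe=1000.0)
        strict_cfg = TargetScanConfig(compute_upe=True, max_upe=10.0)
        with_upe = find_sites(mir, tr2, open_cfg)
        assert any(s.upe and s.upe > 10.0 for s in with_upe)
        strict_sites = find_sites(mir, tr2, strict_cfg)
        assert all(s.upe <= 10.0 for s in strict_sites)


class TestPredictTargets:
    def test_planted_sites_counted_exactly(self):
        mirnas = [_mir(s) for s in range(5)]
        transcripts, expected_pairs = [], 0
        for i, mir in enumerate(mirnas):
            for j in range(i % 3):
                tr, _ = make_transcript_with_site(mir.residues, [MATCH] * 20, seed=100 + 10 * i + j)
                transcripts.append(
                    SequenceRecord(f"t{i}_{j}", tr.residues, Origin.TRANSCRIPT)
                )
                expected_pairs += 1
        sites, summary = predict_targets(mirnas, transcripts)
        assert summary["n_pairs"] == expected_pairs
        assert summary["mean_targets_per_mirna"] == pytest.approx(expected_pairs / 5)

    def test_empty_transcriptome(self):
        sites, summary = predict_targets([_mir(1)], [])
        assert sites == [] and summary["n_pairs"] == 0
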