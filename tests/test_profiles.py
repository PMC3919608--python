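import math

import numpy as np
import pytest

from cfampol.io import AMINO_ACIDS, ProteinRecord
from cfampol.profiles import (
    ProfileMatrix,
    build_profile,
    calibrate_profile,
    detect_polymerases,
    empirical_pvalue,
    pairwise_identity,
    profile_from_json,
    profile_to_json,
    scan_score,
    scan_sequence,
)
from cfampol.synthetic import GeneratorConfig, _random_sequence, make_polymerase


def pure_python_sw(scores, seq_idx, gap_open, gap_extend):
    """Reference affine-gap local aligner (independent of the numba kernel)."""
    L, n = len(scores), len(seq_idx)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(L + 1)]
    E = [[NEG] * (n + 1) for _ in range(L + 1)]
    F = [[NEG] * (n + 1) for _ in range(L + 1)]
    best = 0.0
    for j in range(1, L + 1):
        for i in range(1, n + 1):
            E[j][i] = max(H[j - 1][i] - gap_open, E[j - 1][i]) - gap_extend
            F[j][i] = max(H[j][i - 1] - gap_open, F[j][i - 1]) - gap_extend
            h = max(0.0, H[j - 1][i - 1] + scores[j - 1][seq_idx[i - 1]], E[j][i], F[j][i])
            H[j][i] = h
            best = max(best, h)
    return best


class TestBuildProfile:
    def test_single_sequence_positive_self_scores(self):
        prof = build_profile(["ACD"])
        assert len(prof) == 3
        for col, aa in enumerate("ACD"):
            assert prof.scores[col, AMINO_ACIDS.index(aa)] > 0

    def test_half_gap_column_dropped(self):
        prof = build_profile(["AC", "A-", "AD", "A-"])
        assert len(prof) == 1  # second column is 50% gaps

    def test_closed_form_pure_column(self):
        # one fully conserved W column with a vanishing pseudocount:
        # score -> log2(1 / bg_W) = log2(20) under the flat background
        prof = build_profile(["W", "W", "W", "W"], pseudocount_weight=0.0)
        w = AMINO_ACIDS.index("W")
        assert prof.scores[0, w] == pytest.approx(math.log2(20.0), abs=1e-9)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["ACD", "AC"])

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])

    def test_json_round_trip(self):
        prof = build_profile(["ACDK", "ACDW"], name="x", source_span=(6, 889))
        back = profile_from_json(profile_to_json(prof))
        assert back.name == "x"
        assert back.source_span == (6, 889)
        np.testing.assert_allclose(back.scores, prof.scores)


class TestScan:
    def test_self_scan_is_sum_of_self_scores(self, rng):
        seq = _random_sequence(rng, 40)
        prof = build_profile([seq])
        hit = scan_sequence(prof, ProteinRecord("p", "g", seq))
        expected = sum(
            prof.scores[c, AMINO_ACIDS.index(aa)] for c, aa in enumerate(seq)
        )
        assert hit.bit_score == pytest.approx(expected, rel=1e-5)
        assert hit.coverage == pytest.approx(1.0)
        assert (hit.start, hit.end) == (0, len(seq))

    def test_self_scan_beats_any_shuffle(self, rng):
        seq = _random_sequence(rng, 60)
        prof = build_profile([seq])
        self_score = scan_score(prof, seq)
        for k in range(20):
            shuffled = "".join(np.random.default_rng(k).permutation(list(seq)))
            assert scan_score(prof, shuffled) <= self_score + 1e-6

    def test_unrelated_homopolymer_scores_low(self, rng):
        seq = _random_sequence(rng, 60).replace("A", "C")
        prof = build_profile([seq])
        self_score = scan_score(prof, seq)
        assert scan_score(prof, "A" * 60) <= self_score / 2

    def test_empty_sequence_rejected(self):
        prof = build_profile(["ACD"])
        with pytest.raises(ValueError):
            scan_sequence(prof, "")

    def test_numba_kernel_agrees_with_reference(self, rng):
        """Dual-route check of the DP kernel on small random problems."""
        for _ in range(10):
            cols = int(rng.integers(4, 15))
            prof = build_profile([_random_sequence(rng, cols)])
            seq = _random_sequence(rng, int(rng.integers(5, 25)))
            fast = scan_score(prof, seq)
            matrix = prof.scan_matrix.astype(float).tolist()
            idx = [
                AMINO_ACIDS.index(c) if c in AMINO_ACIDS else 20 for c in seq
            ]
            slow = pure_python_sw(matrix, idx, prof.gap_open, prof.gap_extend)
            assert fast == pytest.approx(slow, abs=1e-3)


class TestEmpiricalPvalue:
    def test_observed_below_all_shuffles_gives_one(self, rng):
        prof = build_profile([_random_sequence(rng, 20)])
        rec = ProteinRecord("p", "g", _random_sequence(rng, 50))
        assert empirical_pvalue(prof, rec, n_shuffles=19, seed=0, observed=0.0) == 1.0

    def test_observed_above_all_shuffles_plus_one_rule(self, rng):
        prof = build_profile([_random_sequence(rng, 20)])
        rec = ProteinRecord("p", "g", _random_sequence(rng, 50))
        assert empirical_pvalue(prof, rec, n_shuffles=99, seed=0, observed=1e9) == pytest.approx(
            1 / 100
        )

    def test_deterministic_per_seed(self, rng):
        prof = build_profile([_random_sequence(rng, 25)])
        rec = ProteinRecord("p", "g", _random_sequence(rng, 60))
        p1 = empirical_pvalue(prof, rec, n_shuffles=19, seed=7)
        p2 = empirical_pvalue(prof, rec, n_shuffles=19, seed=7)
        assert p1 == p2

    def test_monotone_in_observed_score(self, rng):
        prof = build_profile([_random_sequence(rng, 25)])
        rec = ProteinRecord("p", "g", _random_sequence(rng, 60))
        ps = [
            empirical_pvalue(prof, rec, n_shuffles=19, seed=3, observed=obs)
            for obs in (0.0, 5.0, 20.0, 1e9)
        ]
        assert ps == sorted(ps, reverse=True)

    def test_too_few_shuffles_rejected(self, rng):
        prof = build_profile([_random_sequence(rng, 20)])
        rec = ProteinRecord("p", "g", _random_sequence(rng, 30))
        with pytest.raises(ValueError):
            empirical_pvalue(prof, rec, n_shuffles=10)


class TestDetection:
    def test_planted_polymerase_among_decoys(self, tiny_library, tiny_profiles, rng):
        cfg = GeneratorConfig(seed=2, domain_lengths=tiny_library.lengths)
        planted = make_polymerase("DnaE1", cfg, tiny_library, rng, protein_id="pol")
        proteome = [planted.record] + [
            ProteinRecord(f"d{i}", "G", _random_sequence(rng, int(rng.integers(80, 300))))
            for i in range(50)
        ]
        hits = detect_polymerases(proteome, tiny_profiles["detection"], seed=5)
        assert [h.protein_id for h in hits] == ["pol"]

    def test_decoy_only_proteome_is_empty(self, tiny_profiles, rng):
        proteome = [
            ProteinRecord(f"d{i}", "G", _random_sequence(rng, 200)) for i in range(30)
        ]
        assert detect_polymerases(proteome, tiny_profiles["detection"], seed=5) == []

    def test_diverged_polymerase_still_detected(self, tiny_library, tiny_profiles, rng):
        # ~60% identity to the profile source
        cfg = GeneratorConfig(
            seed=3, divergence=0.4, domain_lengths=tiny_library.lengths
        )
        planted = make_polymerase("DnaE1", cfg, tiny_library, rng, protein_id="far")
        hits = detect_polymerases([planted.record], tiny_profiles["detection"], seed=5)
        assert [h.protein_id for h in hits] == ["far"]

    def test_empirical_route_agrees_on_clear_cases(self, tiny_library, tiny_profiles, rng):
        cfg = GeneratorConfig(seed=4, domain_lengths=tiny_library.lengths)
        planted = make_polymerase("DnaE1", cfg, tiny_library, rng, protein_id="pol")
        decoy = ProteinRecord("dec", "G", _random_sequence(rng, 250))
        hits = detect_polymerases(
            [planted.record, decoy],
            tiny_profiles["detection"],
            significance="empirical",
            n_shuffles=19,
            p_threshold=0.05,
            seed=5,
        )
        assert [h.protein_id for h in hits] == ["pol"]


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKVLY", "MKVLY") == 1.0

    def test_single_mismatch_over_ten(self):
        assert pairwise_identity("MKVLYWCHDE", "MKVLYWCHDQ") == pytest.approx(0.9)

    def test_totally_different(self):
        assert pairwise_identity("AAAA", "WWWW") == 0.0

    def test_symmetry_exact(self, rng):
        for _ in range(10):
            a = _random_sequence(rng, int(rng.integers(10, 60)))
            b = _random_sequence(rng, int(rng.integers(10, 60)))
            assert abs(pairwise_identity(a, b) - pairwise_identity(b, a)) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")


class TestCalibration:
    def test_pvalues_in_unit_interval_and_monotone(self, tiny_profiles):
        cal = calibrate_profile(tiny_profiles["PHP"], seed=1)
        ps = [cal.pvalue(s, 300) for s in (0.0, 10.0, 30.0, 100.0, 500.0)]
        assert all(0 < p <= 1 for p in ps)
        assert ps == sorted(ps, reverse=True)

    def test_calibration_deterministic(self, tiny_profiles):
        c1 = calibrate_profile(tiny_profiles["OB"], seed=9)
        c2 = calibrate_profile(tiny_profiles["OB"], seed=9)
        assert (c1.mu, c1.beta) == (c2.mu, c2.beta)
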