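import itertools
import math

import numpy as np
import pytest

from aptastruct import best_match, compute_frequencies, compute_pssm, delta_sse, score_string
from aptastruct.positional_pssm import matrix_frame, strings_to_counts
from aptastruct.sse_annotation import SSE_ALPHABET


class TestFrequencies:
    def test_single_string_gives_unit_indicators(self):
        pfm = compute_frequencies(["SHL"])
        assert pfm.freq[0, 0] == 1.0  # S at position 1
        assert pfm.freq.sum() == 3.0

    def test_counting_example(self):
        pfm = compute_frequencies(["S", "S", "H", "L"])
        assert pfm.freq[SSE_ALPHABET.index("S"), 0] == 0.5
        assert pfm.freq[SSE_ALPHABET.index("H"), 0] == 0.25
        assert pfm.freq[SSE_ALPHABET.index("L"), 0] == 0.25

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            compute_frequencies(["SS", "S"])

    def test_columns_sum_to_one(self, rng):
        strings = [
            "".join(rng.choice(list(SSE_ALPHABET), size=20)) for _ in range(50)
        ]
        pfm = compute_frequencies(strings)
        assert np.allclose(pfm.freq.sum(axis=0), 1.0)


class TestDeltaSSE:
    def test_identical_sets_zero(self):
        pfm = compute_frequencies(["SHL", "SHL"])
        assert np.all(delta_sse(pfm, pfm).delta == 0)

    def test_fifty_point_shift(self):
        dom = compute_frequencies(["S"])
        domsub = compute_frequencies(["S", "H"])
        d = delta_sse(dom, domsub).delta
        assert d[SSE_ALPHABET.index("S"), 0] == 50.0
        assert d[SSE_ALPHABET.index("H"), 0] == -50.0

    def test_columns_sum_to_zero(self, rng):
        a = ["".join(rng.choice(list(SSE_ALPHABET), size=10)) for _ in range(20)]
        b = ["".join(rng.choice(list(SSE_ALPHABET), size=10)) for _ in range(30)]
        d = delta_sse(compute_frequencies(a), compute_frequencies(b)).delta
        assert np.allclose(d.sum(axis=0), 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delta_sse(compute_frequencies(["S"]), compute_frequencies(["SS"]))


def _uniform_background():
    # one string per letter -> every column frequency is exactly 1/7
    return [k * 3 for k in SSE_ALPHABET]


class TestPSSM:
    def test_matched_foreground_scores_zero(self):
        # c = N * mu at every cell -> theta = mu -> S identically 0
        fg = [k * 3 for k in SSE_ALPHABET]
        p = compute_pssm(fg, _uniform_background(), alpha=1.0)
        assert np.allclose(p.S, 0.0)
        assert np.allclose(p.theta, p.mu)

    def test_hand_computed_cell(self):
        p = compute_pssm(["S", "S", "S", "H"], [k for k in SSE_ALPHABET], alpha=1.0)
        k = SSE_ALPHABET.index("S")
        assert p.mu[k, 0] == pytest.approx(1 / 7)
        assert p.theta[k, 0] == pytest.approx(4 / 11)
        assert p.W[k, 0] == pytest.approx(0.75 * math.log2((4 / 11) / (1 / 7)))

    def test_enrichment_sign_and_absence_display_score(self):
        fg = ["S"] * 3 + ["H"]
        # S-rich background keeps the column informative (H > 0) while the
        # foreground is still further S-enriched than the background
        bg = ["S"] * 8 + [k for k in "HLIGDM"]
        p = compute_pssm(fg, bg, alpha=1.0)
        s_idx = SSE_ALPHABET.index("S")
        d_idx = SSE_ALPHABET.index("D")
        assert p.S[s_idx, 0] > 0  # enriched over 1/7 background
        assert p.S[d_idx, 0] == 0  # absent element scores zero
        assert p.Dsp[d_idx, 0] < 0  # but displays as depletion

    def test_column_normalizations(self, rng):
        fg = ["".join(rng.choice(list(SSE_ALPHABET), size=15)) for _ in range(9)]
        bg = ["".join(rng.choice(list(SSE_ALPHABET), size=15)) for _ in range(40)]
        p = compute_pssm(fg, bg, alpha=0.7)
        assert np.allclose(p.mu.sum(axis=0), 1.0)
        assert np.allclose(p.theta.sum(axis=0), 1.0)

    def test_invariant_under_population_duplication(self, rng):
        # duplicating both populations with the pseudo-count scaled along
        # leaves every matrix unchanged (frequencies are what matter)
        fg = ["".join(rng.choice(list(SSE_ALPHABET), size=8)) for _ in range(6)]
        bg = ["".join(rng.choice(list(SSE_ALPHABET), size=8)) for _ in range(20)]
        p1 = compute_pssm(fg, bg, alpha=1.0)
        p2 = compute_pssm(fg * 2, bg * 2, alpha=2.0)
        assert np.allclose(p1.S, p2.S)
        assert np.allclose(p1.mu, p2.mu)
        assert np.allclose(p1.theta, p2.theta)

    def test_weight_monotone_in_enriched_foreground_count(self):
        # one more string carrying an already-enriched letter never
        # decreases that letter's position weight
        bg = ["S", "S", "H", "L", "I", "G", "D", "M"]
        base = ["S", "S", "H"]
        p_lo = compute_pssm(base, bg, alpha=1.0)
        p_hi = compute_pssm(base + ["S"], bg, alpha=1.0)
        k = SSE_ALPHABET.index("S")
        assert p_lo.freq[k, 0] >= p_lo.mu[k, 0]  # enriched regime
        assert p_hi.W[k, 0] >= p_lo.W[k, 0]

    def test_information_content_bounded(self, rng):
        fg = ["".join(rng.choice(list(SSE_ALPHABET), size=12)) for _ in range(9)]
        bg = ["".join(rng.choice(list(SSE_ALPHABET), size=12)) for _ in range(30)]
        p = compute_pssm(fg, bg, alpha=1.0)
        assert np.all(p.H >= 0.0)
        assert np.all(p.H <= np.log2(7) + 1e-9)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            compute_pssm(["S"], ["S"], alpha=0.0)


class TestScoring:
    def test_zero_matrix_scores_zero(self):
        fg = [k * 2 for k in SSE_ALPHABET]
        p = compute_pssm(fg, fg, alpha=1.0)
        # foreground == uniform -> S == 0 -> every string scores 0
        assert np.allclose(p.S, 0.0)
        assert score_string(p, "SH") == 0.0

    def test_argmax_string_maximal_on_toy_alphabet(self, rng):
        fg = ["SSH", "SHH", "SSL", "SSH", "HSH"]
        bg = ["".join(rng.choice(list(SSE_ALPHABET), size=3)) for _ in range(30)]
        p = compute_pssm(fg, bg, alpha=1.0)
        argmax = "".join(
            SSE_ALPHABET[int(np.argmax(p.S[:, j]))] for j in range(3)
        )
        best = max(
            score_string(p, "".join(combo))
            for combo in itertools.product(SSE_ALPHABET, repeat=3)
        )
        assert score_string(p, argmax) == pytest.approx(best)

    def test_best_match_finds_planted_argmax(self, rng):
        fg = ["SSH", "SHH", "SSL"]
        bg = ["".join(rng.choice(list(SSE_ALPHABET), size=3)) for _ in range(30)]
        p = compute_pssm(fg, bg, alpha=1.0)
        argmax = "".join(SSE_ALPHABET[int(np.argmax(p.S[:, j]))] for j in range(3))
        pop = {"a": "LLL", "b": argmax, "c": "MMM"}
        label, _ = best_match(p, pop)
        assert label == "b"

    def test_bad_letter_rejected(self):
        p = compute_pssm(["S"], ["S", "H"], alpha=1.0)
        with pytest.raises(ValueError, match="alphabet"):
            score_string(p, "X")

    def test_matrix_frame_layout(self):
        p = compute_pssm(["SH"], ["SH", "HS"], alpha=1.0)
        frame = matrix_frame(p.S)
        assert list(frame.index) == list(SSE_ALPHABET)
        assert list(frame.columns) == [1, 2]


class TestViennaPopulationTrend:
    def test_single_strand_dominates_five_prime_end(self):
        # folded standard-design strands keep the 5' end single-stranded
        from aptastruct.folding import FoldingConditions, ViennaRNAEngine, fold
        from aptastruct.library_synth import EQUIBASE_DESIGN, generate_library
        from aptastruct.sse_annotation import annotate_structure

        eng = ViennaRNAEngine()
        strings = []
        for rec in generate_library(EQUIBASE_DESIGN, 25, seed=2024):
            s1 = fold(rec, FoldingConditions(), eng)[0]
            strings.append(annotate_structure(s1.pairs).ss_string)
        pfm = compute_frequencies(strings)
        assert SSE_ALPHABET[int(np.argmax(pfm.freq[:, 0]))] == "S"
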