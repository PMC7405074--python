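"""Shuffled nulls, occurrence counting and Z scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kurtosis

from boutgrammar import (
    ModuleSequence,
    count_occurrences,
    enrichment_score,
    infinity_constant,
    normalize_columns,
    shuffle_self_scores,
    shuffle_within_windows,
)
from boutgrammar.enrichment import build_enrichment_matrix


def make_seq(tokens, windows=None):
    n = len(tokens)
    return ModuleSequence(
        "a", tokens, np.arange(n) * 5, np.full(n, 5),
        windows if windows is not None else ["w"] * n,
    )


def alternating(rng, n, n_mod=3):
    toks = []
    for i in range(n):
        kind = "A" if i % 2 == 0 else "I"
        toks.append(f"{kind}{rng.integers(1, n_mod + 1)}")
    return toks


class TestShuffle:
    def test_multiset_and_alternation_preserved(self, rng):
        windows = ["w1"] * 20 + ["w2"] * 20
        seq = make_seq(alternating(rng, 40), windows)
        for s in shuffle_within_windows(seq, 5, rng=rng):
            kinds = [t[0] for t in s.tokens]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))
            for w in ("w1", "w2"):
                for kind in "AI":
                    real = sorted(t for t, lw in zip(seq.tokens, windows)
                                  if lw == w and t[0] == kind)
                    shuf = sorted(t for t, lw in zip(s.tokens, windows)
                                  if lw == w and t[0] == kind)
                    assert real == shuf

    def test_identical_modules_shuffle_to_identity(self, rng):
        seq = make_seq(["A1", "I1"] * 10)
        for s in shuffle_within_windows(seq, 3, rng=rng):
            assert s.tokens == seq.tokens

    def test_same_seed_same_shuffles(self, rng):
        seq = make_seq(alternating(rng, 30))
        a = shuffle_within_windows(seq, 4, rng=np.random.default_rng(5))
        b = shuffle_within_windows(seq, 4, rng=np.random.default_rng(5))
        assert [s.tokens for s in a] == [s.tokens for s in b]

    def test_planted_motif_diluted_by_shuffling(self, rng):
        tokens = []
        for _ in range(50):
            tokens += ["A1", "I1", "A2", "I2"]
            tokens += alternating(rng, 4, 4)
        seq = make_seq(tokens)
        motif = ("A1", "I1", "A2", "I2")
        real = count_occurrences(seq, motif)
        shuf = np.mean([count_occurrences(s, motif)
                        for s in shuffle_within_windows(seq, 10, rng=rng)])
        assert real > shuf


class TestCounting:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [
            (list("ababab"), ("a", "b"), 3),
            (list("ababab"), ("z", "b"), 0),
            (list("ababa"), ("a", "b", "a"), 2),  # overlap allowed
            (list("ab"), ("a", "b", "a"), 0),  # motif longer than sequence
        ],
    )
    def test_overlapping_counts(self, seq, motif, expected):
        assert count_occurrences(seq, motif) == expected

    def test_non_overlapping_convention(self):
        assert count_occurrences(list("ababa"), ("a", "b", "a"),
                                 overlapping=False) == 1

    def test_counts_respect_gaps(self):
        seq = make_seq(["A1", "I1", "A1", "I1"])
        seq.excluded[1] = True
        assert count_occurrences(seq, ("A1", "I1")) == 1


class TestScore:
    def test_printed_worked_example(self):
        # Integer shuffle counts with mean 4.5 and sample SD 1.58.
        shuffles = [2, 3, 3, 4, 4, 5, 5, 6, 6, 7]
        assert np.mean(shuffles) == 4.5
        assert round(float(np.std(shuffles, ddof=1)), 2) == 1.58
        assert round(enrichment_score(10, shuffles), 2) == 3.48

    def test_equal_to_shuffle_mean_is_zero(self):
        assert enrichment_score(4, [4, 4, 3, 5, 4, 4, 4, 4, 4, 4]) == 0.0

    def test_infinity_rule(self):
        shuffles = [4] * 10
        assert enrichment_score(9, shuffles) == pytest.approx(np.sqrt(11))
        assert enrichment_score(1, shuffles) == pytest.approx(-np.sqrt(11))
        assert enrichment_score(4, shuffles) == 0.0
        assert round(infinity_constant(10), 2) == 3.32

    @given(st.lists(st.integers(0, 20), min_size=10, max_size=10),
           st.integers(0, 30))
    def test_self_scores_match_bruteforce(self, shuffles, x):
        out = shuffle_self_scores(shuffles)
        for j in range(10):
            others = [s for i, s in enumerate(shuffles) if i != j]
            mean = np.mean(others)
            sd = np.std(others, ddof=1)
            if sd == 0:
                expected = (np.sqrt(10) * np.sign(shuffles[j] - mean)
                            if shuffles[j] != mean else 0.0)
            else:
                expected = (shuffles[j] - mean) / sd
            assert out[j] == pytest.approx(expected)

    def test_all_equal_shuffles_score_zero(self):
        assert np.all(shuffle_self_scores([3] * 10) == 0)


class TestNormalize:
    def test_constant_column_zeroed_and_flagged(self):
        m = np.array([[1.0, 2.0], [1.0, 4.0]])
        out, flags = normalize_columns(m)
        assert np.all(out[:, 0] == 0) and flags[0] and not flags[1]

    def test_two_point_column_unchanged(self):
        out, _ = normalize_columns(np.array([[-1.0], [1.0]]))
        np.testing.assert_allclose(out, [[-1.0], [1.0]])

    def test_columns_standardized(self, rng):
        out, _ = normalize_columns(rng.normal(2, 3, size=(40, 6)))
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0), 1, atol=1e-10)


class TestMatrix:
    def test_matrix_and_infinite_fraction(self):
        real = pd.DataFrame([[10, 4], [0, 4]], index=["s1", "s2"], columns=["m1", "m2"])
        shuffled = {
            "s1": np.column_stack([[2, 3, 3, 4, 4, 5, 5, 6, 6, 7], [4] * 10]),
            "s2": np.column_stack([[0] * 10, [4] * 10]),
        }
        z, frac = build_enrichment_matrix(real, shuffled)
        assert round(z.loc["s1", "m1"], 2) == 3.48
        assert z.loc["s1", "m2"] == 0.0  # equal branch of the infinity rule
        assert z.loc["s2", "m1"] == 0.0  # zero real, zero shuffles
        assert z.loc["s2", "m2"] == 0.0
        assert frac == 0.0

    def test_kurtosis_real_exceeds_shuffles_on_planted_data(self):
        """Planted sequential structure fattens the tails of the real score
        distribution relative to the shuffle-vs-shuffle null."""
        from boutgrammar import (
            MotifLibrary, PlantedMotif, SimulationSpec, count_library,
            generate_module_sequence,
        )

        spec = SimulationSpec.default(seed=3)
        spec.planted_motifs = [
            PlantedMotif(("A2", "I2", "A3", "I3"), {"day": 0.02}),
            PlantedMotif(("A3", "I1", "A2", "I4"), {"day": 0.01}),
        ]
        rng = np.random.default_rng(3)
        real_z, null_z = [], []
        lib_motifs = [tuple(m.tokens) for m in spec.planted_motifs]
        lib_motifs += [(f"A{i}", f"I{j}") for i in range(1, 6) for j in range(1, 6)]
        lib_motifs = sorted(set(lib_motifs), key=lambda m: (len(m), m))
        lib = MotifLibrary(lib_motifs, [1] * len(lib_motifs))
        for _ in range(4):
            seq, _ = generate_module_sequence(spec, 3000, rng=rng)
            shuffles = shuffle_within_windows(seq, 10, rng=rng)
            x = count_library(seq, lib)
            s = np.stack([count_library(sh, lib) for sh in shuffles])
            for j in range(len(lib)):
                real_z.append(enrichment_score(x[j], s[:, j]))
                null_z.extend(shuffle_self_scores(s[:, j]))
        assert kurtosis(real_z) > kurtosis(null_z)
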