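"""Compression: savings, greedy heuristic vs brute force, library, blocks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boutgrammar import (
    Grammar,
    block_compressibility,
    build_library,
    compress_tokens,
    delta_compressibility,
    savings,
)
from boutgrammar.compression import Rule

from _oracles import best_motif_bruteforce, compress_bruteforce


class TestSavings:
    @pytest.mark.parametrize("w,n,expected", [(2, 4, 1), (3, 5, 6), (2, 2, -1)])
    def test_values(self, w, n, expected):
        assert savings(w, n) == expected

    @pytest.mark.parametrize("n", [1, 3, 10])
    def test_single_symbols_never_compress(self, n):
        assert savings(1, n) == -2

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            savings(0, 3)


class TestCompress:
    def test_alternating_pair_sequence(self):
        g = compress_tokens(list("abababab"))
        assert g.total_savings == 1
        assert g.compressibility == pytest.approx(1 / 8)

    def test_triplet_beats_pair(self):
        g = compress_tokens(list("abcabcabcabc"))
        assert g.rules[0].rhs == ("a", "b", "c")
        assert g.rules[0].count == 4
        assert g.rules[0].savings == 4
        assert g.compressibility == pytest.approx(1 / 3)

    def test_all_distinct_is_incompressible(self):
        g = compress_tokens(list("abcdefg"))
        assert g.rules == []
        assert g.compressibility == 0.0

    def test_empty_sequence(self):
        g = compress_tokens([])
        assert g.compressibility == 0.0 and g.rules == []

    def test_motifs_never_span_segment_gaps(self):
        # 'ab' only occurs across segment boundaries, so nothing compresses;
        # the same tokens as one segment do.
        g = compress_tokens([["a"], ["b"]] * 4)
        assert g.rules == []
        joined = compress_tokens(list("abababab"))
        assert joined.total_savings > 0
        # Repeats fully inside segments still compress.
        within = compress_tokens([["a", "b"]] * 4)
        assert within.total_savings > 0

    @given(
        st.lists(st.sampled_from("abc"), min_size=2, max_size=60),
        st.integers(min_value=2, max_value=6),
    )
    def test_round_trip_and_bounds(self, tokens, max_len):
        g = compress_tokens(tokens, max_len=max_len)
        assert g.expand_segments() == [tuple(tokens)]
        assert 0 <= g.compressibility < 1
        assert all(r.savings > 0 for r in g.rules)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_long_sequences(self, seed):
        # Exercises the vectorized rolling-hash path (n >= 64) against the
        # exhaustive scan oracle, including full replacement iteration.
        rng = np.random.default_rng(seed)
        tokens = [str(t) for t in rng.integers(0, 3, size=150)]
        g = compress_tokens(tokens)
        rules, total, final, original = compress_bruteforce(tokens)
        assert [(r.rhs, r.savings) for r in g.rules] == [(m, s) for _, m, s in rules]
        assert g.total_savings == total


class TestExpand:
    def test_terminal_symbol_expands_to_itself(self):
        g = compress_tokens(list("ab"))
        assert g.expand("a") == ("a",)

    def test_two_level_nesting(self):
        g = Grammar(
            rules=[Rule("X", ("a", "b"), 1, 2), Rule("Y", ("X", "X"), 1, 2)],
            original_length=8,
            compressed_segments=[("Y",)],
        )
        assert g.expand("Y") == ("a", "b", "a", "b")

    def test_unknown_rule_symbol_rejected(self):
        g = compress_tokens(list("ab"))
        with pytest.raises(KeyError):
            g.expand("R99")

    def test_nesting_discovers_motifs_beyond_max_len(self):
        # A 6-long repeat compressed with max_len=4 still emerges via nesting.
        unit = list("abcdef")
        tokens = (unit + list("x")) * 6
        g = compress_tokens(tokens, max_len=4)
        assert tuple(unit) in {g.expand(r.lhs) for r in g.rules} | {
            tuple(g.expand(t)) for seg in g.compressed_segments for t in seg
        } or any(len(g.expand(r.lhs)) > 4 for r in g.rules)


class TestLibrary:
    def test_shared_motif_kept_once(self):
        g1 = compress_tokens(list("ab") * 8)
        g2 = compress_tokens(list("ab") * 4 + list("cd") * 8)
        lib = build_library([g1, g2])
        counts = dict(zip(lib.motifs, lib.source_counts))
        assert any(c == 2 for c in counts.values())
        assert all(lib.motifs.count(m) == 1 for m in lib.motifs)

    def test_empty_grammars(self):
        g = compress_tokens(list("abcd"))
        assert len(build_library([g, g])) == 0

    def test_canonical_order(self):
        g1 = compress_tokens(list("xy") * 8 + list("xyz") * 4)
        g2 = compress_tokens(list("ab") * 8)
        lib = build_library([g1, g2])
        assert lib.motifs == sorted(lib.motifs, key=lambda m: (len(m), m))

    def test_file_round_trip(self, tmp_path):
        lib = build_library([compress_tokens(list("ab") * 8)])
        path = tmp_path / "lib.tsv"
        lib.to_file(path)
        loaded = type(lib).from_file(path)
        assert loaded.motifs == lib.motifs
        assert loaded.source_counts == lib.source_counts


class TestBlocks:
    def test_block_count(self, rng):
        tokens = [str(t) for t in rng.integers(0, 5, size=1000)]
        values = block_compressibility(tokens, block=500)
        assert len(values) == 2

    def test_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            values = block_compressibility(list("ab"), block=500)
        assert len(values) == 0

    def test_periodic_block_beats_shuffled(self, rng):
        periodic = list("abcd") * 125
        shuffled = list(periodic)
        rng.shuffle(shuffled)
        v_per = block_compressibility(periodic, block=500)[0]
        v_shuf = block_compressibility(shuffled, block=500)[0]
        assert v_per > v_shuf

    def test_incompressible_block_scores_zero(self):
        tokens = [f"t{i}" for i in range(500)]
        assert block_compressibility(tokens, block=500)[0] == 0.0

    def test_blocks_remove_length_dependence(self, rng):
        # Full-sequence compressibility grows with length on statistically
        # identical data; fixed-size block values do not.
        full, blocks = [], []
        for n in (500, 1000, 2000, 4000):
            tokens = [str(t) for t in rng.integers(0, 4, size=n)]
            full.append(compress_tokens(tokens).compressibility)
            blocks.append(block_compressibility(tokens, block=500).mean())
        assert full == sorted(full)  # monotone increase with length
        assert max(blocks) - min(blocks) < full[-1] - full[0]


class TestDelta:
    def test_identical_shuffles_give_zero(self):
        real = np.array([0.5, 0.2])
        shuf = np.tile(real[:, None], (1, 10))
        np.testing.assert_allclose(delta_compressibility(real, shuf), 0.0)

    def test_mismatched_pairing_rejected(self):
        with pytest.raises(ValueError):
            delta_compressibility(np.zeros(3), np.zeros((2, 10)))

    def test_planted_repeat_has_positive_delta(self, rng):
        from boutgrammar import ModuleSequence, shuffle_within_windows

        tokens = []
        for _ in range(60):
            tokens += ["A1", "I1", "A2", "I2"] if rng.random() < 0.5 else (
                [f"A{rng.integers(1, 6)}", f"I{rng.integers(1, 6)}"] * 2)
        seq = ModuleSequence("a", tokens, np.arange(len(tokens)) * 3,
                             np.full(len(tokens), 3), ["w"] * len(tokens))
        real = compress_tokens(seq.tokens).compressibility
        shuf = [compress_tokens(s.tokens).compressibility
                for s in shuffle_within_windows(seq, 10, rng=rng)]
        delta = delta_compressibility(np.array([real]), np.array([shuf]))
        assert delta[0] > 0


@pytest.mark.parametrize("seed", range(5))
def test_first_motif_matches_bruteforce(seed, rng):
    rng = np.random.default_rng(seed + 100)
    tokens = [str(t) for t in rng.integers(0, 4, size=80)]
    g = compress_tokens(tokens)
    best = best_motif_bruteforce(tokens)
    if best is None:
        assert g.rules == []
    else:
        assert g.rules[0].rhs == best[2]
        assert g.rules[0].savings == best[0]


def test_compressibility_monotone_in_planted_rate():
    """Spearman correlation between planted-motif rate and compressibility
    must be positive across rates."""
    from scipy.stats import spearmanr

    from boutgrammar import PlantedMotif, SimulationSpec, generate_module_sequence

    rates = [0.0, 0.01, 0.02, 0.04, 0.08]
    values, labels = [], []
    for rate in rates:
        for seed in (1, 2, 3):
            spec = SimulationSpec.default(seed=seed)
            spec.planted_motifs = [
                PlantedMotif(("A2", "I2", "A3", "I3"), {"day": rate})
            ]
            seq, _ = generate_module_sequence(spec, 800)
            values.append(compress_tokens(seq.tokens).compressibility)
            labels.append(rate)
    rho, _ = spearmanr(labels, values)
    assert rho > 0
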