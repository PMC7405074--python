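"""Offline most-compressive-motif compression of module sequences.

At each iteration the algorithm scans the current (partially compressed)
sequence for the contiguous motif of length 2..``max_len`` whose greedy
non-overlapping occurrence count N and length W maximize the savings

    savings = W*N - (W + 1 + N)

i.e. the symbols removed minus the cost of storing the new rule (W + 1)
and writing its symbol at each occurrence (N).  Every counted occurrence is
replaced by a fresh symbol and the scan repeats until no motif saves
anything.  Because later iterations see earlier rule symbols, rules nest,
so terminal motifs longer than ``max_len`` emerge.  Compressibility is the
total savings divided by the original sequence length, in [0, 1).

Ties between equally compressive motifs are broken toward the longer motif
and then the lexicographically smallest token tuple, so output is
deterministic.  Candidate motifs never span excluded-module gaps: the
sequence is split into segments first and every segment boundary is an
impassable barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequences import ModuleSequence

__all__ = [
    "savings",
    "Grammar",
    "Rule",
    "MotifLibrary",
    "compress",
    "compress_tokens",
    "build_library",
    "block_compressibility",
    "delta_compressibility",
]

_HASH_BASE = np.uint64(0x9E3779B97F4A7C15)  # odd 64-bit multiplier
_SMALL_N = 64  # below this, the dict scan beats the vectorized scan


def savings(w: int, n: int) -> int:
    """Symbols saved by replacing ``n`` occurrences of a ``w``-long motif."""
    if w < 1 or n < 1:
        raise ValueError("W and N must be >= 1")
    return w * n - (w + 1 + n)


@dataclass(frozen=True)
class Rule:
    lhs: str
    rhs: tuple[str, ...]
    savings: int
    count: int


@dataclass
class Grammar:
    """Rules discovered by compression, in discovery order."""

    rules: list[Rule]
    original_length: int
    compressed_segments: list[tuple[str, ...]]
    _expansions: dict = field(default_factory=dict, repr=False)

    @property
    def total_savings(self) -> int:
        return sum(r.savings for r in self.rules)

    @property
    def compressibility(self) -> float:
        if self.original_length == 0:
            return 0.0
        return self.total_savings / self.original_length

    def expand(self, symbol: str) -> tuple[str, ...]:
        """Fully terminal module sequence for a symbol (itself if terminal)."""
        if symbol in self._expansions:
            return self._expansions[symbol]
        by_lhs = {r.lhs: r for r in self.rules}
        if symbol not in by_lhs:
            if symbol.startswith("R") and symbol[1:].isdigit():
                raise KeyError(f"unknown rule symbol {symbol!r}")
            return (symbol,)

        def _exp(sym: str) -> tuple[str, ...]:
            if sym in self._expansions:
                return self._expansions[sym]
            rule = by_lhs.get(sym)
            if rule is None:
                return (sym,)
            out = tuple(t for part in rule.rhs for t in _exp(part))
            self._expansions[sym] = out
            return out

        return _exp(symbol)

    def motifs(self) -> list[tuple[str, ...]]:
        """Terminal motif for each rule, in discovery order."""
        return [self.expand(r.lhs) for r in self.rules]

    def expand_segments(self) -> list[tuple[str, ...]]:
        """Round trip: expanding the compressed sequence restores the input."""
        return [
            tuple(t for sym in seg for t in self.expand(sym))
            for seg in self.compressed_segments
        ]


# ---------------------------------------------------------------------------
# Core iteration
# ---------------------------------------------------------------------------

def _greedy_positions(positions, w: int):
    """Left-to-right non-overlapping subset of sorted start positions."""
    kept = []
    last_end = -1
    for p in positions:
        if p >= last_end:
            kept.append(p)
            last_end = p + w
    return kept

def _better(cand, best) -> bool:
    """True if cand=(savings, W, tokens) beats best under the tie-break."""
    if best is None:
        return True
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] > best[1]
    return cand[2] < best[2]


def _best_motif_small(arr, id2tok, max_len):
    """Exhaustive dict scan; used for short sequences."""
    n = len(arr)
    pos: dict[tuple, list[int]] = {}
    for w in range(2, min(max_len, n) + 1):
        for i in range(n - w + 1):
            window = tuple(arr[i : i + w])
            if any(t < 0 for t in window):  # spans a segment barrier
                continue
            pos.setdefault(window, []).append(i)
    best = None
    best_pos = None
    for window, plist in pos.items():
        if len(plist) < 2:
            continue
        w = len(window)
        kept = _greedy_positions(plist, w)
        s = savings(w, len(kept))
        if s <= 0:
            continue
        cand = (s, w, tuple(id2tok[t] for t in window))
        if _better(cand, best):
            best, best_pos = cand, (window, kept)
    if best is None:
        return None
    return best[0], len(best_pos[0]), np.asarray(best_pos[0]), best_pos[1]


def _best_motif_hashed(arr, id2tok, max_len):
    """Vectorized rolling-hash scan with exact verification.

    Upper-bounds each candidate's savings from its overlapping occurrence
    count (savings is increasing in N), then confirms candidates in
    descending bound order with exact greedy counts until no bound can beat
    the incumbent.  Hash collisions are resolved by comparing tokens, so the
    result is exact.
    """
    n = len(arr)
    a = arr.astype(np.int64).view(np.uint64)
    hashes = {}
    cands = []  # (ub, L, hash value)
    h = a.copy()
    for L in range(2, min(max_len, n) + 1):
        h = h[:-1] * _HASH_BASE + a[L - 1 :]
        hashes[L] = h
        uniq, counts = np.unique(h, return_counts=True)
        rep = counts >= 2
        if not rep.any():
            continue
        uniq, counts = uniq[rep], counts[rep]
        ub = L * counts - (L + 1 + counts)
        good = ub > 0
        for u, b in zip(uniq[good], ub[good]):
            cands.append((int(b), L, u))
    if not cands:
        return None
    cands.sort(key=lambda t: -t[0])

    best = None
    best_out = None
    for ub, L, hval in cands:
        if best is not None and ub < best[0]:
            break
        positions = np.flatnonzero(hashes[L] == hval)
        # Windows with a negative token span a segment barrier; barriers are
        # unique sentinels so such windows can only collide, never repeat.
        while positions.size >= 2:
            ref = arr[positions[0] : positions[0] + L]
            if (ref < 0).any():
                matched = np.array([positions[0]])
            else:
                block = arr[positions[:, None] + np.arange(L)]
                same = (block == ref).all(axis=1)
                matched = positions[same]
            rest = np.setdiff1d(positions, matched, assume_unique=True)
            if matched.size >= 2 and (ref >= 0).all():
                kept = _greedy_positions(matched.tolist(), L)
                s = savings(L, len(kept))
                if s > 0:
                    cand = (s, L, tuple(id2tok[t] for t in ref))
                    if _better(cand, best):
                        best = cand
                        best_out = (ref.copy(), kept)
            positions = rest
    if best is None:
        return None
    return best[0], L_of(best_out[0]), best_out[0], best_out[1]


def L_of(ref) -> int:
    return int(len(ref))


def _replace(arr, kept, w, new_id):
    keep = np.ones(len(arr), dtype=bool)
    for p in kept:
        arr[p] = new_id
        keep[p + 1 : p + w] = False
    return arr[keep]


def compress_tokens(segments, max_len: int = 10, rule_prefix: str = "R") -> Grammar:
    """Compress one or more token segments into a :class:`Grammar`.

    ``segments`` is either a flat sequence of hashable tokens or a list of
    such sequences (pre-split at masked gaps); motifs never span segment
    boundaries.  ``max_len`` caps the motif length scanned per iteration
    (nested rules can expand beyond it).
    """
    if segments and not isinstance(segments[0], (list, tuple)):
        segments = [list(segments)]
    segments = [list(s) for s in segments if len(s)]
    original_length = sum(len(s) for s in segments)

    tok2id: dict = {}
    id2tok: list = []

    def _id(tok):
        if tok not in tok2id:
            tok2id[tok] = len(id2tok)
            id2tok.append(tok)
        return tok2id[tok]

    parts = []
    sentinel = -1
    for i, seg in enumerate(segments):
        if i:
            parts.append([sentinel])
            sentinel -= 1
        parts.append([_id(t) for t in seg])
    arr = np.array([t for p in parts for t in p], dtype=np.int64)

    rules: list[Rule] = []
    n_rules = 0
    while len(arr) >= 2:
        finder = _best_motif_small if len(arr) < _SMALL_N else _best_motif_hashed
        found = finder(arr, id2tok, max_len)
        if found is None:
            break
        s, w, motif_ids, kept = found
        n_rules += 1
        lhs = f"{rule_prefix}{n_rules}"
        rhs = tuple(id2tok[t] for t in motif_ids)
        rules.append(Rule(lhs=lhs, rhs=rhs, savings=int(s), count=len(kept)))
        new_id = _id(lhs)
        arr = _replace(arr, kept, w, new_id)

    out_segments: list[tuple[str, ...]] = []
    cur: list = []
    for t in arr:
        if t < 0:
            out_segments.append(tuple(cur))
            cur = []
        else:
            cur.append(id2tok[t])
    out_segments.append(tuple(cur))
    if not segments:
        out_segments = []
    return Grammar(rules=rules, original_length=original_length,
                   compressed_segments=out_segments)


def compress(seq: ModuleSequence, max_len: int = 10) -> Grammar:
    """Compress a module sequence (split at excluded-module gaps)."""
    return compress_tokens(seq.segments(), max_len=max_len)


@dataclass
class MotifLibrary:
    """Unique terminal motifs merged across animals' grammars.

    Canonically ordered by length and then lexicographically by module
    token, so a library built from the same grammars is always identical.
    """

    motifs: list[tuple[str, ...]]
    source_counts: list[int]  # number of grammars contributing each motif

    def __len__(self) -> int:
        return len(self.motifs)

    def index(self) -> dict[tuple[str, ...], int]:
        return {m: i for i, m in enumerate(self.motifs)}

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for m, c in zip(self.motifs, self.source_counts):
                fh.write(" ".join(m) + "\t" + str(c) + "\n")

    @classmethod
    def from_file(cls, path) -> "MotifLibrary":
        motifs, counts = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                toks, _, c = line.partition("\t")
                motifs.append(tuple(toks.split()))
                counts.append(int(c) if c else 1)
        return cls(motifs, counts)


def build_library(grammars) -> MotifLibrary:
    """Merge every grammar's terminal motifs, keeping each unique motif once."""
    counts: dict[tuple[str, ...], int] = {}
    for g in grammars:
        for m in set(g.motifs()):
            counts[m] = counts.get(m, 0) + 1
    motifs = sorted(counts, key=lambda m: (len(m), m))
    return MotifLibrary(motifs=motifs, source_counts=[counts[m] for m in motifs])


def block_compressibility(seq, block: int = 500, max_len: int = 10) -> np.ndarray:
    """Compressibility of consecutive non-overlapping ``block``-module blocks.

    Compressibility varies non-linearly with sequence length, so samples
    with different module counts are compared on fixed-size blocks; the
    trailing partial block is dropped.  ``seq`` may be a
    :class:`ModuleSequence` or a list of token segments.
    """
    if isinstance(seq, ModuleSequence):
        segments = seq.segments()
    elif seq and not isinstance(seq[0], (list, tuple)):
        segments = [list(seq)]
    else:
        segments = [list(s) for s in seq]
    stream = [(i, t) for i, seg in enumerate(segments) for t in seg]
    n = len(stream)
    if n < block:
        warnings.warn(f"sequence has {n} modules, fewer than one {block}-module block")
        return np.empty(0)
    values = []
    for b in range(n // block):
        chunk = stream[b * block : (b + 1) * block]
        segs: list[list] = []
        prev = None
        for seg_i, tok in chunk:
            if seg_i != prev:
                segs.append([])
                prev = seg_i
            segs[-1].append(tok)
        values.append(compress_tokens(segs, max_len=max_len).compressibility)
    return np.asarray(values)


def delta_compressibility(real: np.ndarray, shuffled: np.ndarray) -> np.ndarray:
    """Per-sample real compressibility minus the mean of its paired shuffles.

    ``real`` has shape (n_samples,), ``shuffled`` (n_samples, n_shuffles);
    rows must be paired (same animal and window).
    """
    real = np.asarray(real, dtype=float)
    shuffled = np.asarray(shuffled, dtype=float)
    if shuffled.ndim != 2 or shuffled.shape[0] != real.shape[0]:
        raise ValueError("shuffled values are not paired with the real values")
    return real - shuffled.mean(axis=1)
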