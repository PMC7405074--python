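"""Independent brute-force oracles used by the test suite.

These re-derive expected results by exhaustive enumeration, deliberately
sharing no code with the package implementation beyond the documented
contracts (savings formula, greedy non-overlapping counts, tie-breaks).
"""

from __future__ import annotations


def greedy_count(seq, motif):
    """Left-to-right non-overlapping occurrence count by direct scan."""
    w = len(motif)
    count = 0
    i = 0
    while i <= len(seq) - w:
        if tuple(seq[i : i + w]) == tuple(motif):
            count += 1
            i += w
        else:
            i += 1
    return count


def best_motif_bruteforce(seq, max_len=10):
    """Exhaustively search the maximal-savings motif with the documented
    tie-break (savings, then longer, then lexicographically smallest)."""
    seq = list(seq)
    best = None
    for w in range(2, min(max_len, len(seq)) + 1):
        seen = set()
        for i in range(len(seq) - w + 1):
            motif = tuple(seq[i : i + w])
            if motif in seen:
                continue
            seen.add(motif)
            n = greedy_count(seq, motif)
            if n < 1:
                continue
            s = w * n - (w + 1 + n)
            if s <= 0:
                continue
            cand = (s, w, motif)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
                cand[0] == best[0] and cand[1] == best[1] and cand[2] < best[2]
            ):
                best = cand
    return best  # (savings, w, motif) or None


def compress_bruteforce(seq, max_len=10):
    """Full iterative compression by brute force; returns (rules, savings)."""
    seq = list(seq)
    original = len(seq)
    rules = []
    total = 0
    n_rules = 0
    while True:
        best = best_motif_bruteforce(seq, max_len)
        if best is None:
            break
        s, w, motif = best
        n_rules += 1
        sym = f"R{n_rules}"
        out = []
        i = 0
        while i < len(seq):
            if tuple(seq[i : i + w]) == motif:
                out.append(sym)
                i += w
            else:
                out.append(seq[i])
                i += 1
        seq = out
        rules.append((sym, motif, s))
        total += s
    return rules, total, seq, original


def mrmr_bruteforce(xd, yd, top):
    """Naive mRMR (MID) on pre-discretized columns, plain-python MI."""
    import math
    from collections import Counter

    n, m = len(xd), len(xd[0])

    def mi(a, b):
        ja = Counter(a)
        jb = Counter(b)
        jab = Counter(zip(a, b))
        total = 0.0
        for (va, vb), c in jab.items():
            pab = c / n
            total += pab * math.log(pab / ((ja[va] / n) * (jb[vb] / n)))
        return total

    cols = [[row[j] for row in xd] for j in range(m)]
    rel = [mi(c, yd) for c in cols]
    chosen = []
    red_sum = [0.0] * m
    for step in range(min(top, m)):
        best_j, best_score = None, None
        for j in range(m):
            if j in chosen:
                continue
            if step == 0:
                score = rel[j]
            else:
                score = rel[j] - red_sum[j] / len(chosen)
            if best_score is None or score > best_score + 1e-12:
                best_j, best_score = j, score
        chosen.append(best_j)
        for j in range(m):
            if j not in chosen:
                red_sum[j] += mi(cols[j], cols[best_j])
    return chosen
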