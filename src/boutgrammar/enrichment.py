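"""Shuffle-normalized motif enrichment/constraint scores.

For every animal and time window, each library motif's occurrence count in
the real module sequence is compared with its counts in 10 paired shuffles
of the same window.  Shuffling permutes active module ids among active
slots and inactive ids among inactive slots independently, within each
window, so the module multisets and the active/inactive transition
structure are preserved while sequential structure is destroyed.  The
enrichment/constraint score is the Z deviation of the real count from the
shuffled counts,

    Z = (x - mean(shuffles)) / SD(shuffles)

positive when a motif is used more than chance (enriched), negative when
less (constrained).  When the shuffle SD is zero the score is infinite and
is replaced by the constant ±sqrt(1 + n_shuffles) (±3.32 for 10 shuffles),
or 0 when the real count equals the shuffle mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import as_rng
from .compression import MotifLibrary
from .sequences import ModuleSequence

__all__ = [
    "shuffle_within_windows",
    "count_occurrences",
    "count_library",
    "enrichment_score",
    "shuffle_self_scores",
    "infinity_constant",
    "build_enrichment_matrix",
    "normalize_columns",
]

DEFAULT_N_SHUFFLES = 10


def infinity_constant(n_shuffles: int = DEFAULT_N_SHUFFLES) -> float:
    """Replacement value for infinite scores: sqrt(1 + number of shuffles)."""
    return float(np.sqrt(1 + n_shuffles))


def shuffle_within_windows(
    seq: ModuleSequence,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng=None,
    sample_windows=None,
) -> list[ModuleSequence]:
    """Paired shuffles preserving per-window module multisets and alternation.

    Within every window (the sequence's own labels, or ``sample_windows``
    re-binned by start frame), the active module ids are permuted among the
    window's active slots and the inactive ids among its inactive slots.
    Module lengths travel with their tokens.  Excluded modules stay fixed.
    Windows with <= 1 module of a kind are necessarily unchanged for that
    kind.
    """
    rng = as_rng(rng)
    n = len(seq)
    if sample_windows is not None:
        starts = np.array([w.start for w in sample_windows])
        idx = np.clip(np.searchsorted(starts, seq.starts, side="right") - 1, 0,
                      len(sample_windows) - 1)
        labels = [sample_windows[i].label for i in idx]
    else:
        labels = seq.windows
    active = np.array([t[0] == "A" for t in seq.tokens])
    slots: dict[tuple[str, bool], list[int]] = {}
    for i in range(n):
        if not seq.excluded[i]:
            slots.setdefault((labels[i], bool(active[i])), []).append(i)

    out = []
    for _ in range(n_shuffles):
        tokens = list(seq.tokens)
        lengths = seq.lengths.copy()
        for idxs in slots.values():
            idxs_arr = np.asarray(idxs)
            perm = idxs_arr[rng.permutation(len(idxs_arr))]
            for dst, src in zip(idxs_arr, perm):
                tokens[dst] = seq.tokens[src]
                lengths[dst] = seq.lengths[src]
        starts_new = seq.starts[0] + np.concatenate([[0], np.cumsum(lengths[:-1])])
        out.append(
            ModuleSequence(
                animal_id=seq.animal_id,
                tokens=tokens,
                starts=starts_new,
                lengths=lengths,
                windows=list(seq.windows),
                excluded=seq.excluded.copy(),
            )
        )
    return out


def _as_segments(seq) -> list[list[str]]:
    if isinstance(seq, ModuleSequence):
        return seq.segments()
    if seq and not isinstance(seq[0], (list, tuple)):
        return [list(seq)]
    return [list(s) for s in seq]


def count_occurrences(seq, motif, overlapping: bool = True) -> int:
    """Number of exact matches of ``motif`` in a sequence.

    Sliding matches by default (overlaps allowed), so the count does not
    depend on any replacement order; set ``overlapping=False`` for greedy
    left-to-right non-overlapping counts.  Matches never span excluded-gap
    boundaries.
    """
    motif = tuple(motif)
    w = len(motif)
    if w == 0:
        raise ValueError("motif must be non-empty")
    total = 0
    for seg in _as_segments(seq):
        i = 0
        while i <= len(seg) - w:
            if tuple(seg[i : i + w]) == motif:
                total += 1
                i += 1 if overlapping else w
            else:
                i += 1
    return total


def count_library(seq, library: MotifLibrary, overlapping: bool = True) -> np.ndarray:
    """Occurrence counts of every library motif in one sequence."""
    segments = _as_segments(seq)
    index = library.index()
    lengths = sorted({len(m) for m in library.motifs})
    counts = np.zeros(len(library), dtype=np.int64)
    if overlapping:
        for seg in segments:
            seg = tuple(seg)
            n = len(seg)
            for w in lengths:
                for i in range(n - w + 1):
                    col = index.get(seg[i : i + w])
                    if col is not None:
                        counts[col] += 1
    else:
        for col, motif in enumerate(library.motifs):
            counts[col] = count_occurrences(segments, motif, overlapping=False)
    return counts


def _z_with_infinity_rule(x, means, sds, n_shuffles):
    const = infinity_constant(n_shuffles)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - means) / sds
    degenerate = sds == 0
    z = np.where(degenerate & (x > means), const, z)
    z = np.where(degenerate & (x < means), -const, z)
    z = np.where(degenerate & (x == means), 0.0, z)
    return z, degenerate & (x != means)


def enrichment_score(real_count, shuffled_counts, ddof: int = 1) -> float:
    """Eq.-style Z of a real count against its paired shuffle counts.

    The SD is the sample SD of the shuffled counts (``ddof=1``); a zero SD
    yields ±sqrt(1 + n_shuffles), or 0 when the real count equals the
    shuffle mean.
    """
    s = np.asarray(shuffled_counts, dtype=float)
    z, _ = _z_with_infinity_rule(
        float(real_count), s.mean(), s.std(ddof=ddof), len(s)
    )
    return float(z)


def shuffle_self_scores(shuffled_counts, ddof: int = 1) -> np.ndarray:
    """Leave-one-out Z of each shuffle against the remaining shuffles."""
    s = np.asarray(shuffled_counts, dtype=float)
    k = len(s)
    out = np.empty(k)
    for j in range(k):
        others = np.delete(s, j)
        z, _ = _z_with_infinity_rule(s[j], others.mean(), others.std(ddof=ddof), k - 1)
        out[j] = z
    return out


def build_enrichment_matrix(
    real_counts: pd.DataFrame, shuffled_counts: dict, ddof: int = 1
) -> tuple[pd.DataFrame, float]:
    """Score matrix of samples (animal × window) by motifs.

    ``real_counts`` is a samples × motifs count table; ``shuffled_counts``
    maps each row key to an (n_shuffles × motifs) count array.  Returns the
    Z-score matrix and the fraction of scores hit by the infinity rule.
    """
    z_rows = []
    n_inf = 0
    n_tot = 0
    for key, x in real_counts.iterrows():
        s = np.asarray(shuffled_counts[key], dtype=float)
        z, inf_mask = _z_with_infinity_rule(
            x.to_numpy(dtype=float), s.mean(axis=0), s.std(axis=0, ddof=ddof), s.shape[0]
        )
        z_rows.append(z)
        n_inf += int(inf_mask.sum())
        n_tot += z.size
    zmat = pd.DataFrame(z_rows, index=real_counts.index, columns=real_counts.columns)
    return zmat, (n_inf / n_tot if n_tot else 0.0)


def normalize_columns(m, ddof: int = 0):
    """Column-wise z-normalization (population SD).

    Zero-SD columns are set to 0 and flagged.  Returns (normalized, flags).
    """
    values = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to normalize columns")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    flags = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (values - mean) / sd
    out[:, flags] = 0.0
    if isinstance(m, pd.DataFrame):
        out = pd.DataFrame(out, index=m.index, columns=m.columns)
        flags = pd.Series(flags, index=m.columns)
    return out, flags
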