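"""Bout segmentation of Δ-pixel traces.

An *active bout* is a maximal run of frames with Δ pixels > 0 and an
*inactive bout* a maximal run of zeros, so consecutive bouts strictly
alternate and together partition the recording.  Active bouts carry six
features — length (s), mean, SD, total, minimum and maximum Δ pixels —
while inactive bouts are described by their length alone.

Processing order expected by the pipeline: artifact ceiling, masks, then
segmentation.  Bouts touched by a ceiling artifact or a mask are flagged
rather than dropped, so downstream stages can decide what to exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import ActivityRecording

__all__ = [
    "Bout",
    "apply_artifact_ceiling",
    "apply_masks",
    "segment_bouts",
    "active_features",
    "bout_table",
    "ACTIVE_FEATURES",
]

#: Feature order of the active-bout feature vector.
ACTIVE_FEATURES = ("length_s", "mean", "sd", "total", "min", "max")

DEFAULT_CEILING = 200  # Δ pixels; plate-artifact threshold


@dataclass
class Bout:
    """A maximal run of frames of one kind.

    ``flags`` may contain ``at_edge`` (leading/trailing bout, true extent
    censored), ``artifact`` (overlaps a ceiling-zeroed run) and ``masked``
    (overlaps an excluded interval).
    """

    kind: str  # "active" | "inactive"
    start_frame: int
    length_frames: int
    values: np.ndarray | None = None  # frame values, active bouts only
    flags: frozenset = field(default_factory=frozenset)

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.length_frames

    @property
    def excluded(self) -> bool:
        return bool(self.flags & {"masked"})


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and lengths of maximal True runs in a boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate([[0], starts])
    if m[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return starts, ends - starts


def apply_artifact_ceiling(
    rec: ActivityRecording, ceiling: int = DEFAULT_CEILING
) -> tuple[ActivityRecording, pd.DataFrame]:
    """Zero every active run containing any frame above ``ceiling``.

    A single out-of-range frame invalidates its whole active run (tracking
    artifacts such as reflections produce implausible spikes), so the full
    run is set to zero.  Returns the cleaned recording and a report of the
    zeroed runs; the recording remembers them in ``artifact_runs`` so that
    segmentation can flag the inactive bouts they merge into.
    """
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    values = rec.values
    if values.size and values.min() < 0:
        raise ValueError("Δ-pixel values must be non-negative")
    starts, lengths = _runs(values > 0)
    zeroed = []
    out = values.copy()
    for s, n in zip(starts, lengths):
        run = values[s : s + n]
        if run.max() > ceiling:
            out[s : s + n] = 0
            zeroed.append((int(s), int(n), int(run.max())))
    report = pd.DataFrame(zeroed, columns=["start_frame", "length_frames", "max_value"])
    new = rec.with_values(out)
    new.artifact_runs = list(rec.artifact_runs) + [(s, n) for s, n, _ in zeroed]
    return new, report


def apply_masks(rec: ActivityRecording) -> ActivityRecording:
    """Zero masked frames (e.g. water changes) and keep the intervals noted.

    Masked frames become zeros, merging into the surrounding inactive
    structure; :func:`segment_bouts` flags every bout overlapping a mask as
    ``masked`` so later analysis can exclude it.
    """
    if not rec.masks:
        return rec
    out = rec.values.copy()
    for a, b in rec.masks:
        out[a:b] = 0
    return rec.with_values(out)


def _overlaps(start: int, end: int, intervals) -> bool:
    return any(a < end and start < b for a, b in intervals)


def segment_bouts(rec: ActivityRecording) -> list[Bout]:
    """Segment a recording into an alternating list of bouts.

    Assumes the artifact ceiling and masks have already been applied
    (non-zero frames inside a mask are a contract violation).  The returned
    bouts partition ``[0, n_frames)``.
    """
    values = rec.values
    if values.size == 0:
        return []
    for a, b in rec.masks:
        if np.any(values[a:b] != 0):
            raise ValueError("masked frames contain non-zero values; call apply_masks first")
    active = values > 0
    # Boundaries wherever the active state changes.
    change = np.flatnonzero(np.diff(active.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [values.size]])
    masked_intervals = rec.masks
    artifact_intervals = [(s, s + n) for s, n in rec.artifact_runs]
    bouts = []
    for s, e in zip(starts, ends):
        kind = "active" if active[s] else "inactive"
        flags = set()
        if s == 0 or e == values.size:
            flags.add("at_edge")
        if _overlaps(s, e, masked_intervals):
            flags.add("masked")
        if kind == "inactive" and _overlaps(s, e, artifact_intervals):
            flags.add("artifact")
        bouts.append(
            Bout(
                kind=kind,
                start_frame=int(s),
                length_frames=int(e - s),
                values=values[s:e] if kind == "active" else None,
                flags=frozenset(flags),
            )
        )
    return bouts


def active_features(bout: Bout, frame_rate: float) -> np.ndarray:
    """Six-feature vector of an active bout (see :data:`ACTIVE_FEATURES`).

    SD is the population SD (``ddof=0``) so single-frame bouts have SD 0
    and every bout is featurizable.
    """
    if bout.kind != "active":
        raise ValueError("active_features requires an active bout")
    v = np.asarray(bout.values, dtype=float)
    return np.array(
        [
            bout.length_frames / frame_rate,
            v.mean(),
            v.std(ddof=0),
            v.sum(),
            v.min(),
            v.max(),
        ]
    )


def bout_table(rec: ActivityRecording) -> pd.DataFrame:
    """Vectorized bout table for one recording.

    Columns: ``animal_id, kind, start_frame, length_frames, length_s, mean,
    sd, total, min, max, window, flags``.  Feature columns are NaN for
    inactive bouts; ``flags`` is a comma-joined string (empty when none).
    """
    values = rec.values.astype(np.float64)
    n = values.size
    if n == 0:
        return pd.DataFrame(
            columns=[
                "animal_id", "kind", "start_frame", "length_frames", "length_s",
                "mean", "sd", "total", "min", "max", "window", "flags",
            ]
        )
    active = values > 0
    change = np.flatnonzero(np.diff(active.astype(np.int8))) + 1
    starts = np.concatenate([[0], change]).astype(np.int64)
    ends = np.concatenate([change, [n]]).astype(np.int64)
    lengths = ends - starts
    kinds = np.where(active[starts], "active", "inactive")

    # Active-bout features via segment reductions.
    totals = np.add.reduceat(values, starts)
    sumsq = np.add.reduceat(values**2, starts)
    means = totals / lengths
    var = np.maximum(sumsq / lengths - means**2, 0.0)
    mins = np.minimum.reduceat(values, starts)
    maxs = np.maximum.reduceat(values, starts)

    is_active = kinds == "active"
    df = pd.DataFrame(
        {
            "animal_id": rec.animal_id,
            "kind": kinds,
            "start_frame": starts,
            "length_frames": lengths,
            "length_s": lengths / rec.frame_rate,
            "mean": np.where(is_active, means, np.nan),
            "sd": np.where(is_active, np.sqrt(var), np.nan),
            "total": np.where(is_active, totals, np.nan),
            "min": np.where(is_active, mins, np.nan),
            "max": np.where(is_active, maxs, np.nan),
            "window": rec.window_labels(starts),
        }
    )

    flags = [set() for _ in range(len(starts))]
    flags[0].add("at_edge")
    flags[-1].add("at_edge")
    for intervals, tag, inactive_only in (
        (rec.masks, "masked", False),
        ([(s, s + ln) for s, ln in rec.artifact_runs], "artifact", True),
    ):
        for a, b in intervals:
            hit = np.flatnonzero((starts < b) & (ends > a))
            for i in hit:
                if not inactive_only or kinds[i] == "inactive":
                    flags[i].add(tag)
    df["flags"] = [",".join(sorted(f)) for f in flags]
    return df
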