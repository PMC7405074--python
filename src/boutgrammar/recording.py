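"""Activity recordings: one animal's Δ-pixel trace plus its light schedule.

A Δ-pixel trace is a per-frame count of the pixels that changed intensity in
one well, recorded at a fixed frame rate (25 Hz in the standard setup).
Frames are 0-based and every interval is half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "ActivityRecording",
    "read_activity_csv",
    "write_activity_csv",
    "subdivide_windows",
]


@dataclass(frozen=True)
class Window:
    """A labeled half-open frame interval ``[start, end)``."""

    label: str
    start: int
    end: int

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class ActivityRecording:
    """One animal's Δ-pixel frame series.

    Parameters
    ----------
    animal_id:
        Token identifying the animal (CSV column name).
    values:
        Non-negative integer Δ-pixel counts, one per frame.
    frame_rate:
        Frames per second.
    schedule:
        Ordered windows that tile ``[0, n_frames)`` without overlap, e.g.
        alternating day/night lighting periods.
    masks:
        Excluded intervals (e.g. water changes); merged if overlapping.
    artifact_runs:
        ``(start, length)`` of active runs zeroed by the artifact ceiling.
        Populated by :func:`boutgrammar.bouts.apply_artifact_ceiling`.
    group:
        Optional experimental group / genotype / dose label.
    """

    animal_id: str
    values: np.ndarray
    frame_rate: float = 25.0
    schedule: list[Window] = field(default_factory=list)
    masks: list[tuple[int, int]] = field(default_factory=list)
    artifact_runs: list[tuple[int, int]] = field(default_factory=list)
    group: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.floor(self.values)):
                raise ValueError("Δ-pixel values must be integers")
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise ValueError("Δ-pixel values must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.schedule:
            self.schedule = [Window("all", 0, self.n_frames)]
        self._validate_schedule()
        self.masks = _merge_masks(self.masks, self.n_frames)

    def _validate_schedule(self) -> None:
        pos = 0
        for w in self.schedule:
            if w.start != pos or w.end < w.start:
                raise ValueError("schedule windows must tile the recording without overlap")
            pos = w.end
        if pos != self.n_frames:
            raise ValueError(
                f"schedule covers [0, {pos}) but the recording has {self.n_frames} frames"
            )

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def window_labels(self, frames: np.ndarray) -> np.ndarray:
        """Schedule label of each 0-based frame index."""
        starts = np.array([w.start for w in self.schedule])
        idx = np.searchsorted(starts, np.asarray(frames), side="right") - 1
        labels = np.array([w.label for w in self.schedule], dtype=object)
        return labels[np.clip(idx, 0, len(labels) - 1)]

    def with_values(self, values: np.ndarray, **updates) -> "ActivityRecording":
        return replace(self, values=values, **updates)


def _merge_masks(masks, n_frames: int) -> list[tuple[int, int]]:
    if not masks:
        return []
    masks = sorted((int(a), int(b)) for a, b in masks)
    for a, b in masks:
        if a < 0 or b > n_frames or b < a:
            raise ValueError(f"mask ({a}, {b}) lies outside the recording")
    merged = [masks[0]]
    overlapped = False
    for a, b in masks[1:]:
        pa, pb = merged[-1]
        if a <= pb:
            overlapped = True
            merged[-1] = (pa, max(pb, b))
        else:
            merged.append((a, b))
    if overlapped:
        warnings.warn("overlapping masks were merged", stacklevel=3)
    return merged


def subdivide_windows(
    schedule: list[Window], span_frames: int, min_frames: int = 1
) -> list[Window]:
    """Split schedule windows into consecutive sub-windows of ``span_frames``.

    Used for the hourly analysis: a 14 h day window at 25 Hz splits into
    14 one-hour windows labeled ``day.00`` ... ``day.13``.  A trailing
    remainder shorter than ``min_frames`` is folded into the last sub-window.
    """
    out: list[Window] = []
    for w in schedule:
        edges = list(range(w.start, w.end, span_frames)) + [w.end]
        if len(edges) > 2 and edges[-1] - edges[-2] < min_frames:
            del edges[-2]
        for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
            out.append(Window(f"{w.label}.{i:02d}", a, b))
    return out


# ---------------------------------------------------------------------------
# CSV ingestion: frames × animals table + long-format metadata table.
# ---------------------------------------------------------------------------

def write_activity_csv(recordings, values_path, metadata_path) -> None:
    """Write recordings as a frames × animals CSV plus a metadata CSV.

    The metadata table is long-format with columns
    ``animal_id, field, label, start_frame, end_frame`` where ``field`` is
    ``group`` (frame columns empty), ``window`` or ``mask``.  Recordings may
    differ in length; shorter traces are zero-padded and the padding recorded
    as a mask so it is excluded downstream.
    """
    n_max = max(r.n_frames for r in recordings)
    table = {}
    meta_rows = []
    for rec in recordings:
        v = rec.values
        masks = list(rec.masks)
        schedule = list(rec.schedule)
        if rec.n_frames < n_max:
            v = np.concatenate([v, np.zeros(n_max - rec.n_frames, dtype=v.dtype)])
            masks.append((rec.n_frames, n_max))
            last = schedule[-1]
            schedule[-1] = Window(last.label, last.start, n_max)
        table[rec.animal_id] = v
        meta_rows.append((rec.animal_id, "group", rec.group, "", ""))
        meta_rows.append((rec.animal_id, "frame_rate", repr(rec.frame_rate), "", ""))
        for w in schedule:
            meta_rows.append((rec.animal_id, "window", w.label, w.start, w.end))
        for a, b in masks:
            meta_rows.append((rec.animal_id, "mask", "", a, b))
    pd.DataFrame(table).to_csv(values_path, index=False)
    pd.DataFrame(
        meta_rows, columns=["animal_id", "field", "label", "start_frame", "end_frame"]
    ).to_csv(metadata_path, index=False)


def read_activity_csv(values_path, metadata_path, default_frame_rate: float = 25.0):
    """Read recordings written by :func:`write_activity_csv`.

    Returns a list of :class:`ActivityRecording`, one per column of the
    frames × animals table.
    """
    values = pd.read_csv(values_path, comment="#")
    meta = pd.read_csv(
        metadata_path, comment="#", dtype={"animal_id": str}, keep_default_na=False
    )
    recordings = []
    for animal_id in values.columns:
        sub = meta[meta["animal_id"] == str(animal_id)]
        group = ""
        frame_rate = default_frame_rate
        schedule: list[Window] = []
        masks: list[tuple[int, int]] = []
        for row in sub.itertuples(index=False):
            if row.field == "group":
                group = row.label
            elif row.field == "frame_rate":
                frame_rate = float(row.label)
            elif row.field == "window":
                schedule.append(Window(row.label, int(row.start_frame), int(row.end_frame)))
            elif row.field == "mask":
                masks.append((int(row.start_frame), int(row.end_frame)))
        recordings.append(
            ActivityRecording(
                animal_id=str(animal_id),
                values=values[animal_id].to_numpy(),
                frame_rate=frame_rate,
                schedule=schedule,
                masks=masks,
                group=group,
            )
        )
    return recordings
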