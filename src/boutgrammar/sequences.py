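"""Module sequences: an animal's behavior as alternating behavioral modules.

After clustering, each bout is replaced by its module symbol — ``A<k>`` for
active modules and ``I<k>`` for inactive ones, with ids 1..K ordered by
ascending mean bout length — giving a strictly alternating symbolic
sequence anchored to frames.  Bouts flagged masked are kept in place but
marked ``excluded``; downstream motif operations treat them as gaps that
candidate motifs may not span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModuleSequence", "module_kind", "sequence_from_table"]


def module_kind(token: str) -> str:
    """'active' or 'inactive' from a module token such as ``A2`` / ``I5``."""
    if token.startswith("A"):
        return "active"
    if token.startswith("I"):
        return "inactive"
    raise ValueError(f"not a module token: {token!r}")


@dataclass
class ModuleSequence:
    """Alternating active/inactive module symbols with frame anchors."""

    animal_id: str
    tokens: list[str]
    starts: np.ndarray  # frame anchor per symbol, strictly increasing
    lengths: np.ndarray  # frames per symbol
    windows: list[str]  # schedule window label per symbol
    excluded: np.ndarray | None = None  # bool per symbol

    def __post_init__(self):
        self.tokens = list(self.tokens)
        n = len(self.tokens)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.windows = list(self.windows)
        if self.excluded is None:
            self.excluded = np.zeros(n, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not (len(self.starts) == len(self.lengths) == len(self.windows) == n
                == len(self.excluded)):
            raise ValueError("field lengths disagree")
        if n:
            if np.any(np.diff(self.starts) <= 0):
                raise ValueError("frame anchors must be strictly increasing")
            kinds = [t[0] for t in self.tokens]
            pairs = set(zip(kinds[:-1], kinds[1:]))
            if ("A", "A") in pairs or ("I", "I") in pairs:
                raise ValueError("module kinds must strictly alternate")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def kinds(self) -> np.ndarray:
        return np.array(["active" if t[0] == "A" else "inactive" for t in self.tokens])

    def segments(self) -> list[list[str]]:
        """Kept tokens split into contiguous runs at excluded-module gaps.

        Motif candidates and occurrence counts never span these gaps.
        """
        return self._split(np.arange(len(self.tokens)))

    def _split(self, idx: np.ndarray) -> list[list[str]]:
        segs: list[list[str]] = []
        cur: list[str] = []
        prev = None
        for i in idx:
            if self.excluded[i]:
                if cur:
                    segs.append(cur)
                    cur = []
                prev = None
                continue
            if prev is not None and i != prev + 1 and cur:
                segs.append(cur)
                cur = []
            cur.append(self.tokens[i])
            prev = i
        if cur:
            segs.append(cur)
        return segs

    def window_segments(self, sample_windows=None) -> dict[str, list[list[str]]]:
        """Kept tokens grouped by window, each as gap-split segments.

        With ``sample_windows`` (a list of :class:`~boutgrammar.recording.Window`,
        e.g. hourly subdivisions) modules are re-binned by start frame;
        otherwise the sequence's own per-module window labels are used.
        Ordered dict: insertion order follows the sequence.
        """
        n = len(self.tokens)
        if sample_windows is not None:
            starts = np.array([w.start for w in sample_windows])
            idx = np.searchsorted(starts, self.starts, side="right") - 1
            idx = np.clip(idx, 0, len(sample_windows) - 1)
            labels = [sample_windows[i].label for i in idx]
        else:
            labels = self.windows
        out: dict[str, list[list[str]]] = {}
        order: dict[str, list[int]] = {}
        for i in range(n):
            order.setdefault(labels[i], []).append(i)
        for label, idxs in order.items():
            out[label] = self._split(np.asarray(idxs))
        return out

    def total_frames(self) -> int:
        return int((self.starts[-1] + self.lengths[-1]) if len(self) else 0)


def sequence_from_table(modules: pd.DataFrame, animal_id: str) -> ModuleSequence:
    """Build a :class:`ModuleSequence` from a per-bout module table.

    Expects columns ``animal_id, module, start_frame, length_frames, window,
    flags`` with one row per bout in frame order (the module table written by
    the clustering stage).
    """
    sub = modules[modules["animal_id"] == animal_id].sort_values("start_frame")
    flags = sub["flags"].fillna("") if "flags" in sub else pd.Series("", index=sub.index)
    return ModuleSequence(
        animal_id=animal_id,
        tokens=list(sub["module"]),
        starts=sub["start_frame"].to_numpy(),
        lengths=sub["length_frames"].to_numpy(),
        windows=list(sub["window"]),
        excluded=flags.str.contains("masked").to_numpy(),
    )
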