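"""Ground-truthed synthetic Δ-pixel recordings.

The generator emulates the statistical structure the downstream method
assumes: an alternating sequence of active and inactive behavioral modules
whose usage probabilities differ between schedule windows (day/night), each
module rendering as a run of positive integer Δ-pixel values (active) or
zeros (inactive), with recurrent module motifs planted at known positions.

Every stage of the pipeline can therefore be tested against known truth:
bout segmentation against the planted run-length structure, clustering
against the planted module labels, compression and enrichment against the
planted motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._rng import as_rng, child_rng
from .recording import ActivityRecording, Window
from .sequences import ModuleSequence

__all__ = [
    "Dist",
    "ModuleTemplate",
    "PlantedMotif",
    "SimulationSpec",
    "GroundTruth",
    "generate_module_sequence",
    "render_deltapixels",
    "simulate_dataset",
]


@dataclass(frozen=True)
class Dist:
    """A small family of positive-integer distributions.

    kinds
    -----
    ``constant(value)``; ``uniform_int(low, high)`` inclusive;
    ``normal_int(mean, sd)`` rounded then clipped at ``minimum``;
    ``lognormal10_int(log10_mean, log10_sd)`` — ``round(10**N(m, s))``
    clipped at ``minimum``, natural for inactive-bout lengths that span
    orders of magnitude.
    """

    kind: str
    params: tuple
    minimum: int = 1

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            out = np.full(size, self.params[0], dtype=np.int64)
        elif self.kind == "uniform_int":
            lo, hi = self.params
            out = rng.integers(lo, hi + 1, size=size)
        elif self.kind == "normal_int":
            mean, sd = self.params
            out = np.rint(rng.normal(mean, sd, size=size)).astype(np.int64)
        elif self.kind == "lognormal10_int":
            m, s = self.params
            out = np.rint(10.0 ** rng.normal(m, s, size=size)).astype(np.int64)
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        return np.maximum(out, self.minimum)

    @property
    def min_value(self) -> int:
        if self.kind == "constant":
            return int(self.params[0])
        if self.kind == "uniform_int":
            return max(int(self.params[0]), self.minimum)
        return self.minimum

    @property
    def mean_value(self) -> float:
        if self.kind == "constant":
            return float(self.params[0])
        if self.kind == "uniform_int":
            return (self.params[0] + self.params[1]) / 2
        if self.kind == "normal_int":
            return float(self.params[0])
        m, s = self.params
        return 10.0**m * math.exp(0.5 * (s * math.log(10)) ** 2)

    def to_dict(self):
        return {"kind": self.kind, "params": list(self.params), "minimum": self.minimum}

    @classmethod
    def from_dict(cls, d):
        return cls(d["kind"], tuple(d["params"]), int(d.get("minimum", 1)))


@dataclass(frozen=True)
class ModuleTemplate:
    """Length distribution (frames) and, for active modules, per-frame amplitude."""

    length: Dist
    amplitude: Dist | None = None  # None for inactive modules

    def to_dict(self):
        d = {"length": self.length.to_dict()}
        if self.amplitude is not None:
            d["amplitude"] = self.amplitude.to_dict()
        return d

    @classmethod
    def from_dict(cls, d):
        amp = d.get("amplitude")
        return cls(Dist.from_dict(d["length"]), Dist.from_dict(amp) if amp else None)


@dataclass(frozen=True)
class PlantedMotif:
    """A module motif planted at a per-module rate in selected windows."""

    tokens: tuple[str, ...]
    rates: dict = field(default_factory=dict)  # window label -> insertions per module

    def __post_init__(self):
        kinds = [t[0] for t in self.tokens]
        if any(k not in "AI" for k in kinds):
            raise ValueError(f"bad motif token in {self.tokens}")
        if any(a == b for a, b in zip(kinds[:-1], kinds[1:])):
            raise ValueError(f"planted motif must alternate active/inactive: {self.tokens}")

    def to_dict(self):
        return {"tokens": list(self.tokens), "rates": dict(self.rates)}

    @classmethod
    def from_dict(cls, d):
        return cls(tuple(d["tokens"]), dict(d["rates"]))


@dataclass
class SimulationSpec:
    """Full description of a synthetic experiment.

    ``module_probs`` maps each window label to categorical probabilities over
    the active and over the inactive modules (each summing to 1).  All
    randomness flows from ``seed``: the same spec and seed give identical
    output.
    """

    frame_rate: float
    schedule: list[Window]
    active_templates: list[ModuleTemplate]
    inactive_templates: list[ModuleTemplate]
    module_probs: dict  # label -> {"active": [...], "inactive": [...]}
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.active_templates or not self.inactive_templates:
            raise ValueError("need at least one active and one inactive template")
        for t in self.active_templates:
            if t.amplitude is None:
                raise ValueError("active templates need an amplitude distribution")
            if t.amplitude.min_value < 1:
                raise ValueError("an active template could emit 0 Δ pixels inside a run")
            if t.length.min_value < 1:
                raise ValueError("template lengths must be >= 1 frame")
        for t in self.inactive_templates:
            if t.length.min_value < 1:
                raise ValueError("template lengths must be >= 1 frame")
        for w in self.schedule:
            probs = self.module_probs.get(w.label)
            if probs is None:
                raise ValueError(f"no module probabilities for window {w.label!r}")
            for kind, n in (("active", len(self.active_templates)),
                            ("inactive", len(self.inactive_templates))):
                p = np.asarray(probs[kind], dtype=float)
                if len(p) != n or abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
                    raise ValueError(
                        f"{kind} probabilities for window {w.label!r} must be "
                        f"length {n} and sum to 1"
                    )
        for m in self.planted_motifs:
            for tok in m.tokens:
                k = int(tok[1:])
                n = len(self.active_templates if tok[0] == "A" else self.inactive_templates)
                if not 1 <= k <= n:
                    raise ValueError(f"motif token {tok} has no template")

    def template(self, token: str) -> ModuleTemplate:
        pool = self.active_templates if token[0] == "A" else self.inactive_templates
        return pool[int(token[1:]) - 1]

    # -- plain hierarchical config ------------------------------------------
    def to_dict(self):
        return {
            "frame_rate": self.frame_rate,
            "schedule": [[w.label, w.start, w.end] for w in self.schedule],
            "active_templates": [t.to_dict() for t in self.active_templates],
            "inactive_templates": [t.to_dict() for t in self.inactive_templates],
            "module_probs": {
                lbl: {k: list(map(float, v)) for k, v in d.items()}
                for lbl, d in self.module_probs.items()
            },
            "planted_motifs": [m.to_dict() for m in self.planted_motifs],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            frame_rate=float(d["frame_rate"]),
            schedule=[Window(l, int(a), int(b)) for l, a, b in d["schedule"]],
            active_templates=[ModuleTemplate.from_dict(t) for t in d["active_templates"]],
            inactive_templates=[ModuleTemplate.from_dict(t) for t in d["inactive_templates"]],
            module_probs=d["module_probs"],
            planted_motifs=[PlantedMotif.from_dict(m) for m in d.get("planted_motifs", [])],
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls, seed: int = 0) -> "SimulationSpec":
        """The package's standard study conditions.

        A 14 h day / 10 h night cycle at 25 Hz with five active and five
        inactive modules.  Active modules grade from short weak movements to
        long strong ones (amplitudes within the plausible 3–165 Δ-pixel
        range); inactive modules are log-spaced from ~0.1 s to ~1 min.  Day
        behavior favors short modules; night behavior favors long ones and
        never uses the shortest active or inactive module, giving the
        familiar diurnal activity pattern and roughly 20,000 modules per
        animal per cycle.  Two motifs built from rare modules (plus the
        day-exclusive shortest modules, which silence them at night) are
        planted in the day only, each at ~2 occurrences per day hour.
        """
        day = 14 * 3600 * 25
        night = 10 * 3600 * 25
        active = [
            ModuleTemplate(Dist("normal_int", (3, 1), 2), Dist("normal_int", (5, 1), 1)),
            ModuleTemplate(Dist("normal_int", (8, 2), 2), Dist("normal_int", (15, 2), 1)),
            ModuleTemplate(Dist("normal_int", (15, 3), 2), Dist("normal_int", (35, 3), 1)),
            ModuleTemplate(Dist("normal_int", (30, 5), 2), Dist("normal_int", (70, 5), 1)),
            ModuleTemplate(Dist("normal_int", (60, 8), 2), Dist("normal_int", (130, 8), 1)),
        ]
        inactive = [
            ModuleTemplate(Dist("lognormal10_int", (0.35, 0.12))),
            ModuleTemplate(Dist("lognormal10_int", (1.05, 0.12))),
            ModuleTemplate(Dist("lognormal10_int", (1.75, 0.12))),
            ModuleTemplate(Dist("lognormal10_int", (2.45, 0.12))),
            ModuleTemplate(Dist("lognormal10_int", (3.15, 0.12))),
        ]
        return cls(
            frame_rate=25.0,
            schedule=[Window("day", 0, day), Window("night", day, day + night)],
            active_templates=active,
            inactive_templates=inactive,
            module_probs={
                "day": {
                    "active": [0.20, 0.35, 0.25, 0.15, 0.05],
                    "inactive": [0.25, 0.35, 0.25, 0.10, 0.05],
                },
                "night": {
                    "active": [0.0, 0.20, 0.20, 0.30, 0.30],
                    "inactive": [0.0, 0.10, 0.20, 0.30, 0.40],
                },
            },
            planted_motifs=[
                PlantedMotif(("A5", "I5", "A1", "I4", "A5", "I1"), {"day": 0.0014}),
                PlantedMotif(("A4", "I5", "A1", "I5", "A5", "I1"), {"day": 0.0014}),
            ],
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Planted truth for one simulated animal."""

    tokens: list[str]  # true module token per bout (after planting)
    windows: list[str]  # window label per bout
    motif_occurrences: list[tuple[int, int]]  # (motif index, start position)


def _draw_ids(rng, cum_probs, size):
    return np.searchsorted(cum_probs, rng.random(size), side="right")


def _draw_lengths(rng, templates, ids):
    out = np.empty(len(ids), dtype=np.int64)
    for k, t in enumerate(templates):
        sel = np.flatnonzero(ids == k)
        if sel.size:
            out[sel] = t.length.sample(rng, sel.size)
    return out


def generate_module_sequence(
    spec: SimulationSpec, n_modules: int, rng=None, animal_id: str = "sim"
) -> tuple[ModuleSequence, GroundTruth]:
    """Sample a strictly alternating module sequence of ``n_modules`` symbols.

    Modules are drawn from the window containing their start frame (the last
    window's probabilities extend past the end of the schedule if the module
    budget outlasts it), then planted motifs are spliced in by overwriting
    kind-compatible module runs at uniformly chosen non-overlapping
    positions, at each motif's per-module rate for each window.
    """
    if n_modules < 2:
        raise ValueError("n_modules must be >= 2")
    rng = as_rng(rng if rng is not None else spec.seed)
    cum = {
        lbl: {k: np.cumsum(p[k]) for k in ("active", "inactive")}
        for lbl, p in spec.module_probs.items()
    }

    tokens: list[str] = []
    lengths: list[int] = []
    win_labels: list[str] = []
    frame = 0
    w_idx = 0
    kind_active = True  # sequences start with an active module
    while len(tokens) < n_modules:
        while w_idx < len(spec.schedule) - 1 and frame >= spec.schedule[w_idx].end:
            w_idx += 1
        w = spec.schedule[w_idx]
        label = w.label
        # Draw a chunk of alternating modules for this window.
        mean_len = _mean_module_frames(spec, label)
        remaining_frames = max(w.end - frame, 1)
        est = int(remaining_frames / mean_len) + 8 if w_idx < len(spec.schedule) - 1 else n_modules
        chunk = int(min(max(est, 16), n_modules - len(tokens)))
        n_act = (chunk + (1 if kind_active else 0)) // 2
        n_ina = chunk - n_act
        a_ids = _draw_ids(rng, cum[label]["active"], n_act)
        i_ids = _draw_ids(rng, cum[label]["inactive"], n_ina)
        a_len = _draw_lengths(rng, spec.active_templates, a_ids)
        i_len = _draw_lengths(rng, spec.inactive_templates, i_ids)
        ids = np.empty(chunk, dtype=np.int64)
        lens = np.empty(chunk, dtype=np.int64)
        a_slots = slice(0, None, 2) if kind_active else slice(1, None, 2)
        i_slots = slice(1, None, 2) if kind_active else slice(0, None, 2)
        ids[a_slots], lens[a_slots] = a_ids, a_len
        ids[i_slots], lens[i_slots] = i_ids, i_len
        starts_rel = frame + np.concatenate([[0], np.cumsum(lens[:-1])])
        if w_idx < len(spec.schedule) - 1:
            take = int(np.searchsorted(starts_rel, w.end, side="left"))
            take = max(take, 1) if starts_rel[0] < w.end else 0
        else:
            take = chunk
        for j in range(take):
            act = kind_active if j % 2 == 0 else not kind_active
            tokens.append(("A" if act else "I") + str(ids[j] + 1))
            lengths.append(int(lens[j]))
            win_labels.append(label)
        if take:
            kind_active = (kind_active if take % 2 == 0 else not kind_active)
            frame = int(starts_rel[take - 1] + lens[take - 1])

    tokens = tokens[:n_modules]
    lengths = lengths[:n_modules]
    win_labels = win_labels[:n_modules]

    occurrences = _plant_motifs(spec, tokens, lengths, win_labels, rng)

    lengths_arr = np.asarray(lengths, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths_arr[:-1])])
    seq = ModuleSequence(
        animal_id=animal_id,
        tokens=tokens,
        starts=starts,
        lengths=lengths_arr,
        windows=win_labels,
    )
    truth = GroundTruth(tokens=list(tokens), windows=list(win_labels),
                        motif_occurrences=occurrences)
    return seq, truth


def _mean_module_frames(spec: SimulationSpec, label: str) -> float:
    p = spec.module_probs[label]
    ma = sum(pr * t.length.mean_value for pr, t in zip(p["active"], spec.active_templates))
    mi = sum(pr * t.length.mean_value for pr, t in zip(p["inactive"], spec.inactive_templates))
    return (ma + mi) / 2


def _plant_motifs(spec, tokens, lengths, win_labels, rng) -> list[tuple[int, int]]:
    n = len(tokens)
    used = np.zeros(n, dtype=bool)
    occurrences: list[tuple[int, int]] = []
    win_arr = np.asarray(win_labels, dtype=object)
    kind_active = np.array([t[0] == "A" for t in tokens])
    for m_idx, motif in enumerate(spec.planted_motifs):
        L = len(motif.tokens)
        want_active = motif.tokens[0][0] == "A"
        for label, rate in motif.rates.items():
            if rate <= 0:
                continue
            in_window = win_arr == label
            n_window = int(in_window.sum())
            n_target = int(round(rate * n_window))
            if n_target == 0 or L > n:
                continue
            # Starts whose whole extent lies in the window with matching kinds.
            ok = in_window.copy()
            for off in range(1, L):
                ok[:-off] &= in_window[off:]
                ok[-off:] = False
            cand = np.flatnonzero(ok & (kind_active == want_active))
            cand = cand[rng.permutation(cand.size)]
            planted = 0
            for pos in cand:
                if planted >= n_target:
                    break
                if used[pos : pos + L].any():
                    continue
                for off, tok in enumerate(motif.tokens):
                    tokens[pos + off] = tok
                    lengths[pos + off] = int(spec.template(tok).length.sample(rng, 1)[0])
                used[pos : pos + L] = True
                occurrences.append((m_idx, int(pos)))
                planted += 1
    occurrences.sort(key=lambda t: t[1])
    return occurrences


def render_deltapixels(
    seq: ModuleSequence, spec: SimulationSpec, rng=None, group: str = ""
) -> ActivityRecording:
    """Render a module sequence to an integer Δ-pixel trace.

    Active modules render as runs of per-frame draws from their amplitude
    distribution (all > 0); inactive modules as runs of zeros.  The
    recording's schedule is rebuilt from the sequence's per-module window
    labels so that window boundaries land exactly on module boundaries.
    """
    spec.validate()
    rng = as_rng(rng if rng is not None else spec.seed)
    total = seq.total_frames()
    values = np.zeros(total, dtype=np.int64)
    # Group the active frames by module id so amplitudes are drawn in bulk.
    by_template: dict[str, list[int]] = {}
    for i, tok in enumerate(seq.tokens):
        if tok[0] == "A":
            by_template.setdefault(tok, []).append(i)
    for tok, idxs in sorted(by_template.items()):
        amp = spec.template(tok).amplitude
        n_frames = int(seq.lengths[idxs].sum())
        draws = amp.sample(rng, n_frames)
        ptr = 0
        for i in idxs:
            ln = int(seq.lengths[i])
            s = int(seq.starts[i])
            values[s : s + ln] = draws[ptr : ptr + ln]
            ptr += ln
    schedule = []
    if len(seq):
        cur_label, cur_start = seq.windows[0], 0
        for i in range(1, len(seq)):
            if seq.windows[i] != cur_label:
                schedule.append(Window(cur_label, cur_start, int(seq.starts[i])))
                cur_label, cur_start = seq.windows[i], int(seq.starts[i])
        schedule.append(Window(cur_label, cur_start, total))
    return ActivityRecording(
        animal_id=seq.animal_id,
        values=values,
        frame_rate=spec.frame_rate,
        schedule=schedule,
        group=group,
    )


def simulate_dataset(
    spec: SimulationSpec,
    n_animals: int,
    n_modules: int,
    animal_ids: list[str] | None = None,
    group: str = "",
):
    """Simulate a cohort; returns (recordings, sequences, truths).

    Each animal gets an independent generator derived from ``spec.seed`` and
    its index, so results are identical however the animals are iterated.
    """
    if animal_ids is None:
        animal_ids = [f"fish{i + 1:02d}" for i in range(n_animals)]
    recs, seqs, truths = [], [], []
    for i, aid in enumerate(animal_ids[:n_animals]):
        rng = child_rng(spec.seed, "animal", i)
        seq, truth = generate_module_sequence(spec, n_modules, rng=rng, animal_id=aid)
        rec = render_deltapixels(seq, spec, rng=rng, group=group)
        recs.append(rec)
        seqs.append(seq)
        truths.append(truth)
    return recs, seqs, truths
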