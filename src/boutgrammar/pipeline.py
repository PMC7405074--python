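"""End-to-end orchestration: simulate → segment → cluster → compress →
enrich → classify, with file artifacts between stages.

Each stage reads its predecessor's CSV artifacts from the run directory and
writes its own, so stages can be re-run individually.  Every artifact
carries a ``# config=<hash>`` comment line for provenance, and a
``manifest.json`` records the config hash, seed, package version and
per-stage row counts.  Per-animal work is distributed with a process-level
parallel map; every animal draws from its own generator derived from the
master seed and the animal index, so parallel and serial runs are
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from ._rng import child_rng
from .bouts import apply_artifact_ceiling, apply_masks, bout_table
from .classification import classifier_report
from .clustering import ClusterParams, cluster_bouts
from .compression import MotifLibrary, block_compressibility, build_library, compress
from .enrichment import (
    build_enrichment_matrix,
    count_library,
    normalize_columns,
    shuffle_within_windows,
)
from .recording import read_activity_csv, subdivide_windows, write_activity_csv
from .sequences import sequence_from_table
from .synthetic import SimulationSpec, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("boutgrammar")

STAGES = ("simulate", "segment", "cluster", "compress", "enrich", "classify")


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of a pipeline run; ``seed`` is mandatory."""

    seed: int
    out: str = "run"
    frame_rate: float = 25.0
    ceiling: int = 200
    n_jobs: int = 1
    simulate: dict = dataclasses.field(
        default_factory=lambda: {"n_animals": 4, "n_modules": 4000, "spec": None}
    )
    cluster: dict = dataclasses.field(
        default_factory=lambda: {
            "n_probe": 2000, "n_models": 50, "k_range": [2, 10],
            "sample_range": [2000, 4000], "k_nn": 50, "n_init": 5,
            "reg_covar": 0.01, "n_components": "auto",
        }
    )
    compress: dict = dataclasses.field(
        default_factory=lambda: {"max_len": 10, "block": 500}
    )
    enrich: dict = dataclasses.field(
        default_factory=lambda: {"n_shuffles": 10, "window_span_s": 3600.0}
    )
    classify: dict = dataclasses.field(
        default_factory=lambda: {
            "top": 250, "folds": 10, "smooth_width": 3, "repeats": 10,
            "contrast": "window", "exclude": [],
        }
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "seed" not in d:
            raise ValueError("config must set a seed")
        base = cls(seed=int(d["seed"]))
        for key, value in d.items():
            if not hasattr(base, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(base, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(base, key, value)
        return base

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def hash(self) -> str:
        """Hash of the scientific configuration (paths and parallelism,
        which cannot change results, are excluded)."""
        d = self.to_dict()
        d.pop("out", None)
        d.pop("n_jobs", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={cfg.hash}\n")
        df.to_csv(fh, index=index)


def _need(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}; run the '{producer}' stage first"
        )
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> int:
    opts = cfg.simulate
    spec_path = opts.get("spec")
    spec = SimulationSpec.from_yaml(spec_path) if spec_path else SimulationSpec.default()
    spec.seed = cfg.seed
    recs, seqs, truths = simulate_dataset(spec, opts["n_animals"], opts["n_modules"])
    write_activity_csv(recs, out / "deltapixels.csv", out / "metadata.csv")
    truth_rows = []
    for seq, truth in zip(seqs, truths):
        for m_idx, pos in truth.motif_occurrences:
            truth_rows.append((seq.animal_id, m_idx, pos))
    _write_csv(
        pd.DataFrame(truth_rows, columns=["animal_id", "motif", "position"]),
        out / "ground_truth_motifs.csv", cfg,
    )
    truth_tokens = pd.DataFrame(
        [
            (s.animal_id, i, t, w)
            for s, tr in zip(seqs, truths)
            for i, (t, w) in enumerate(zip(tr.tokens, tr.windows))
        ],
        columns=["animal_id", "position", "module", "window"],
    )
    _write_csv(truth_tokens, out / "ground_truth_modules.csv", cfg)
    return len(recs)


def _segment_one(rec, ceiling):
    rec, _ = apply_artifact_ceiling(rec, ceiling)
    rec = apply_masks(rec)
    return bout_table(rec)


def stage_segment(cfg: PipelineConfig, out: Path) -> int:
    recs = read_activity_csv(
        _need(out / "deltapixels.csv", "segment", "simulate"),
        _need(out / "metadata.csv", "segment", "simulate"),
        default_frame_rate=cfg.frame_rate,
    )
    tables = Parallel(n_jobs=cfg.n_jobs)(
        delayed(_segment_one)(rec, cfg.ceiling) for rec in recs
    )
    bouts = pd.concat(tables, ignore_index=True)
    _write_csv(bouts, out / "bouts.csv", cfg)
    return len(bouts)


def stage_cluster(cfg: PipelineConfig, out: Path) -> int:
    bouts = pd.read_csv(_need(out / "bouts.csv", "cluster", "segment"), comment="#",
                        dtype={"animal_id": str}, keep_default_na=False,
                        na_values=[""])
    opts = dict(cfg.cluster)
    params = ClusterParams(
        n_probe=opts["n_probe"], n_models=opts["n_models"],
        k_range=tuple(opts["k_range"]), sample_range=tuple(opts["sample_range"]),
        k_nn=opts["k_nn"], n_init=opts["n_init"], reg_covar=opts["reg_covar"],
        n_components=opts["n_components"],
    )
    seed = child_rng(cfg.seed, "cluster")
    modules, summary = cluster_bouts(bouts, params, seed=seed)
    _write_csv(modules, out / "modules.csv", cfg)
    _write_csv(summary, out / "module_summary.csv", cfg)
    return len(modules)


def _load_sequences(cfg: PipelineConfig, out: Path, stage: str):
    modules = pd.read_csv(_need(out / "modules.csv", stage, "cluster"), comment="#",
                          dtype={"animal_id": str}, keep_default_na=False,
                          na_values=[""])
    animals = list(pd.unique(modules["animal_id"]))
    return [sequence_from_table(modules, a) for a in animals]


def _compress_one(seq, max_len, block):
    g = compress(seq, max_len=max_len)
    blocks = block_compressibility(seq, block=block, max_len=max_len) if block else []
    return g, blocks


def stage_compress(cfg: PipelineConfig, out: Path) -> int:
    seqs = _load_sequences(cfg, out, "compress")
    opts = cfg.compress
    results = Parallel(n_jobs=cfg.n_jobs)(
        delayed(_compress_one)(s, opts["max_len"], opts.get("block")) for s in seqs
    )
    grammars = [g for g, _ in results]
    library = build_library(grammars)
    library.to_file(out / "motif_library.tsv")
    rule_rows = []
    for seq, g in zip(seqs, grammars):
        for r in g.rules:
            rule_rows.append(
                (seq.animal_id, r.lhs, " ".join(r.rhs), " ".join(g.expand(r.lhs)),
                 r.savings, r.count)
            )
    _write_csv(
        pd.DataFrame(rule_rows, columns=["animal_id", "rule", "definition",
                                         "terminal", "savings", "occurrences"]),
        out / "grammars.csv", cfg,
    )
    block_rows = []
    for seq, (_, blocks) in zip(seqs, results):
        for b, value in enumerate(blocks):
            block_rows.append((seq.animal_id, b, value))
    _write_csv(
        pd.DataFrame(block_rows, columns=["animal_id", "block", "compressibility"]),
        out / "blocks.csv", cfg,
    )
    return len(library)


def _enrich_one(seq, windows, library, n_shuffles, seed):
    rng = child_rng(seed, "enrich", seq.animal_id)
    by_window = seq.window_segments(windows)
    shuffles = shuffle_within_windows(seq, n_shuffles, rng=rng, sample_windows=windows)
    real_rows = {}
    shuf_rows = {}
    for label, segs in by_window.items():
        key = (seq.animal_id, label)
        real_rows[key] = count_library(segs, library)
        shuf_rows[key] = np.stack(
            [count_library(s.window_segments(windows).get(label, []), library)
             for s in shuffles]
        )
    return real_rows, shuf_rows


def stage_enrich(cfg: PipelineConfig, out: Path) -> int:
    seqs = _load_sequences(cfg, out, "enrich")
    library = MotifLibrary.from_file(_need(out / "motif_library.tsv", "enrich", "compress"))
    opts = cfg.enrich
    span = opts.get("window_span_s")
    results = Parallel(n_jobs=cfg.n_jobs)(
        delayed(_enrich_one)(
            seq,
            _sample_windows(seq, span, cfg.frame_rate),
            library,
            opts["n_shuffles"],
            cfg.seed,
        )
        for seq in seqs
    )
    real = {}
    shuf = {}
    for r, s in results:
        real.update(r)
        shuf.update(s)
    keys = sorted(real)
    real_df = pd.DataFrame(
        [real[k] for k in keys],
        index=pd.MultiIndex.from_tuples(keys, names=["animal_id", "window"]),
        columns=[f"m{i}" for i in range(len(library))],
    )
    zmat, frac_inf = build_enrichment_matrix(real_df, shuf)
    log.info("infinite scores replaced: %.2f%%", 100 * frac_inf)
    _write_csv(zmat.reset_index(), out / "enrichment.csv", cfg)
    motif_ids = pd.DataFrame(
        {"motif_id": [f"m{i}" for i in range(len(library))],
         "definition": [" ".join(m) for m in library.motifs]}
    )
    _write_csv(motif_ids, out / "motif_ids.csv", cfg)
    return zmat.shape[0]


def _sample_windows(seq, span_s, frame_rate):
    from .recording import Window

    if span_s is None:
        return None
    span = int(round(span_s * frame_rate))
    windows = []
    cur_label, cur_start = None, 0
    for i, lbl in enumerate(seq.windows):
        if lbl != cur_label:
            if cur_label is not None:
                windows.append(Window(cur_label, cur_start, int(seq.starts[i])))
            cur_label, cur_start = lbl, int(seq.starts[i])
    windows.append(Window(cur_label, cur_start, seq.total_frames()))
    return subdivide_windows(windows, span, min_frames=span // 2)


def stage_classify(cfg: PipelineConfig, out: Path) -> int:
    z = pd.read_csv(_need(out / "enrichment.csv", "classify", "enrich"), comment="#",
                    dtype={"animal_id": str})
    opts = cfg.classify
    rows = z.set_index(["animal_id", "window"])
    if opts["contrast"] == "window":
        labels = np.array([w.split(".")[0] for _, w in rows.index])
    elif opts["contrast"] == "group":
        meta = pd.read_csv(out / "metadata.csv", comment="#", dtype={"animal_id": str},
                           keep_default_na=False)
        groups_map = dict(
            meta[meta["field"] == "group"][["animal_id", "label"]].itertuples(index=False)
        )
        labels = np.array([groups_map.get(a, "") for a, _ in rows.index])
    else:
        raise ValueError(f"unknown contrast {opts['contrast']!r}")
    keep = ~np.isin(labels, list(opts.get("exclude") or []))
    rows, labels = rows[keep], labels[keep]
    animals = np.array([a for a, _ in rows.index])
    normalized, _ = normalize_columns(rows)
    report = classifier_report(
        normalized, labels,
        comparison=opts["contrast"],
        top=opts["top"], folds=opts["folds"], smooth_width=opts["smooth_width"],
        repeats=opts["repeats"],
        seed=int(child_rng(cfg.seed, "classify").integers(2**31)),
        groups=animals,
    )
    frame = report.to_frame()
    frame["best_motif"] = rows.columns[report.ranked[0]]
    _write_csv(frame, out / "report.csv", cfg)
    ranked_ids = rows.columns[report.ranked]
    _write_csv(
        pd.DataFrame({"rank": np.arange(1, len(ranked_ids) + 1), "motif_id": ranked_ids}),
        out / "ranking.csv", cfg,
    )
    return len(frame)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "cluster": stage_cluster,
    "compress": stage_compress,
    "enrich": stage_enrich,
    "classify": stage_classify,
}


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; returns the run manifest."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    stages = [s for s in STAGES if s in stages]
    manifest_path = out / "manifest.json"
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash,
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    if manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh)
        if previous.get("config_hash") == cfg.hash:
            manifest["stages"] = previous.get("stages", {})
    for stage in stages:
        t0 = time.perf_counter()
        rows = _STAGE_FUNCS[stage](cfg, out)
        dt = time.perf_counter() - t0
        log.info("stage %-9s %6d rows in %.1fs", stage, rows, dt)
        manifest["stages"][stage] = {"rows": int(rows), "seconds": round(dt, 2)}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest
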