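"""Evidence-accumulation clustering of bouts into behavioral modules.

Active bouts are clustered in a PCA-reduced space of their six z-scored
features; inactive bouts on (dithered) log10 length.  An ensemble of
Gaussian mixture models — each fit to a random subsample with a random
component count — votes on pairwise co-assignment of a fixed set of probe
points; average-link clustering of the resulting co-assignment matrix is
cut at the maximum cluster lifetime to pick the module count.  Clusters
are then equalized in size by subsampling, every bout is assigned by the
mode of its 50 nearest template points, and modules are relabeled 1..K by
ascending mean bout length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import KNeighborsClassifier

from ._rng import as_rng
from .bouts import ACTIVE_FEATURES

__all__ = [
    "zscore_per_animal",
    "center_and_project",
    "scree_knee",
    "EvidenceMatrix",
    "accumulate_evidence",
    "cut_max_lifetime",
    "normalize_and_assign",
    "relabel_by_length",
    "ClusterParams",
    "cluster_bouts",
]


def zscore_per_animal(x: np.ndarray, animals, ddof: int = 0) -> np.ndarray:
    """Z-score each feature within each animal (population SD).

    Removes per-animal location and scale so that animals with different
    baseline activity contribute comparably.  Raises a descriptive error if
    an animal has zero SD in a feature or fewer than 2 bouts.
    """
    x = np.asarray(x, dtype=float)
    animals = np.asarray(animals)
    out = np.empty_like(x)
    for animal in pd.unique(animals):
        sel = animals == animal
        if sel.sum() < 2:
            raise ValueError(f"animal {animal!r} has fewer than 2 bouts")
        block = x[sel]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=ddof)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [ACTIVE_FEATURES[i] if i < len(ACTIVE_FEATURES) else str(i)
                     for i in zero]
            raise ValueError(
                f"animal {animal!r} has zero SD in feature(s) {', '.join(names)}"
            )
        out[sel] = (block - mu) / sd
    return out


def scree_knee(fractions: np.ndarray) -> int:
    """Knee of a scree curve: keep components up to the largest successive drop.

    A reproducible stand-in for the visual knee judgment: with explained
    variance fractions f1 >= f2 >= ..., returns the k maximizing
    f_k - f_{k+1}.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) < 2:
        return len(fractions)
    drops = fractions[:-1] - fractions[1:]
    return int(np.argmax(drops)) + 1


def center_and_project(x: np.ndarray, n_components="auto"):
    """Center features and project onto principal axes.

    ``n_components='auto'`` keeps the scree knee; ``'all'`` keeps every
    component.  Returns (scores, explained variance fractions, k).
    """
    x = np.asarray(x, dtype=float)
    n_feat = x.shape[1]
    pca = PCA(n_components=n_feat, svd_solver="full")
    scores = pca.fit_transform(x)  # PCA centers internally
    fractions = pca.explained_variance_ratio_
    if n_components == "auto":
        k = scree_knee(fractions)
    elif n_components == "all":
        k = n_feat
    else:
        k = int(n_components)
        if k > n_feat:
            raise ValueError(f"n_components={k} exceeds the {n_feat} features")
    return scores[:, :k], fractions, k


@dataclass
class EvidenceMatrix:
    """Pairwise co-assignment tallies over an ensemble of mixture models."""

    probe_indices: np.ndarray  # row indices into the point matrix
    counts: np.ndarray  # symmetric, diagonal == n_models
    n_models: int

    def validate(self) -> None:
        c = self.counts
        if not np.array_equal(c, c.T):
            raise ValueError("evidence matrix must be symmetric")
        if np.any(np.diag(c) != self.n_models):
            raise ValueError("evidence diagonal must equal n_models")
        if c.min() < 0 or c.max() > self.n_models:
            raise ValueError("evidence entries must lie in [0, n_models]")


def accumulate_evidence(
    points: np.ndarray,
    n_probe: int = 40_000,
    n_models: int = 200,
    k_range: tuple[int, int] = (2, 20),
    sample_range: tuple[int, int] = (40_000, 100_000),
    seed=None,
    n_init: int = 5,
    reg_covar: float = 1e-6,
) -> EvidenceMatrix:
    """Accumulate co-assignment evidence from an ensemble of GMMs.

    A fixed probe set of ``n_probe`` points is sampled once; then for each
    of ``n_models`` iterations a training set of uniformly random size in
    ``sample_range`` is drawn and fit with a full-covariance Gaussian
    mixture with a uniformly random component count in ``k_range``
    (k-means++ initialization, best of ``n_init`` restarts by
    log-likelihood).  Every probe point is assigned to its maximum-posterior
    component and co-assignment tallies are accumulated.

    Defaults mirror a large-scale study (tens of millions of bouts); pass
    smaller values, scaled to the data, for desk-scale work.
    """
    rng = as_rng(seed)
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n_points = points.shape[0]
    if n_probe > n_points:
        raise ValueError(f"n_probe={n_probe} exceeds the {n_points} available points")
    probe_idx = np.sort(rng.choice(n_points, size=n_probe, replace=False))
    probes = points[probe_idx]

    counts = np.zeros((n_probe, n_probe), dtype=np.uint32)
    lo_k, hi_k = k_range
    lo_s, hi_s = sample_range
    lo_s, hi_s = min(lo_s, n_points), min(hi_s, n_points)
    for _ in range(n_models):
        n_sample = int(rng.integers(lo_s, hi_s + 1))
        k = int(rng.integers(lo_k, hi_k + 1))
        train = points[rng.choice(n_points, size=n_sample, replace=False)]
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=reg_covar,
            n_init=n_init,
            init_params="k-means++",
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # occasional non-convergence is fine
            gmm.fit(train)
            labels = gmm.predict(probes)
        for c in range(k):
            idx = np.flatnonzero(labels == c)
            if idx.size:
                counts[np.ix_(idx, idx)] += 1
    ev = EvidenceMatrix(probe_indices=probe_idx, counts=counts, n_models=n_models)
    ev.validate()
    return ev


def cut_max_lifetime(ev: EvidenceMatrix) -> tuple[np.ndarray, int]:
    """Average-link clustering of the evidence matrix, cut at max lifetime.

    Dissimilarity is ``n_models - counts``.  The lifetime of a cluster
    count K is the merge-height gap over which exactly K clusters exist;
    the cut with the largest lifetime wins, ties broken toward larger K.
    Returns (labels 1..K per probe, K).
    """
    ev.validate()
    n = ev.counts.shape[0]
    if n == 1:
        return np.array([1]), 1
    d = (ev.n_models - ev.counts).astype(float)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    if np.allclose(heights, heights[0]):
        if heights[0] == 0:
            warnings.warn("degenerate all-equal evidence matrix; returning K=1")
            return np.ones(n, dtype=int), 1
        if n == 2:
            return np.array([1, 2]), 2
    # K = n - m clusters exist while the threshold sits between merge m-1
    # and merge m; the K with the widest such gap survives longest.
    gaps = np.diff(heights)  # gap for K = n-1 .. 2
    ks = n - 1 - np.arange(len(gaps))
    if len(gaps) == 0:
        k = 2 if heights[0] > 0 else 1
    else:
        best = np.flatnonzero(gaps == gaps.max())
        k = int(ks[best].max())
    labels = fcluster(z, t=k, criterion="maxclust")
    return labels, int(labels.max())


def normalize_and_assign(
    points: np.ndarray,
    probe_indices: np.ndarray,
    probe_labels: np.ndarray,
    k_nn: int = 50,
    seed=None,
) -> np.ndarray:
    """Size-normalize clusters and assign every point by k-NN mode vote.

    From each probe cluster, the size of the smallest cluster is sampled
    without replacement to form equal-sized template sets; every point
    (probe or not) is then assigned the mode cluster of its ``k_nn``
    nearest templates (Euclidean; ties go to the lowest module id).
    """
    rng = as_rng(seed)
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    probe_labels = np.asarray(probe_labels)
    cluster_ids = np.unique(probe_labels)
    sizes = {c: int((probe_labels == c).sum()) for c in cluster_ids}
    n_min = min(sizes.values())
    template_idx = []
    template_lab = []
    for c in cluster_ids:
        members = np.flatnonzero(probe_labels == c)
        chosen = rng.choice(members, size=n_min, replace=False)
        template_idx.extend(probe_indices[chosen])
        template_lab.extend([c] * n_min)
    template_idx = np.asarray(template_idx)
    template_lab = np.asarray(template_lab)
    if k_nn > len(template_idx):
        warnings.warn(
            f"k_nn={k_nn} exceeds the {len(template_idx)} template points; reducing"
        )
        k_nn = len(template_idx)
    knn = KNeighborsClassifier(n_neighbors=k_nn)
    knn.fit(points[template_idx], template_lab)
    return knn.predict(points)


def relabel_by_length(
    labels: np.ndarray, lengths: np.ndarray, totals: np.ndarray | None = None
) -> tuple[np.ndarray, dict[int, float]]:
    """Relabel modules 1..K by ascending mean bout length.

    Ties in mean length are broken by the smaller mean total Δ pixels (pass
    ``totals``), then by original id.  Idempotent.
    """
    labels = np.asarray(labels)
    lengths = np.asarray(lengths, dtype=float)
    stats = []
    for c in np.unique(labels):
        sel = labels == c
        mean_len = lengths[sel].mean()
        mean_tot = float(totals[sel].mean()) if totals is not None else 0.0
        stats.append((mean_len, mean_tot, c))
    stats.sort()
    mapping = {old: new + 1 for new, (_, _, old) in enumerate(stats)}
    new_labels = np.array([mapping[c] for c in labels])
    means = {mapping[c]: m for m, _, c in stats}
    return new_labels, means


@dataclass
class ClusterParams:
    """Ensemble-clustering parameters (see :func:`accumulate_evidence`)."""

    n_probe: int = 40_000
    n_models: int = 200
    k_range: tuple[int, int] = (2, 20)
    sample_range: tuple[int, int] = (40_000, 100_000)
    k_nn: int = 50
    n_init: int = 5
    reg_covar: float = 1e-6
    n_components: object = "auto"  # PCA components for the active space
    inactive_log10: bool = True
    dequantize: bool = True  # dither integer lengths before log10

    def scaled_to(self, n_points: int) -> "ClusterParams":
        """Shrink sampling sizes proportionally when data are smaller."""
        if n_points >= self.sample_range[1]:
            return self
        factor = n_points / self.sample_range[1]
        scale = lambda v: max(2, int(round(v * factor)))
        return ClusterParams(
            n_probe=min(scale(self.n_probe), n_points),
            n_models=self.n_models,
            k_range=self.k_range,
            sample_range=(scale(self.sample_range[0]), n_points),
            k_nn=self.k_nn,
            n_init=self.n_init,
            reg_covar=self.reg_covar,
            n_components=self.n_components,
            inactive_log10=self.inactive_log10,
            dequantize=self.dequantize,
        )


def prepare_inactive(lengths: np.ndarray, params: ClusterParams, rng) -> np.ndarray:
    """Inactive-bout clustering space: log10 of dithered integer lengths.

    Frame counts are integers, so identical short lengths form zero-variance
    spikes that degenerate mixture components latch onto; adding U(0,1)
    dequantization dither restores the underlying continuous length scale.
    """
    x = np.asarray(lengths, dtype=float)
    if params.dequantize:
        x = x + rng.random(x.size)
    if params.inactive_log10:
        x = np.log10(x)
    return x[:, None]


def cluster_bouts(
    bouts: pd.DataFrame, params: ClusterParams | None = None, seed=0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster a pooled bout table into active and inactive modules.

    ``bouts`` is the table from :func:`boutgrammar.bouts.bout_table`
    (possibly concatenated over animals).  Returns the table with a
    ``module`` column (``A1..`` / ``I1..``) plus a per-module summary.
    Bouts flagged masked are excluded from clustering and assignment
    templates but still receive a module label.
    """
    if params is None:
        params = ClusterParams()
    rng = as_rng(seed)
    bouts = bouts.reset_index(drop=True)
    flags = bouts.get("flags", pd.Series("", index=bouts.index)).fillna("")
    excluded = flags.str.contains("masked|artifact").to_numpy()
    modules = np.empty(len(bouts), dtype=object)
    summaries = []
    for kind, prefix in (("active", "A"), ("inactive", "I")):
        sel = bouts["kind"] == kind
        sub = bouts[sel]
        if kind == "active":
            feats = sub[list(ACTIVE_FEATURES)].to_numpy(dtype=float)
            z = zscore_per_animal(feats, sub["animal_id"].to_numpy())
            space, _, _ = center_and_project(z, params.n_components)
        else:
            space = prepare_inactive(
                sub["length_frames"].to_numpy(), params, np.random.default_rng(rng.integers(2**31))
            )
        # Flagged bouts are never probes or templates but still get a label.
        kept = np.flatnonzero(~excluded[sel.to_numpy()])
        p = params.scaled_to(kept.size)
        ev = accumulate_evidence(
            space[kept],
            n_probe=p.n_probe,
            n_models=p.n_models,
            k_range=p.k_range,
            sample_range=p.sample_range,
            seed=np.random.default_rng(rng.integers(2**31)),
            n_init=p.n_init,
            reg_covar=p.reg_covar,
        )
        probe_labels, _ = cut_max_lifetime(ev)
        raw = normalize_and_assign(
            space, kept[ev.probe_indices], probe_labels, k_nn=p.k_nn,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
        totals = sub["total"].to_numpy(dtype=float) if kind == "active" else None
        labels, mean_len = relabel_by_length(
            raw, sub["length_frames"].to_numpy(), totals
        )
        modules[np.flatnonzero(sel)] = [f"{prefix}{c}" for c in labels]
        for c, m in sorted(mean_len.items()):
            members = sub[labels == c]
            summaries.append(
                {
                    "module": f"{prefix}{c}",
                    "kind": kind,
                    "count": len(members),
                    "mean_length_frames": m,
                    "mean_length_s": members["length_s"].mean(),
                    "mean_total": members["total"].mean() if kind == "active" else np.nan,
                }
            )
    out = bouts.copy()
    out["module"] = modules
    return out, pd.DataFrame(summaries)
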