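"""Voxelwise within-network statistics on Fisher-z maps.

Condition (after vs before) and interaction (patient change vs control
change) contrasts of a 2 x 2 repeated-measures design, with nonparametric
cluster-level family-wise error correction: clusters are formed at a
two-tailed voxel threshold (default p = 0.005) under 26-connectivity and
their extents compared with a permutation null of the maximal cluster extent
(sign flipping for the condition effect, group-label permutation for the
interaction). Corrected p = (1 + #null >= observed) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "fisher_z",
    "condition_effect",
    "interaction_effect",
    "cluster_fwe",
    "Cluster",
    "ClusterResult",
]

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


def fisher_z(r):
    """Fisher's r-to-z transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t of per-subject differences, voxelwise; zero-variance -> 0."""
    n = diffs.shape[0]
    if n < 2:
        return np.zeros(diffs.shape[1:])
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def condition_effect(before: np.ndarray, after: np.ndarray) -> np.ndarray:
    """Voxelwise paired t of (after - before) across all subjects.

    ``before``/``after``: (n_subjects, *grid). Positive = increase after
    training. Zero-variance voxels get t = 0 (masked out).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after shapes must match (every subject has both sessions)")
    return _paired_t(after - before)


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t, x minus y, voxelwise; zero-variance -> 0."""
    nx, ny = x.shape[0], y.shape[0]
    mx, my = x.mean(axis=0), y.mean(axis=0)
    ssx = ((x - mx) ** 2).sum(axis=0)
    ssy = ((y - my) ** 2).sum(axis=0)
    pooled = (ssx + ssy) / (nx + ny - 2)
    se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mx - my) / se, 0.0)
    return t


def interaction_effect(
    before: np.ndarray, after: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Voxelwise two-sample t on per-subject (after - before), patients minus
    controls. ``groups`` is a boolean array (True = patient) over subjects."""
    groups = np.asarray(groups, dtype=bool)
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    diffs = np.asarray(after, dtype=float) - np.asarray(before, dtype=float)
    return _two_sample_t(diffs[groups], diffs[~groups])


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) integer coordinates
    peak: tuple[int, int, int]
    peak_stat: float
    extent: int
    corrected_p: float
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    null_max_extent: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def _max_extent(binary: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=CONNECTIVITY_26)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _sign_flip_t_maps(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for many sign-flip permutations at once.

    Sign flipping leaves each subject's squared values unchanged, so the sum of
    squares is constant across permutations and only the mean changes.
    """
    n = diffs_flat.shape[0]
    ss = (diffs_flat**2).sum(axis=0)  # (V,)
    means = signs @ diffs_flat / n  # (P, V)
    var = (ss[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    se = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, means / se, 0.0)
    return t


def cluster_fwe(
    diffs: np.ndarray,
    groups: np.ndarray | None = None,
    p_form: float = 0.005,
    p_fwe: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Permutation cluster-extent FWE correction of a t contrast.

    Parameters
    ----------
    diffs : ndarray (n_subjects, X, Y, Z)
        Per-subject (after - before) difference maps.
    groups : boolean array over subjects or None
        None -> condition effect (one-sample t of diffs, sign-flip null);
        array -> interaction effect (two-sample t patients minus controls,
        group-label permutation null).
    p_form : two-tailed cluster-forming voxel threshold (default 0.005).
    p_fwe : cluster-level familywise threshold (default 0.05).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 10:
        raise ValueError(
            f"only {n} permutable units; too few for a permutation null "
            "(< 10) — use exact enumeration"
        )
    grid = diffs.shape[1:]
    flat = diffs.reshape(n, -1)
    rng = np.random.default_rng(seed)

    if groups is None:
        df = n - 1
        observed = _paired_t(diffs)
    else:
        groups = np.asarray(groups, dtype=bool)
        df = n - 2
        observed = _two_sample_t(diffs[groups], diffs[~groups])
    thresh = float(stats.t.ppf(1 - p_form / 2, df))

    # null distribution of the maximal cluster extent
    null_max = np.empty(n_perm, dtype=int)
    if groups is None:
        chunk = 250
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            signs = rng.choice([-1.0, 1.0], size=(m, n))
            tmaps = _sign_flip_t_maps(flat, signs)
            for r in range(m):
                null_max[done + r] = _max_extent(
                    np.abs(tmaps[r].reshape(grid)) > thresh
                )
            done += m
    else:
        n_pat = int(groups.sum())
        for r in range(n_perm):
            perm = rng.permutation(n)
            g = np.zeros(n, dtype=bool)
            g[perm[:n_pat]] = True
            tmap = _two_sample_t(flat[g], flat[~g])
            null_max[r] = _max_extent(np.abs(tmap.reshape(grid)) > thresh)

    labels, n_clust = ndimage.label(np.abs(observed) > thresh, structure=CONNECTIVITY_26)
    clusters: list[Cluster] = []
    for c in range(1, n_clust + 1):
        vox = np.argwhere(labels == c)
        vals = observed[labels == c]
        peak_local = np.argmax(np.abs(vals))
        extent = vox.shape[0]
        p_corr = float((1 + (null_max >= extent).sum()) / (1 + n_perm))
        clusters.append(
            Cluster(
                voxels=vox,
                peak=tuple(int(v) for v in vox[peak_local]),
                peak_stat=float(vals[peak_local]),
                extent=extent,
                corrected_p=p_corr,
                significant=p_corr < p_fwe,
            )
        )
    clusters.sort(key=lambda c: -c.extent)
    return ClusterResult(clusters=clusters, threshold=thresh, null_max_extent=null_max)
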