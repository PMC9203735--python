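"""Group spatial ICA: MDL component-number estimation, temporal-concatenation
ICA with multi-restart stability selection, dual-regression back-reconstruction,
and template-based network labeling by goodness of fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA, FastICA

__all__ = [
    "estimate_ncomp_mdl",
    "GroupICA",
    "ICADecomposition",
    "NetworkAssignment",
    "fit_group_ica",
    "goodness_of_fit",
    "assign_networks",
]

logger = logging.getLogger(__name__)

EIGENVALUE_FLOOR = 1e-12


def estimate_ncomp_mdl(data: np.ndarray, q_max: int | None = None) -> int:
    """Number of signal components by the classical MDL eigenvalue criterion.

    ``data`` is observations x channels (for fMRI: voxels x timepoints). With
    m channels, T observations, and sorted sample-covariance eigenvalues
    l_1 >= ... >= l_m, the criterion for q components is

        MDL(q) = -T (m - q) ln( g_q / a_q ) + q (2m - q) ln(T) / 2

    where g_q and a_q are the geometric and arithmetic means of the smallest
    m - q eigenvalues. Returns the argmin over q in [0, m - 1]. Eigenvalues at
    or below zero are floored with a logged warning.
    """
    data = np.asarray(data, dtype=float)
    t, m = data.shape
    if t <= m:
        raise ValueError(f"need more observations ({t}) than channels ({m})")
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / (t - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    if np.any(eig <= 0):
        logger.warning("flooring %d non-positive eigenvalues", int((eig <= 0).sum()))
        eig = np.maximum(eig, EIGENVALUE_FLOOR)
    if q_max is None:
        q_max = m - 1
    q_max = min(q_max, m - 1)
    best_q, best_val = 0, np.inf
    log_eig = np.log(eig)
    for q in range(q_max + 1):
        tail = eig[q:]
        geo = np.mean(log_eig[q:])
        arith = np.log(np.mean(tail))
        ll = -t * (m - q) * (geo - arith)
        penalty = 0.5 * q * (2 * m - q) * np.log(t)
        val = ll + penalty
        if val < best_val:
            best_val, best_q = val, q
    return best_q


@dataclass
class ICADecomposition:
    """Group maps plus per subject-session back-reconstructed data."""

    n_components: int
    group_maps: np.ndarray  # (n_components, n_voxels), z-scored per row
    subject_timecourses: list[np.ndarray]  # each (T, n_components)
    subject_maps: list[np.ndarray]  # each (n_components, n_voxels)
    grid: tuple[int, ...] | None = None
    stability_: float = 0.0


class GroupICA(BaseEstimator):
    """Temporal-concatenation group spatial ICA with dual regression.

    Subject data are voxel-wise variance normalized, temporally concatenated,
    PCA-reduced to ``n_components`` and unmixed with FastICA. ``n_restarts``
    random initializations are run; the restart whose components are most
    reproducible across restarts (highest mean best-match |r| to every other
    restart) is kept. Subject time courses and maps come from dual regression.

    Attributes (after fit): ``components_`` (z-scored group spatial maps),
    ``decomposition_`` (full :class:`ICADecomposition`).
    """

    def __init__(self, n_components: int = 6, n_restarts: int = 5,
                 seed: int = 0, max_iter: int = 500, tol: float = 1e-4):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, images: list[np.ndarray]) -> "GroupICA":
        mats, grid = _flatten_images(images)
        # per-subject variance normalization: voxel means removed, one global
        # scale per subject (voxel-wise unit variance would inflate pure-noise
        # voxels to signal scale)
        normed = []
        for x in mats:
            centered = x - x.mean(axis=0)
            sd = centered.std()
            normed.append(centered / (sd if sd > 0 else 1.0))
        concat = np.concatenate(normed, axis=0)  # (sum_T, V)
        k = self.n_components
        if k > min(concat.shape):
            raise ValueError(f"n_components = {k} exceeds reduced dimension")
        pca = PCA(n_components=k, svd_solver="randomized",
                  random_state=self.seed)
        reduced = pca.fit_transform(concat)  # (sum_T, k)
        # spatial ICA: sources are spatial maps; samples are voxels
        y = pca.components_ * np.sqrt(pca.explained_variance_)[:, None]  # (k, V)
        runs = []
        rng = np.random.default_rng(self.seed)
        last_err: Exception | None = None
        for _ in range(self.n_restarts):
            rs = int(rng.integers(0, 2**31 - 1))
            ica = FastICA(n_components=k, whiten="unit-variance",
                          max_iter=self.max_iter, tol=self.tol, random_state=rs)
            try:
                maps = ica.fit_transform(y.T).T  # (k, V)
                runs.append(maps)
            except Exception as exc:  # pragma: no cover - convergence failure
                last_err = exc
        if not runs:
            raise RuntimeError(f"all ICA restarts failed: {last_err}")
        best_idx, best_score = 0, -np.inf
        if len(runs) > 1:
            for a in range(len(runs)):
                score = np.mean([
                    _match_score(runs[a], runs[b])
                    for b in range(len(runs)) if b != a
                ])
                if score > best_score:
                    best_idx, best_score = a, score
        maps = runs[best_idx]
        # z-score each map by its own mean/SD
        maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(
            axis=1, keepdims=True, ddof=0
        )
        tcs, smaps = [], []
        pinv_maps = np.linalg.pinv(maps)  # (V, k)
        for x in normed:
            tc = x @ pinv_maps  # (T, k) stage 1
            smap = np.linalg.pinv(tc) @ x  # (k, V) stage 2
            tcs.append(tc)
            smaps.append(smap)
        self.components_ = maps
        self.decomposition_ = ICADecomposition(
            n_components=k,
            group_maps=maps,
            subject_timecourses=tcs,
            subject_maps=smaps,
            grid=grid,
            stability_=float(best_score) if len(runs) > 1 else 1.0,
        )
        return self


def _flatten_images(images: list[np.ndarray]):
    """Accept 4D (X,Y,Z,T) or 2D (T,V) per subject-session; return T x V mats."""
    mats = []
    grid = None
    for img in images:
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 4:
            g = arr.shape[:3]
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(f"grid mismatch: {g} vs {grid}")
            mats.append(arr.reshape(-1, arr.shape[3]).T)  # (T, V)
        elif arr.ndim == 2:
            mats.append(arr)
        else:
            raise ValueError("images must be 4D (X,Y,Z,T) or 2D (T,V)")
    v = mats[0].shape[1]
    if any(m.shape[1] != v for m in mats):
        raise ValueError("all subjects must share the voxel grid")
    return mats, grid


def _match_score(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over rows of a of the best absolute correlation with any row of b."""
    corr = np.abs(_cross_corr(a, b))
    return float(corr.max(axis=1).mean())


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return az @ bz.T


def fit_group_ica(
    images: list[np.ndarray],
    n_components: int,
    n_restarts: int = 5,
    seed: int = 0,
) -> ICADecomposition:
    """Functional wrapper over :class:`GroupICA`; see its docstring."""
    est = GroupICA(n_components=n_components, n_restarts=n_restarts, seed=seed)
    est.fit(images)
    return est.decomposition_


def goodness_of_fit(map_values: np.ndarray, template: np.ndarray) -> float:
    """Template goodness of fit: mean map value inside the binary template
    minus the mean outside."""
    m = np.asarray(map_values, dtype=float).ravel()
    t = np.asarray(template).ravel().astype(bool)
    if m.shape != t.shape:
        raise ValueError("map and template must share the grid")
    n_in = int(t.sum())
    if n_in == 0 or n_in == t.size:
        raise ValueError("template must be non-empty and not all-ones")
    return float(m[t].mean() - m[~t].mean())


@dataclass
class NetworkAssignment:
    """Component index per network label, with goodness-of-fit audit scores."""

    mapping: dict[str, int]
    scores: dict[str, float] = field(default_factory=dict)
    all_scores: np.ndarray | None = None  # (n_components, n_templates)


def assign_networks(
    dec: ICADecomposition | np.ndarray,
    templates: dict[str, np.ndarray],
) -> NetworkAssignment:
    """Greedy label assignment by descending goodness of fit.

    Each component is used at most once; ties break toward the lower component
    index. A best score <= 0 triggers a warning about a dubious assignment.
    """
    maps = dec.group_maps if isinstance(dec, ICADecomposition) else np.asarray(dec)
    maps2d = maps.reshape(maps.shape[0], -1)
    labels = list(templates.keys())
    if maps2d.shape[0] < len(labels):
        raise ValueError("need at least as many components as templates")
    score_mat = np.array([
        [goodness_of_fit(maps2d[c], templates[lab]) for lab in labels]
        for c in range(maps2d.shape[0])
    ])
    mapping: dict[str, int] = {}
    scores: dict[str, float] = {}
    used_c: set[int] = set()
    used_l: set[int] = set()
    # order all (component, label) pairs by descending score, component index tiebreak
    pairs = sorted(
        ((c, li) for c in range(score_mat.shape[0]) for li in range(len(labels))),
        key=lambda cl: (-score_mat[cl[0], cl[1]], cl[0], cl[1]),
    )
    for c, li in pairs:
        if c in used_c or li in used_l:
            continue
        mapping[labels[li]] = c
        scores[labels[li]] = float(score_mat[c, li])
        if score_mat[c, li] <= 0:
            logger.warning(
                "dubious assignment: best goodness-of-fit for %s is %.3f <= 0",
                labels[li], score_mat[c, li],
            )
        used_c.add(c)
        used_l.add(li)
        if len(used_l) == len(labels):
            break
    return NetworkAssignment(mapping=mapping, scores=scores, all_scores=score_mat)
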