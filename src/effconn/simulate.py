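"""Ground-truth study synthesis.

Generates two-group x two-session studies whose statistical structure matches
what the analysis assumes: per subject-session network time courses driven by
a stable VAR process with a known directed coefficient graph, optional
hemodynamic convolution and voxel rendering for the ICA stage, confound tables
with motion outliers, and clinical scores linearly coupled to the true causal
strength of one designated directed edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .containers import ConfoundTable, TimeSeriesMatrix
from .graphs import CausalGraph, default_six_network_graph

__all__ = [
    "simulate_var",
    "hrf_kernel",
    "convolve_hrf",
    "render_voxels",
    "blob_maps",
    "StudySpec",
    "SubjectSession",
    "SyntheticStudy",
    "generate_study",
    "true_edge_strength",
]

DEFAULT_BURN_IN = 500


def simulate_var(
    graph: CausalGraph,
    n_timepoints: int,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int | None = None,
    tr_seconds: float = 2.0,
) -> TimeSeriesMatrix:
    """Simulate a T x N series from x_t = sum_k A_k x_{t-k} + e_t.

    Innovations are zero-mean Gaussian, independent across nodes with the
    graph's per-node variances. The first ``burn_in`` samples are discarded to
    remove initial-condition transients. Deterministic given ``seed``.
    """
    graph.check_stable()
    p, n = graph.order, graph.n_nodes
    if n_timepoints <= 10 * p:
        raise ValueError(f"n_timepoints must exceed 10*order = {10 * p}")
    rng = np.random.default_rng(seed)
    total = n_timepoints + burn_in
    sd = np.sqrt(graph.noise_vars)
    e = rng.standard_normal((total, n)) * sd
    x = np.zeros((total + p, n))
    coeffs = graph.coeffs
    for t in range(total):
        acc = e[t].copy()
        for k in range(p):
            acc += coeffs[k] @ x[p + t - k - 1]
        x[p + t] = acc
    out = x[p + burn_in :]
    return TimeSeriesMatrix(out, tr_seconds, list(graph.node_names))


def hrf_kernel(tr_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at ``tr_seconds``.

    Peak at ~6 s, undershoot at ~16 s with 1/6 amplitude; peak-normalized.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be > 0")
    t = np.arange(0, duration_seconds + tr_seconds / 2, tr_seconds)
    peak = gamma_dist.pdf(t, 6.0)
    undershoot = gamma_dist.pdf(t, 16.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def convolve_hrf(ts: TimeSeriesMatrix, tr_seconds: float | None = None) -> TimeSeriesMatrix:
    """Convolve each channel with the canonical HRF; output length = input length."""
    tr = ts.sampling_interval if tr_seconds is None else tr_seconds
    h = hrf_kernel(tr)
    out = np.empty_like(ts.values)
    for j in range(ts.n_channels):
        out[:, j] = np.convolve(ts.values[:, j], h)[: ts.n_timepoints]
    return ts.copy_with(out)


def blob_maps(
    grid: tuple[int, int, int],
    centers: list[tuple[float, float, float]],
    radius: float = 2.5,
) -> np.ndarray:
    """Gaussian blob spatial maps, one per center, peak-normalized, on a grid.

    Returns ndarray (n_maps, *grid), non-negative.
    """
    xx, yy, zz = np.meshgrid(*(np.arange(s) for s in grid), indexing="ij")
    maps = []
    for cx, cy, cz in centers:
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        m = np.exp(-d2 / (2 * radius**2))
        maps.append(m / m.max())
    return np.stack(maps)


def render_voxels(
    maps: np.ndarray,
    ts: TimeSeriesMatrix,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render node time courses into a 4D voxel image (X, Y, Z, T).

    voxel series = sum over nodes of map_value * node series + Gaussian noise.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must have shape (n_maps, X, Y, Z)")
    if maps.shape[0] != ts.n_channels:
        raise ValueError(
            f"map count {maps.shape[0]} != channel count {ts.n_channels}"
        )
    if np.any(maps < 0):
        raise ValueError("maps must be non-negative")
    grid = maps.shape[1:]
    # (X,Y,Z,T) = sum_n maps[n,...,None] * ts[:,n]
    img = np.tensordot(maps, ts.values, axes=([0], [1]))  # (X, Y, Z, T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    assert img.shape == (*grid, ts.n_timepoints)
    return img


@dataclass
class ClinicalLink:
    """Linear coupling of a synthetic score to the designated edge's strength."""

    slope: float
    intercept: float
    noise_sd: float


def _default_links() -> dict[str, ClinicalLink]:
    # SF-36-like 0-100 subscales; slopes chosen so the planted GPDC range
    # (~0.1-0.35) spans a few tens of points.
    return {
        "RP": ClinicalLink(slope=150.0, intercept=20.0, noise_sd=10.0),
        "BP": ClinicalLink(slope=100.0, intercept=40.0, noise_sd=10.0),
    }


@dataclass
class StudySpec:
    """Design of a synthetic two-group x two-session study.

    The designated directed edge is multiplied by ``patient_edge_deficit`` in
    patients at baseline and by ``patient_edge_deficit * training_edge_gain``
    post-session; controls use the base graph in both sessions.
    """

    n_patients: int = 21
    n_controls: int = 19
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    base_graph: CausalGraph = field(default_factory=default_six_network_graph)
    designated_edge: tuple[str, str] = ("SMN", "DMN")
    patient_edge_deficit: float = 0.3
    training_edge_gain: float = 3.0
    clinical_links: dict[str, ClinicalLink] = field(default_factory=_default_links)
    subject_sd: float = 0.2  # SD of the per-subject lognormal factor on the edge
    outlier_fraction: float = 0.05
    n_noise_voxels: int = 30
    with_voxels: bool = False
    voxel_grid: tuple[int, int, int] = (12, 14, 12)
    voxel_noise_sd: float = 0.1
    apply_hrf: bool = False
    burn_in: int = DEFAULT_BURN_IN
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if self.patient_edge_deficit <= 0 or self.training_edge_gain <= 0:
            raise ValueError("edge deficit and gain must be in (0, inf)")
        src, tgt = self.designated_edge
        i, j = self.base_graph.edge_index(src, tgt)
        if np.all(self.base_graph.coeffs[:, i, j] == 0):
            raise ValueError(f"designated edge {src}->{tgt} absent from base_graph")


@dataclass
class SubjectSession:
    subject_id: str
    group: str  # "patient" | "control"
    session: str  # "before" | "after"
    timeseries: TimeSeriesMatrix
    confounds: ConfoundTable
    graph: CausalGraph
    voxels: np.ndarray | None = None
    scores: dict[str, float] = field(default_factory=dict)
    true_edge_strength: float = 0.0


@dataclass
class SyntheticStudy:
    spec: StudySpec
    sessions: list[SubjectSession]
    spatial_maps: np.ndarray | None = None

    def select(self, group: str | None = None, session: str | None = None):
        out = self.sessions
        if group is not None:
            out = [s for s in out if s.group == group]
        if session is not None:
            out = [s for s in out if s.session == session]
        return out

    @property
    def subject_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.sessions:
            if s.subject_id not in seen:
                seen.append(s.subject_id)
        return seen


def true_edge_strength(
    graph: CausalGraph,
    edge: tuple[str, str],
    tr_seconds: float = 2.0,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    n_freqs: int = 129,
) -> float:
    """Band-averaged GPDC of one directed edge computed from true coefficients."""
    from .gca import band_average, gpdc_from_coeffs

    spec = gpdc_from_coeffs(
        graph.coeffs, graph.noise_vars, tr_seconds, n_freqs=n_freqs,
        channel_names=graph.node_names,
    )
    edges = band_average(spec, low_hz, high_hz)
    i, j = graph.edge_index(*edge)
    return float(edges.values[i, j])


def _session_graph(spec: StudySpec, group: str, session: str) -> CausalGraph:
    src, tgt = spec.designated_edge
    if group == "control":
        return spec.base_graph
    factor = spec.patient_edge_deficit
    if session == "after":
        factor *= spec.training_edge_gain
    return spec.base_graph.with_edge_scaled(src, tgt, factor)


def _make_confounds(
    rng: np.random.Generator, n_frames: int, outlier_fraction: float, n_noise_voxels: int
) -> ConfoundTable:
    fd = np.abs(rng.normal(0.2, 0.08, size=n_frames))
    fd = np.minimum(fd, 0.45)
    dvars = np.abs(rng.normal(1.0, 0.15, size=n_frames))
    dvars = np.minimum(dvars, 1.45)
    n_out = int(round(outlier_fraction * n_frames))
    if n_out > 0:
        # motion outliers arrive as a contiguous burst (one movement event)
        start = int(rng.integers(0, n_frames - n_out + 1))
        idx = np.arange(start, start + n_out)
        fd[idx] = rng.uniform(0.6, 1.2, size=n_out)
        dvars[idx] = rng.uniform(1.6, 2.5, size=n_out)
    # noise compartment: shared low-frequency drift + sinusoid + white noise
    t = np.arange(n_frames)
    shared = 0.5 * np.sin(2 * np.pi * t / 40.0) + 0.3 * (t / n_frames - 0.5)
    weights = rng.uniform(0.5, 1.5, size=n_noise_voxels)
    noise = shared[:, None] * weights[None, :] + rng.normal(
        0.0, 0.3, size=(n_frames, n_noise_voxels)
    )
    return ConfoundTable(fd=fd, std_dvars=dvars, noise_series=noise)


def generate_study(spec: StudySpec) -> SyntheticStudy:
    """Generate a full synthetic study; fully reproducible from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    n_nodes = spec.base_graph.n_nodes
    maps = None
    if spec.with_voxels:
        gx, gy, gz = spec.voxel_grid
        rng_maps = np.random.default_rng(root.spawn(1)[0])
        centers = [
            (
                float(rng_maps.uniform(2, gx - 3)),
                float(rng_maps.uniform(2, gy - 3)),
                float(rng_maps.uniform(2, gz - 3)),
            )
            for _ in range(n_nodes)
        ]
        maps = blob_maps(spec.voxel_grid, centers)

    sessions: list[SubjectSession] = []
    groups = [("patient", spec.n_patients), ("control", spec.n_controls)]
    subj_counter = 0
    src, tgt = spec.designated_edge
    for group, count in groups:
        for _ in range(count):
            sid = f"sub-{subj_counter:03d}"
            subj_counter += 1
            # persistent per-subject factor on the designated edge: gives the
            # between-subject strength variation the clinical link rides on
            subj_rng = np.random.default_rng(root.spawn(1)[0])
            f_subj = float(np.exp(subj_rng.normal(0.0, spec.subject_sd)))
            for session in ("before", "after"):
                child = root.spawn(1)[0]
                rngs = [np.random.default_rng(s) for s in child.spawn(4)]
                g = _session_graph(spec, group, session)
                if f_subj != 1.0:
                    g = g.with_edge_scaled(src, tgt, f_subj)
                ts = simulate_var(
                    g,
                    spec.n_timepoints,
                    burn_in=spec.burn_in,
                    seed=rngs[0],
                    tr_seconds=spec.tr_seconds,
                )
                if spec.apply_hrf:
                    ts = convolve_hrf(ts)
                conf = _make_confounds(
                    rngs[1], spec.n_timepoints, spec.outlier_fraction, spec.n_noise_voxels
                )
                vox = None
                if spec.with_voxels:
                    vox = render_voxels(maps, ts, spec.voxel_noise_sd, seed=rngs[2])
                strength = true_edge_strength(g, spec.designated_edge, spec.tr_seconds)
                scores = {}
                for name, link in spec.clinical_links.items():
                    noise = link.noise_sd * rngs[3].standard_normal() if link.noise_sd > 0 else 0.0
                    scores[name] = link.intercept + link.slope * strength + noise
                sessions.append(
                    SubjectSession(
                        subject_id=sid,
                        group=group,
                        session=session,
                        timeseries=ts,
                        confounds=conf,
                        graph=g,
                        voxels=vox,
                        scores=scores,
                        true_edge_strength=strength,
                    )
                )
    return SyntheticStudy(spec=spec, sessions=sessions, spatial_maps=maps)
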