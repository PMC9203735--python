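"""Directed VAR coefficient graphs: the ground truth of every simulation.

A CausalGraph is a stable VAR(p) parameterization: ``coeffs[k][i][j]`` is the
influence of node ``j`` at lag ``k+1`` on node ``i`` (source column, target
row), plus per-node innovation variances. Stability is the spectral radius of
the companion matrix being < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical six resting-state network labels used throughout.
DEFAULT_NETWORKS = ["SMN", "ECN", "SN", "VN", "RFPN", "DMN"]


class StabilityError(ValueError):
    """Raised when a VAR coefficient set is non-stationary."""

    def __init__(self, spectral_radius: float):
        self.spectral_radius = spectral_radius
        super().__init__(
            f"VAR process is unstable: companion spectral radius "
            f"{spectral_radius:.4f} >= 1"
        )


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of a VAR(p): (N*p) x (N*p) block matrix."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


def spectral_radius(coeffs: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


@dataclass
class CausalGraph:
    """Stable VAR(p) generative structure.

    coeffs : ndarray (p, N, N); ``coeffs[k, i, j]`` = effect of node j at lag
        k+1 on node i (dimensionless).
    noise_vars : ndarray (N,) of innovation variances, strictly positive.
    node_names : optional labels; default ch0..chN-1.
    """

    coeffs: np.ndarray
    noise_vars: np.ndarray
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, N, N)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coeffs must be finite")
        self.noise_vars = np.asarray(self.noise_vars, dtype=float)
        if self.noise_vars.shape != (self.n_nodes,):
            raise ValueError("noise_vars must have shape (N,)")
        if np.any(self.noise_vars <= 0):
            raise ValueError("noise_vars must be strictly positive")
        if not self.node_names:
            self.node_names = [f"ch{i}" for i in range(self.n_nodes)]
        if len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length must equal n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.coeffs)

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    def check_stable(self) -> None:
        rho = self.spectral_radius
        if rho >= 1.0:
            raise StabilityError(rho)

    def edge_index(self, source: str, target: str) -> tuple[int, int]:
        """(row, col) index of the directed edge source -> target."""
        j = self.node_names.index(source)
        i = self.node_names.index(target)
        return i, j

    def with_edge_scaled(self, source: str, target: str, factor: float) -> "CausalGraph":
        """Copy of the graph with one directed edge multiplied across all lags."""
        i, j = self.edge_index(source, target)
        if np.all(self.coeffs[:, i, j] == 0):
            raise ValueError(f"edge {source}->{target} absent from graph")
        coeffs = self.coeffs.copy()
        coeffs[:, i, j] *= factor
        return CausalGraph(coeffs, self.noise_vars.copy(), list(self.node_names))

    def to_dict(self) -> dict:
        return {
            "coeffs": self.coeffs.tolist(),
            "noise_vars": self.noise_vars.tolist(),
            "node_names": list(self.node_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CausalGraph":
        return cls(np.array(d["coeffs"]), np.array(d["noise_vars"]), list(d["node_names"]))


def random_stable_graph(
    n_nodes: int,
    order: int,
    seed: int,
    density: float = 0.4,
    scale: float = 0.4,
    max_tries: int = 200,
) -> CausalGraph:
    """Draw a random sparse VAR graph and rescale until stable.

    Off-diagonal coefficients are Bernoulli(density) x N(0, scale^2); diagonals
    get a mild positive self-coupling. Coefficients are shrunk geometrically
    until the companion spectral radius drops below 0.95.
    """
    rng = np.random.default_rng(seed)
    coeffs = rng.normal(0.0, scale, size=(order, n_nodes, n_nodes))
    mask = rng.random((order, n_nodes, n_nodes)) < density
    coeffs *= mask
    for k in range(order):
        np.fill_diagonal(coeffs[k], rng.uniform(0.1, 0.4, size=n_nodes) / (k + 1))
    noise_vars = rng.uniform(0.5, 2.0, size=n_nodes)
    for _ in range(max_tries):
        if spectral_radius(coeffs) < 0.95:
            return CausalGraph(coeffs, noise_vars)
        coeffs = coeffs * 0.9
    raise RuntimeError("could not stabilize random graph")


def default_six_network_graph() -> CausalGraph:
    """Six-network VAR(1) ground truth mirroring a healthy resting pattern.

    Directed edges: SMN->DMN (the designated edge of the study design),
    SMN->RFPN, SMN->ECN, SN->DMN, SN->VN, RFPN->VN; self-couplings of 0.6
    concentrate spectral power at low frequencies (< ~0.1 Hz at TR = 2 s).
    """
    names = list(DEFAULT_NETWORKS)
    n = len(names)
    a = np.zeros((1, n, n))
    np.fill_diagonal(a[0], 0.6)
    idx = {nm: i for i, nm in enumerate(names)}

    def set_edge(src: str, tgt: str, w: float) -> None:
        a[0, idx[tgt], idx[src]] = w

    set_edge("SMN", "DMN", 0.35)
    set_edge("SMN", "RFPN", 0.30)
    set_edge("SMN", "ECN", 0.30)
    set_edge("SN", "DMN", 0.30)
    set_edge("SN", "VN", 0.30)
    set_edge("RFPN", "VN", 0.30)
    g = CausalGraph(a, np.ones(n), names)
    g.check_stable()
    return g
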