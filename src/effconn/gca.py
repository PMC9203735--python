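"""Multivariate Granger causality in the frequency domain.

The causal core of the pipeline: ordinary-least-squares MVAR estimation with
AIC lag-order selection, generalized partial directed coherence (GPDC)
spectra, band-averaged effective-connectivity edge matrices, and surrogate
(phase-randomization) edge detection.

Direction convention, used everywhere: ``values[i, j]`` is the influence of
channel j (source, column) on channel i (target, row).

For an estimated VAR(p) with lag matrices A_k and residual variances
sigma_i^2, the coefficient transfer matrix at normalized frequency f is

    Abar(f) = I - sum_k A_k exp(-i 2 pi f k)

and the GPDC magnitude from source j to target i is

    |pi_ij(f)| = (|Abar_ij(f)| / sigma_i) / sqrt(sum_k |Abar_kj(f)|^2 / sigma_k^2)

which column-normalizes: sum_i |pi_ij(f)|^2 = 1 for every source j and f.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .containers import CensorMask, TimeSeriesMatrix
from .graphs import spectral_radius

__all__ = [
    "MVAR",
    "VARModel",
    "GPDCSpectrum",
    "EdgeMatrix",
    "fit_mvar",
    "select_order_aic",
    "transfer_matrix",
    "gpdc",
    "gpdc_from_coeffs",
    "band_average",
    "detect_edges_surrogate",
    "phase_randomize",
]

logger = logging.getLogger(__name__)

DEFAULT_N_FREQS = 129
DEFAULT_BAND = (0.01, 0.1)


@dataclass
class VARModel:
    """Fitted MVAR: lag matrices, residual covariance, bookkeeping."""

    coeffs: np.ndarray  # (p, N, N); [k, i, j] = effect of j at lag k+1 on i
    residual_cov: np.ndarray  # (N, N)
    n_samples_used: int
    sampling_interval: float = 2.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.residual_cov = np.asarray(self.residual_cov, dtype=float)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def noise_vars(self) -> np.ndarray:
        return np.diag(self.residual_cov)

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.coeffs)


@dataclass
class GPDCSpectrum:
    """|pi_ij(f)| magnitudes on a physical frequency grid (Hz)."""

    freqs: np.ndarray  # (F,) Hz
    values: np.ndarray  # (N, N, F) in [0, 1]
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeMatrix:
    """N x N band-averaged GPDC for one subject-session."""

    values: np.ndarray
    band: tuple[float, float] = DEFAULT_BAND
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = ""
    group: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.values.shape[0])]


class MVAR(BaseEstimator):
    """Multivariate autoregressive model estimated by per-equation OLS.

    Parameters
    ----------
    order : int or None
        VAR lag order. None selects it by AIC up to ``p_max``.
    p_max : int
        Upper bound for AIC order selection (used when order is None).
    standardize : bool
        Z-score each channel before fitting (default True), so the residual
        variance weighting of GPDC is comparable across channels.
    ridge : float
        Jitter added to the regressor Gram matrix only if it is singular.

    Attributes
    ----------
    coeffs_ : ndarray (p, N, N)
    residual_cov_ : ndarray (N, N), small-sample divisor T - p - N*p - 1
    order_ : int, the fitted lag order
    n_samples_used_ : int
    """

    def __init__(
        self,
        order: int | None = 1,
        p_max: int = 5,
        standardize: bool = True,
        ridge: float = 1e-8,
    ):
        self.order = order
        self.p_max = p_max
        self.standardize = standardize
        self.ridge = ridge

    def fit(self, X, censor: CensorMask | None = None) -> "MVAR":
        values, tr, names = _as_values(X)
        if censor is not None:
            run = censor.longest_contiguous_run()
            values = values[run]
        if self.standardize:
            values = _zscore(values)
        order = self.order
        if order is None:
            order = _select_order(values, self.p_max, self.ridge)
        model = _ols_var(values, order, self.ridge)
        self.coeffs_ = model.coeffs
        self.residual_cov_ = model.residual_cov
        self.order_ = order
        self.n_samples_used_ = model.n_samples_used
        self.model_ = VARModel(
            model.coeffs, model.residual_cov, model.n_samples_used, tr, names
        )
        return self

    def gpdc(self, freqs_hz: np.ndarray | None = None) -> GPDCSpectrum:
        return gpdc(self.model_, freqs_hz, self.model_.sampling_interval)

    def edge_matrix(
        self, low_hz: float = DEFAULT_BAND[0], high_hz: float = DEFAULT_BAND[1]
    ) -> EdgeMatrix:
        return band_average(self.gpdc(), low_hz, high_hz)


def _as_values(X) -> tuple[np.ndarray, float, list[str]]:
    if isinstance(X, TimeSeriesMatrix):
        return X.values, X.sampling_interval, list(X.channel_names)
    arr = np.asarray(X, dtype=float)
    return arr, 2.0, [f"ch{i}" for i in range(arr.shape[1])]


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - values.mean(axis=0)) / sd


def _check_identifiable(t: int, n: int, p: int) -> None:
    if p < 1:
        raise ValueError("order must be >= 1")
    if t - p <= n * p + 1:
        raise ValueError(
            f"not identifiable: T - p = {t - p} must exceed N*p + 1 = {n * p + 1}"
        )


def _lag_design(values: np.ndarray, p: int, start: int | None = None):
    """Response Y (T_eff x N) and regressors Z (T_eff x (N*p + 1), intercept last)."""
    t, n = values.shape
    if start is None:
        start = p
    y = values[start:]
    t_eff = t - start
    z = np.empty((t_eff, n * p + 1))
    for k in range(1, p + 1):
        z[:, (k - 1) * n : k * n] = values[start - k : t - k]
    z[:, -1] = 1.0
    return y, z


def _ols_var(values: np.ndarray, p: int, ridge: float, start: int | None = None) -> VARModel:
    t, n = values.shape
    _check_identifiable(t, n, p)
    y, z = _lag_design(values, p, start)
    gram = z.T @ z
    try:
        beta = np.linalg.solve(gram, z.T @ y)
    except np.linalg.LinAlgError:
        logger.warning("singular regressor Gram matrix; ridge fallback with jitter %g", ridge)
        beta = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]), z.T @ y)
    resid = y - z @ beta
    t_eff = y.shape[0]
    dof = t_eff - n * p - 1
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    residual_cov = resid.T @ resid / dof
    # beta rows: lag-1 block, ..., lag-p block, intercept; columns = equations
    coeffs = np.stack(
        [beta[(k - 1) * n : k * n, :].T for k in range(1, p + 1)]
    )  # (p, N, N): [k, i, j] = effect of j at lag k+1 on i
    return VARModel(coeffs, residual_cov, t_eff)


def fit_mvar(
    ts: TimeSeriesMatrix | np.ndarray,
    order: int = 1,
    standardize: bool = True,
    censor: CensorMask | None = None,
) -> VARModel:
    """OLS MVAR fit at a fixed lag order; see :class:`MVAR` for details."""
    est = MVAR(order=order, standardize=standardize)
    est.fit(ts, censor=censor)
    return est.model_


def _select_order(values: np.ndarray, p_max: int, ridge: float = 1e-8) -> int:
    t, n = values.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    _check_identifiable(t, n, p_max)
    t_eff = t - p_max
    best_p, best_aic = 1, np.inf
    for p in range(1, p_max + 1):
        # common sample window: responses start at index p_max for every p
        y, z = _lag_design(values, p, start=p_max)
        gram = z.T @ z
        try:
            beta = np.linalg.solve(gram, z.T @ y)
        except np.linalg.LinAlgError:
            beta = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]), z.T @ y)
        resid = y - z @ beta
        sigma_ml = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            logdet = -np.inf  # degenerate fit: treat as perfect, smallest p wins ties
        aic = logdet + 2.0 * p * n * n / t_eff
        if aic < best_aic - 1e-12:
            best_aic, best_p = aic, p
    return best_p


def select_order_aic(
    ts: TimeSeriesMatrix | np.ndarray, p_max: int, standardize: bool = True
) -> int:
    """AIC(p) = ln det Sigma_p + 2 p N^2 / T_eff over p = 1..p_max; ties -> smallest.

    All candidate orders are fitted on the common sample window implied by
    ``p_max`` so their likelihoods are comparable.
    """
    values, _, _ = _as_values(ts)
    if standardize:
        values = _zscore(values)
    return _select_order(values, p_max)


def transfer_matrix(model: VARModel, f_norm: float) -> np.ndarray:
    """Abar(f) = I - sum_k A_k exp(-i 2 pi f k) at normalized frequency f."""
    if not 0.0 <= f_norm <= 0.5:
        raise ValueError("f_norm must be in [0, 0.5] cycles/sample")
    n = model.n_channels
    abar = np.eye(n, dtype=complex)
    for k in range(model.order):
        abar -= model.coeffs[k] * np.exp(-2j * np.pi * f_norm * (k + 1))
    return abar


def gpdc_from_coeffs(
    coeffs: np.ndarray,
    noise_vars: np.ndarray,
    sampling_interval: float,
    n_freqs: int = DEFAULT_N_FREQS,
    freqs_hz: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> GPDCSpectrum:
    """GPDC spectrum directly from lag matrices and innovation variances."""
    coeffs = np.asarray(coeffs, dtype=float)
    noise_vars = np.asarray(noise_vars, dtype=float)
    if np.any(noise_vars <= 0):
        raise ValueError("noise variances must be strictly positive")
    nyquist = 0.5 / sampling_interval
    if freqs_hz is None:
        freqs_hz = np.linspace(0.0, nyquist, n_freqs)
    else:
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        if np.any(freqs_hz > nyquist + 1e-12):
            raise ValueError(f"frequencies above Nyquist {nyquist} Hz")
    p, n, _ = coeffs.shape
    f_norm = freqs_hz * sampling_interval  # cycles/sample
    k = np.arange(1, p + 1)
    # phase (p, F)
    phase = np.exp(-2j * np.pi * np.outer(k, f_norm))
    abar = np.eye(n, dtype=complex)[:, :, None] - np.tensordot(
        coeffs, phase, axes=([0], [0])
    )  # (N, N, F)
    sigma = np.sqrt(noise_vars)
    weighted = np.abs(abar) / sigma[:, None, None]  # |Abar_ij| / sigma_i
    denom = np.sqrt(np.sum(weighted**2, axis=0, keepdims=True))  # per source column j
    values = weighted / denom
    names = channel_names or [f"ch{i}" for i in range(n)]
    return GPDCSpectrum(freqs=freqs_hz, values=values, channel_names=list(names))


def gpdc(
    model: VARModel,
    freqs_hz: np.ndarray | None = None,
    sampling_interval: float | None = None,
    n_freqs: int = DEFAULT_N_FREQS,
) -> GPDCSpectrum:
    """GPDC spectrum of a fitted MVAR on a physical frequency grid."""
    tr = model.sampling_interval if sampling_interval is None else sampling_interval
    return gpdc_from_coeffs(
        model.coeffs, model.noise_vars, tr,
        n_freqs=n_freqs, freqs_hz=freqs_hz, channel_names=model.channel_names,
    )


def band_average(
    spec: GPDCSpectrum,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
) -> EdgeMatrix:
    """Entrywise mean of |pi_ij(f)| over grid frequencies in [low, high] inclusive."""
    sel = (spec.freqs >= low_hz) & (spec.freqs <= high_hz)
    if sel.sum() < 2:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz intersects the frequency grid in "
            f"{int(sel.sum())} point(s); need >= 2"
        )
    values = spec.values[:, :, sel].mean(axis=2)
    return EdgeMatrix(values=values, band=(low_hz, high_hz),
                      channel_names=list(spec.channel_names))


def phase_randomize(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent phase randomization per channel, amplitude spectra preserved."""
    t, n = values.shape
    fft = np.fft.rfft(values, axis=0)
    n_freq = fft.shape[0]
    phases = rng.uniform(0, 2 * np.pi, size=(n_freq, n))
    phases[0] = 0.0
    if t % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    surrogate = np.fft.irfft(fft * np.exp(1j * phases), n=t, axis=0)
    return surrogate


def detect_edges_surrogate(
    ts: TimeSeriesMatrix | np.ndarray,
    n_surrogates: int = 99,
    alpha: float = 0.05,
    seed: int | None = None,
    order: int | None = None,
    p_max: int = 5,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
) -> np.ndarray:
    """Per-edge causality detection against phase-randomized surrogates.

    The observed band-averaged GPDC of each directed edge is compared with its
    distribution over ``n_surrogates`` phase-randomized copies of the data
    (independent phases per channel, amplitude spectra preserved, which
    destroys cross-channel lagged structure). An edge is detected when the
    surrogate p-value (1 + #surrogates >= observed) / (1 + n_surrogates) is
    <= alpha. Returns a boolean N x N matrix (diagonal False).
    """
    if (n_surrogates + 1) * alpha < 1.0:
        raise ValueError(
            f"n_surrogates = {n_surrogates} too few for alpha = {alpha}; "
            f"need at least {int(np.ceil(1 / alpha)) - 1}"
        )
    values, tr, names = _as_values(ts)
    rng = np.random.default_rng(seed)
    if order is None:
        order = select_order_aic(values, p_max)
    observed = fit_mvar(values, order=order)
    obs_edges = band_average(
        gpdc(observed, sampling_interval=tr), low_hz, high_hz
    ).values
    n = values.shape[1]
    exceed = np.zeros((n, n), dtype=int)
    for _ in range(n_surrogates):
        surr = phase_randomize(values, rng)
        model = fit_mvar(surr, order=order)
        surr_edges = band_average(
            gpdc(model, sampling_interval=tr), low_hz, high_hz
        ).values
        exceed += surr_edges >= obs_edges
    pvals = (1.0 + exceed) / (1.0 + n_surrogates)
    detected = pvals <= alpha
    np.fill_diagonal(detected, False)
    return detected
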