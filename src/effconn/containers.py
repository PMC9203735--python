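"""Core in-memory containers shared across pipeline stages.

The currency of the pipeline is the multichannel network time series: one
matrix per subject-session, rows = timepoints, columns = network components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeriesMatrix:
    """A T x N multichannel time series for one subject-session.

    Parameters
    ----------
    values : ndarray of shape (T, N)
        Signal values, arbitrary units.
    sampling_interval : float
        Sampling interval in seconds (fMRI TR). Default 2.0 s.
    channel_names : list of str, optional
        One label per column. Auto-generated ``ch0..chN-1`` if omitted.
    """

    values: np.ndarray
    sampling_interval: float = 2.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D (T, N), got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at (row={bad[0]}, col={bad[1]})")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.values.shape[1])]
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.sampling_interval

    def copy_with(self, values: np.ndarray) -> "TimeSeriesMatrix":
        return TimeSeriesMatrix(
            values=np.asarray(values, dtype=float),
            sampling_interval=self.sampling_interval,
            channel_names=list(self.channel_names),
        )


@dataclass
class ConfoundTable:
    """Per-frame nuisance measurements accompanying one time series.

    fd : framewise displacement per frame (mm, >= 0)
    std_dvars : standardized DVARS per frame (dimensionless)
    noise_series : frames x voxels matrix from noise compartments (CompCor input)
    """

    fd: np.ndarray
    std_dvars: np.ndarray
    noise_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.std_dvars = np.asarray(self.std_dvars, dtype=float)
        if self.fd.shape != self.std_dvars.shape:
            raise ValueError("fd and std_dvars must have the same length")
        if np.any(self.fd < 0):
            raise ValueError("framewise displacement must be non-negative")
        if self.noise_series is not None:
            self.noise_series = np.asarray(self.noise_series, dtype=float)
            if self.noise_series.shape[0] != self.fd.shape[0]:
                raise ValueError("noise_series frame count must match fd")

    @property
    def n_frames(self) -> int:
        return self.fd.shape[0]


# reason codes for censored frames
REASON_FD = "FD"
REASON_DVARS = "DVARS"
REASON_BOTH = "FD+DVARS"


@dataclass
class CensorMask:
    """Per-frame keep/censor decisions with a reason code per censored frame."""

    keep: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.keep.shape[0]

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    def longest_contiguous_run(self) -> slice:
        """Slice of the longest run of consecutive kept frames (empty if none)."""
        best_start, best_len = 0, 0
        start = None
        for i, k in enumerate(list(self.keep) + [False]):
            if k and start is None:
                start = i
            elif not k and start is not None:
                if i - start > best_len:
                    best_start, best_len = start, i - start
                start = None
        return slice(best_start, best_start + best_len)
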