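"""Edge-wise group statistics on effective-connectivity matrices.

One-sample, independent-groups (pooled-variance), and paired t tests per
directed edge with Benjamini-Hochberg FDR correction across the N(N-1)
off-diagonal edges of each test family; edge-occurrence frequency maps; and
Pearson correlation of an edge's causal strength with clinical scores.
Self-edges are excluded from all edge statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .gca import EdgeMatrix

__all__ = [
    "StudyTable",
    "EdgeTestResult",
    "bh_fdr",
    "one_sample_edges",
    "independent_t_edges",
    "paired_t_edges",
    "edge_frequency",
    "edge_score_correlation",
    "CorrelationResult",
]

logger = logging.getLogger(__name__)

GROUPS = ("patient", "control")
SESSIONS = ("before", "after")


@dataclass
class StudyRecord:
    subject_id: str
    group: str
    session: str
    edges: EdgeMatrix
    scores: dict[str, float] = field(default_factory=dict)
    true_edge_strength: float | None = None


@dataclass
class StudyTable:
    """Subject-session records carrying edge matrices and clinical scores."""

    records: list[StudyRecord]

    def __post_init__(self) -> None:
        if self.records:
            n = self.records[0].edges.values.shape[0]
            for r in self.records:
                if r.edges.values.shape != (n, n):
                    raise ValueError("inconsistent edge-matrix size across records")

    @property
    def channel_names(self) -> list[str]:
        return list(self.records[0].edges.channel_names)

    @property
    def n_channels(self) -> int:
        return self.records[0].edges.values.shape[0]

    def select(self, group: str | None = None, session: str | None = None) -> list[StudyRecord]:
        out = self.records
        if group is not None:
            out = [r for r in out if r.group == group]
        if session is not None:
            out = [r for r in out if r.session == session]
        return out

    def stack(self, group: str | None = None, session: str | None = None) -> np.ndarray:
        recs = self.select(group, session)
        if not recs:
            n = self.n_channels
            return np.empty((0, n, n))
        return np.stack([r.edges.values for r in recs])

    def paired_diffs(self, group: str) -> tuple[list[str], np.ndarray]:
        """Per-subject (after - before) edge differences; unpaired excluded."""
        before = {r.subject_id: r for r in self.select(group, "before")}
        after = {r.subject_id: r for r in self.select(group, "after")}
        ids = []
        diffs = []
        for sid in before:
            if sid in after:
                ids.append(sid)
                diffs.append(after[sid].edges.values - before[sid].edges.values)
            else:
                logger.warning("excluding unpaired subject %s", sid)
        for sid in after:
            if sid not in before:
                logger.warning("excluding unpaired subject %s", sid)
        return ids, np.stack(diffs)


@dataclass
class EdgeTestResult:
    """Per-edge t, raw p, BH-adjusted q, and significance flags (q < level)."""

    t: np.ndarray  # (N, N); diagonal NaN
    p: np.ndarray
    q: np.ndarray
    flags: np.ndarray  # boolean
    group_means: dict[str, np.ndarray] = field(default_factory=dict)
    channel_names: list[str] = field(default_factory=list)
    family: str = ""

    def to_frame(self) -> pd.DataFrame:
        n = self.t.shape[0]
        names = self.channel_names or [f"ch{i}" for i in range(n)]
        rows = []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rows.append({
                    "source": names[j],
                    "target": names[i],
                    "t": self.t[i, j],
                    "p": self.p[i, j],
                    "q": self.q[i, j],
                    "significant": bool(self.flags[i, j]),
                })
        return pd.DataFrame(rows)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and flags (adjusted < q)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy(), np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, adjusted < q


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _fdr_on_edges(t: np.ndarray, p: np.ndarray, q_level: float):
    n = t.shape[0]
    mask = _offdiag_mask(n)
    q = np.full((n, n), np.nan)
    flags = np.zeros((n, n), dtype=bool)
    adj, flg = bh_fdr(p[mask], q=q_level)
    q[mask] = adj
    flags[mask] = flg
    np.fill_diagonal(t, np.nan)
    np.fill_diagonal(p, np.nan)
    return t, p, q, flags


def _one_sample_t(values: np.ndarray):
    """values: (n_subj, N, N) -> elementwise one-sample t against 0 and p.

    Zero-variance edges: a nonzero mean is degenerate certainty (p = smallest
    positive float); a zero mean is a perfect null (p = 1). Both are logged.
    """
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = 2 * sps.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    if np.any(zero_var & _offdiag_mask(values.shape[1])):
        logger.info("zero-variance edges: p set to tiny (mean != 0) or 1 (mean == 0)")
    p = np.where(zero_var & (mean != 0), np.finfo(float).tiny, p)
    p = np.where(zero_var & (mean == 0), 1.0, p)
    return t, p


def one_sample_edges(
    table: StudyTable,
    group: str,
    session: str,
    q_level: float = 0.05,
) -> EdgeTestResult:
    """One-sample t of each edge against 0 for one group x session cell."""
    values = table.stack(group, session)
    if values.shape[0] < 3:
        raise ValueError("need >= 3 subjects for a one-sample test")
    t, p = _one_sample_t(values)
    t, p, q, flags = _fdr_on_edges(t, p, q_level)
    return EdgeTestResult(
        t, p, q, flags,
        group_means={f"{group}/{session}": values.mean(axis=0)},
        channel_names=table.channel_names,
        family=f"one-sample:{group}/{session}",
    )


def independent_t_edges(
    table: StudyTable,
    session: str,
    q_level: float = 0.05,
    welch: bool = False,
) -> EdgeTestResult:
    """Two-sample t per edge, patients vs controls at one session.

    Positive t = patients higher. Pooled-variance (Student) by default;
    ``welch=True`` switches to unequal-variance t.
    """
    pat = table.stack("patient", session)
    con = table.stack("control", session)
    if pat.shape[0] < 2 or con.shape[0] < 2:
        raise ValueError("both groups need >= 2 subjects")
    res = sps.ttest_ind(pat, con, axis=0, equal_var=not welch)
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)
    bad = ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    t, p, q, flags = _fdr_on_edges(t, p, q_level)
    return EdgeTestResult(
        t, p, q, flags,
        group_means={
            f"patient/{session}": pat.mean(axis=0),
            f"control/{session}": con.mean(axis=0),
        },
        channel_names=table.channel_names,
        family=f"independent:{session}",
    )


def paired_t_edges(
    table: StudyTable,
    group: str,
    q_level: float = 0.05,
) -> EdgeTestResult:
    """Paired t per edge of (after - before) within one group."""
    _, diffs = table.paired_diffs(group)
    if diffs.shape[0] < 3:
        raise ValueError("need >= 3 paired subjects")
    t, p = _one_sample_t(diffs)
    t, p, q, flags = _fdr_on_edges(t, p, q_level)
    return EdgeTestResult(
        t, p, q, flags,
        group_means={f"{group}/after-before": diffs.mean(axis=0)},
        channel_names=table.channel_names,
        family=f"paired:{group}",
    )


def edge_frequency(detections: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Entrywise mean of per-subject binary detection matrices (in [0, 1])."""
    arr = np.asarray(detections, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("need a non-empty stack of N x N detection matrices")
    if arr.shape[1] != arr.shape[2]:
        raise ValueError("detection matrices must be square with consistent N")
    return arr.mean(axis=0)


@dataclass
class CorrelationResult:
    r: float
    r2: float
    p: float
    slope: float
    intercept: float
    n: int
    edge: tuple[str, str]
    score: str
    mode: str


def edge_score_correlation(
    table: StudyTable,
    edge: tuple[str, str],
    score: str,
    mode: str = "levels",
    group: str = "patient",
    session: str = "before",
    use_true_strength: bool = False,
) -> CorrelationResult:
    """Pearson correlation between one edge's causal strength and a clinical
    score, with the exact t-based two-tailed p (df = n - 2) and a fitted line.

    mode="levels" correlates values at one group x session cell;
    mode="differences" correlates per-subject (after - before) changes in both
    variables. ``use_true_strength`` swaps in the stored ground-truth strength
    (synthetic studies only).
    """
    names = table.channel_names
    src, tgt = edge
    i, j = names.index(tgt), names.index(src)

    def strength(rec: StudyRecord) -> float:
        if use_true_strength:
            if rec.true_edge_strength is None:
                raise ValueError("record has no stored ground-truth strength")
            return rec.true_edge_strength
        return float(rec.edges.values[i, j])

    if mode == "levels":
        recs = [r for r in table.select(group, session) if score in r.scores]
        x = np.array([strength(r) for r in recs])
        y = np.array([r.scores[score] for r in recs])
    elif mode == "differences":
        before = {r.subject_id: r for r in table.select(group, "before")}
        after = {r.subject_id: r for r in table.select(group, "after")}
        ids = [s for s in before if s in after
               and score in before[s].scores and score in after[s].scores]
        x = np.array([strength(after[s]) - strength(before[s]) for s in ids])
        y = np.array([after[s].scores[score] - before[s].scores[score] for s in ids])
    else:
        raise ValueError("mode must be 'levels' or 'differences'")

    if x.size < 3:
        raise ValueError("need >= 3 complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable is constant")
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(
        r=float(r), r2=float(r**2), p=float(p),
        slope=float(slope), intercept=float(intercept),
        n=int(x.size), edge=edge, score=score, mode=mode,
    )
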