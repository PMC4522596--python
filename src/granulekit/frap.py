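"""FRAP quantification for RNP granules.

Implements the double-normalization analysis used to measure molecular
turnover of fluorescent foci in small cells, where the photobleaching /
photoconversion pulse aimed at one focus can also deplete nearby structures:

1. background subtraction and double normalization of the focus signal
   against a reference focus in a neighboring cell, which corrects for
   acquisition bleaching shared by both;
2. a quality-control step that fits an exponential decay to the post-bleach
   reference signal, extrapolates it back over the pre-bleach baseline, and
   excludes cells whose reference focus lost fluorescence at the bleach
   event itself (photoconversion crosstalk);
3. a single-exponential recovery fit ``y = A * (1 - exp(-p * x))`` of the
   normalized post-bleach signal, with the half-recovery time
   ``t_1/2 = ln(2) / p``;
4. group summaries: medians, quartiles and an unpaired two-sample t-test on
   per-cell half-times.

Slow half-times (minutes) indicate a solid, amyloid-like assembly; fast
half-times (tens of seconds) indicate a liquid-like granule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "IntensityTrace",
    "NormalizedTrace",
    "ReferenceQC",
    "RecoveryFit",
    "GroupSummary",
    "TraceRejected",
    "normalize_trace",
    "reference_qc",
    "fit_recovery",
    "half_time",
    "fit_trace",
    "analyze_traces",
    "summarize_groups",
]

LN2 = float(np.log(2.0))

# trust-region NLS settings shared by every fit in this module
_LSQ_OPTS = dict(method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=1000)


class TraceRejected(ValueError):
    """Raised when a trace cannot be normalized (distinct from QC exclusion)."""


@dataclass
class IntensityTrace:
    """Raw per-cell FRAP time series.

    Parameters
    ----------
    time
        Acquisition time of each frame in seconds, uniformly spaced,
        ``time[0] == 0`` at the first acquired frame.
    I_F, I_R, I_B
        Focus, reference-focus and background intensity per frame.
    bleach_index
        Index of the first post-bleach frame; equals the number of
        pre-bleach frames.
    """

    time: np.ndarray
    I_F: np.ndarray
    I_R: np.ndarray
    I_B: np.ndarray
    bleach_index: int
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.I_F = np.asarray(self.I_F, dtype=float)
        self.I_R = np.asarray(self.I_R, dtype=float)
        self.I_B = np.asarray(self.I_B, dtype=float)
        n = len(self.time)
        for name in ("I_F", "I_R", "I_B"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name}: length {len(getattr(self, name))} != {n} frames")
        if not (1 <= self.bleach_index < n):
            raise ValueError(f"bleach_index: must satisfy 1 <= bleach_index < {n}, got {self.bleach_index}")
        for name in ("time", "I_F", "I_R", "I_B"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name}: non-finite values")
        if n > 1:
            dt = np.diff(self.time)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time: frames must be uniformly spaced and increasing")

    @property
    def n_prebleach(self) -> int:
        return self.bleach_index

    @property
    def bleach_time(self) -> float:
        """Time of the first post-bleach frame (seconds)."""
        return float(self.time[self.bleach_index])


@dataclass
class NormalizedTrace:
    """Double-normalized post-bleach recovery curve."""

    time_post: np.ndarray  # seconds since the bleach (0 at first post frame)
    I_F_norm: np.ndarray
    I_F_pre: float  # background-subtracted pre-bleach mean of the focus
    I_R_pre: float  # ... and of the reference focus
    cell_id: str = "cell"


@dataclass
class ReferenceQC:
    """Reference-focus decay fit and photoconversion-crosstalk exclusion."""

    A_decay: float
    p_decay: float
    I_R_estimate: float
    I_R_measured: float
    excluded: bool
    fit_residual: float
    usable: bool = True  # False when the decay fit did not converge


@dataclass
class RecoveryFit:
    """Single-exponential recovery fit ``y = A (1 - e^{-p x})``."""

    A_rec: float
    p_rec: float
    t_half: float  # seconds; NaN when not converged
    fit_residual: float
    converged: bool
    offset: float = 0.0  # only fitted when include_offset=True


@dataclass
class GroupSummary:
    """Two-group comparison of per-cell half-recovery times."""

    labels: tuple[str, str]
    groups: tuple[list[float], list[float]]
    medians: tuple[float, float]
    quartiles: tuple[tuple[float, float], tuple[float, float]]  # (q25, q75) per group
    n: tuple[int, int]
    t_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        a, b = self.labels
        return {
            "groups": {
                a: {"n": self.n[0], "median_s": self.medians[0], "q25_s": self.quartiles[0][0], "q75_s": self.quartiles[0][1]},
                b: {"n": self.n[1], "median_s": self.medians[1], "q25_s": self.quartiles[1][0], "q75_s": self.quartiles[1][1]},
            },
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def normalize_trace(trace: IntensityTrace) -> NormalizedTrace:
    """Background-subtract and double-normalize a FRAP trace.

    The pre-bleach means ``I_F_pre = mean(I_F - I_B)`` and
    ``I_R_pre = mean(I_R - I_B)`` are taken over frames
    ``0 .. bleach_index-1``; the normalized post-bleach signal is

        I_F_norm(t) = [(I_F(t) - I_B(t)) / I_F_pre] / [(I_R(t) - I_B(t)) / I_R_pre]

    which is exactly invariant to a common gain or offset applied to all
    three channels, and cancels acquisition bleaching shared by focus and
    reference.

    Raises
    ------
    TraceRejected
        If a pre-bleach mean is nonpositive, or the background-subtracted
        reference is nonpositive on any post-bleach frame. This marks an
        unusable measurement, distinct from the crosstalk QC exclusion.
    """
    k = trace.bleach_index
    f_pre = float(np.mean(trace.I_F[:k] - trace.I_B[:k]))
    r_pre = float(np.mean(trace.I_R[:k] - trace.I_B[:k]))
    if f_pre <= 0 or r_pre <= 0:
        raise TraceRejected(
            f"{trace.cell_id}: nonpositive pre-bleach mean (I_F_pre={f_pre:.3g}, I_R_pre={r_pre:.3g})"
        )
    ref = (trace.I_R[k:] - trace.I_B[k:]) / r_pre
    if np.any(ref <= 0):
        raise TraceRejected(f"{trace.cell_id}: nonpositive reference signal in the post-bleach period")
    foc = (trace.I_F[k:] - trace.I_B[k:]) / f_pre
    return NormalizedTrace(
        time_post=trace.time[k:] - trace.time[k],
        I_F_norm=foc / ref,
        I_F_pre=f_pre,
        I_R_pre=r_pre,
        cell_id=trace.cell_id,
    )


def reference_qc(
    trace: IntensityTrace,
    qc_tolerance: float = 0.02,
    subtract_background: bool = True,
) -> ReferenceQC:
    """Fit the reference-focus decay and apply the crosstalk exclusion rule.

    An exponential ``y = A * exp(p * x)`` (``p`` unconstrained in sign) is
    fitted to the post-bleach reference signal, with ``x`` measured from the
    bleach. Extrapolating the fitted curve back over the pre-bleach time
    points and averaging yields ``I_R_estimate``, the reference level the
    decay alone predicts for the baseline. If the actually measured
    baseline ``I_R_measured`` exceeds it — i.e.
    ``I_R_estimate < I_R_measured * (1 - qc_tolerance)`` — the reference
    focus lost fluorescence at the bleach event (photoconversion
    crosstalk) and the cell is excluded. ``qc_tolerance=0`` recovers the
    literal inequality.
    """
    k = trace.bleach_index
    if len(trace.time) - k < 3:
        raise ValueError("reference_qc: need >= 3 post-bleach frames")
    bg = trace.I_B if subtract_background else np.zeros_like(trace.I_B)
    y = trace.I_R[k:] - bg[k:]
    x = trace.time[k:] - trace.time[k]
    measured = float(np.mean(trace.I_R[:k] - bg[:k]))

    A0 = max(float(y[0]), 1e-12)
    yl = max(float(y[-1]), 1e-12)
    p0 = np.log(yl / A0) / (x[-1] - x[0]) if x[-1] > x[0] else 0.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        return theta[0] * np.exp(theta[1] * x) - y

    sol = optimize.least_squares(residuals, x0=[A0, p0], **_LSQ_OPTS)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return ReferenceQC(np.nan, np.nan, np.nan, measured, excluded=False, fit_residual=rms, usable=False)
    A_fit, p_fit = map(float, sol.x)
    x_pre = trace.time[:k] - trace.time[k]  # negative: extrapolation backward
    estimate = float(np.mean(A_fit * np.exp(p_fit * x_pre)))
    excluded = estimate < measured * (1.0 - qc_tolerance)
    return ReferenceQC(A_fit, p_fit, estimate, measured, excluded=excluded, fit_residual=rms)


def fit_recovery(norm: NormalizedTrace, include_offset: bool = False) -> RecoveryFit:
    """Fit ``y = A (1 - e^{-p x})`` (optionally ``+ c``) to a normalized curve.

    Initialization: ``A0`` is the mean of the last 10% of points; ``p0`` is
    ``ln 2 / t*`` where ``t*`` is the first time the curve exceeds ``A0/2``,
    falling back to ``4 / span``. A fit that fails to converge, or converges
    to a nonpositive rate or amplitude, is flagged ``converged=False`` with
    ``t_half`` NaN; such traces are non-recovering and are dropped from
    group summaries.
    """
    x = np.asarray(norm.time_post, dtype=float)
    y = np.asarray(norm.I_F_norm, dtype=float)
    if len(x) < 3:
        raise ValueError("fit_recovery: need >= 3 post-bleach points")
    span = float(x[-1] - x[0]) if x[-1] > x[0] else 1.0

    n_tail = max(1, int(round(0.1 * len(y))))
    A0 = float(np.mean(y[-n_tail:]))
    above = np.nonzero((y >= A0 / 2.0) & (x > 0))[0]
    p0 = LN2 / float(x[above[0]]) if (A0 > 0 and above.size) else 4.0 / span
    if A0 <= 0:
        A0 = max(float(np.max(y)), 1e-3)

    if include_offset:
        def residuals(theta: np.ndarray) -> np.ndarray:
            A, p, c = theta
            return c + A * (1.0 - np.exp(-p * x)) - y
        x0 = [A0, p0, float(y[0])]
    else:
        def residuals(theta: np.ndarray) -> np.ndarray:
            A, p = theta
            return A * (1.0 - np.exp(-p * x)) - y
        x0 = [A0, p0]

    sol = optimize.least_squares(residuals, x0=x0, **_LSQ_OPTS)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    A_fit = float(sol.x[0])
    p_fit = float(sol.x[1])
    c_fit = float(sol.x[2]) if include_offset else 0.0
    ok = bool(sol.success) and np.all(np.isfinite(sol.x)) and p_fit > 0 and A_fit > 0
    return RecoveryFit(
        A_rec=A_fit,
        p_rec=p_fit,
        t_half=LN2 / p_fit if ok else float("nan"),
        fit_residual=rms,
        converged=ok,
        offset=c_fit,
    )


def half_time(p_rec: float) -> float:
    """Half-recovery time ``t_1/2 = ln 2 / p`` for a recovery rate ``p > 0``."""
    if not np.isfinite(p_rec) or p_rec <= 0:
        raise ValueError(f"half_time: non-recovering trace (p_rec={p_rec!r} <= 0)")
    return LN2 / float(p_rec)


def fit_trace(
    trace: IntensityTrace,
    qc_tolerance: float = 0.02,
    include_offset: bool = False,
    subtract_background: bool = True,
) -> tuple[NormalizedTrace, ReferenceQC, RecoveryFit]:
    """Run normalization, reference QC and recovery fitting on one trace."""
    norm = normalize_trace(trace)
    qc = reference_qc(trace, qc_tolerance=qc_tolerance, subtract_background=subtract_background)
    rec = fit_recovery(norm, include_offset=include_offset)
    return norm, qc, rec


def analyze_traces(
    traces: Sequence[IntensityTrace],
    qc_tolerance: float = 0.02,
    include_offset: bool = False,
) -> pd.DataFrame:
    """Fit every trace; return a per-cell table.

    Columns: cell_id, rejected, excluded, converged, usable, A_rec, p_rec,
    t_half_s, rec_residual, I_R_estimate, I_R_measured. A trace that fails
    normalization is kept in the table with ``rejected=True`` and NaN fits.
    """
    rows = []
    for trace in traces:
        row: dict = {"cell_id": trace.cell_id, "rejected": False, "excluded": False,
                     "converged": False, "usable": True, "A_rec": np.nan, "p_rec": np.nan,
                     "t_half_s": np.nan, "rec_residual": np.nan,
                     "I_R_estimate": np.nan, "I_R_measured": np.nan}
        try:
            _, qc, rec = fit_trace(trace, qc_tolerance=qc_tolerance, include_offset=include_offset)
        except TraceRejected:
            row["rejected"] = True
            rows.append(row)
            continue
        row.update(excluded=qc.excluded, usable=qc.usable,
                   I_R_estimate=qc.I_R_estimate, I_R_measured=qc.I_R_measured,
                   converged=rec.converged, A_rec=rec.A_rec, p_rec=rec.p_rec,
                   t_half_s=rec.t_half, rec_residual=rec.fit_residual)
        rows.append(row)
    return pd.DataFrame(rows)


def usable_half_times(table: pd.DataFrame) -> list[float]:
    """Half-times of traces that passed normalization, QC and fitting."""
    ok = table[(~table.rejected) & (~table.excluded) & table.usable & table.converged]
    return [float(v) for v in ok.t_half_s]


def summarize_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    labels: tuple[str, str] = ("A", "B"),
) -> GroupSummary:
    """Medians, quartiles and an unpaired equal-variance t-test on half-times.

    The test is two-sided on the raw per-cell values. With fewer than two
    values in either group the test is skipped (NaN statistic) with a
    warning; medians and quartiles are still reported.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("summarize_groups: both groups must be nonempty")
    med = (float(np.median(a)), float(np.median(b)))
    quart = (
        (float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        (float(np.percentile(b, 25)), float(np.percentile(b, 75))),
    )
    if a.size < 2 or b.size < 2:
        warnings.warn("summarize_groups: a group has <2 values; t-test skipped", stacklevel=2)
        t_stat, p_val = float("nan"), float("nan")
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return GroupSummary(
        labels=labels,
        groups=([float(v) for v in a], [float(v) for v in b]),
        medians=med,
        quartiles=quart,
        n=(int(a.size), int(b.size)),
        t_statistic=t_stat,
        p_value=p_val,
    )
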