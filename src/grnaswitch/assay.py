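"""Readout math for switch characterization assays.

Fluorescence from a switch experiment is normalized to the dynamic range
set by a targeting gRNA control (0%) and a non-targeting gRNA control
(100%):

    normalized = 100 * (F_expt - F_targeting) / (F_nontargeting - F_targeting)

For growth assays, a per-cell GFP synthesis-rate analogue is computed as
the differential dF/dOD over fixed time windows inside the
exponential-growth span (found as the window maximizing linearity of
log OD600), and normalized the same way.  Flow-cytometry means are
background-subtracted before normalization.  Group comparisons use
Welch's two-tailed t-test (unequal variances).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayTable",
    "DifferentialSeries",
    "normalized_fluorescence",
    "facs_normalize",
    "find_exponential_window",
    "growth_differentials",
    "normalized_expression",
    "welch_t_test",
    "analyze_plate",
]

ROLES = ("experiment", "targeting_control", "nontargeting_control", "background")


@dataclass
class AssayTable:
    """Plate-reader time series for a set of samples.

    time is a strictly increasing grid in minutes; ``fluor`` and
    ``abs600`` map sample label -> np.ndarray aligned with time; roles
    tag each sample as experiment / targeting_control /
    nontargeting_control / background.
    """

    time: np.ndarray
    fluor: Dict[str, np.ndarray]
    roles: Dict[str, str]
    abs600: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for label, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for sample {label!r}")
        for label, series in self.fluor.items():
            if len(series) != len(self.time):
                raise ValueError(f"sample {label!r}: series length != time grid")

    def by_role(self, role: str) -> list:
        return [s for s, r in self.roles.items() if r == role]

    def single(self, role: str) -> str:
        matches = self.by_role(role)
        if len(matches) != 1:
            raise ValueError(f"need exactly one {role!r} sample, found {len(matches)}")
        return matches[0]

    @classmethod
    def from_csv(cls, series_csv, samplesheet_tsv) -> "AssayTable":
        """Long-format CSV (time_min, sample, fluor[, abs600]) plus a
        samplesheet TSV (sample, role)."""
        df = pd.read_csv(series_csv)
        roles = pd.read_csv(samplesheet_tsv, sep="\t").set_index("sample")["role"].to_dict()
        times = np.unique(df["time_min"].values)
        fluor, od = {}, {}
        for sample, grp in df.groupby("sample"):
            grp = grp.sort_values("time_min")
            if not np.array_equal(grp["time_min"].values, times):
                raise ValueError(f"sample {sample!r} is not on the common time grid")
            fluor[sample] = grp["fluor"].values.astype(float)
            if "abs600" in grp:
                od[sample] = grp["abs600"].values.astype(float)
        return cls(time=times, fluor=fluor, roles=roles, abs600=od or None)


@dataclass
class DifferentialSeries:
    """dF/dOD differentials over fixed windows inside the exponential span."""

    times: np.ndarray  # window start times (min)
    diffs: np.ndarray
    window_minutes: float
    exponential_window: Tuple[float, float]


def normalized_fluorescence(expt, targeting, nontargeting):
    """Percent of the targeting/non-targeting control dynamic range."""
    expt = np.asarray(expt, dtype=float)
    denom = np.asarray(nontargeting, dtype=float) - np.asarray(targeting, dtype=float)
    if np.any(denom == 0):
        raise ZeroDivisionError("targeting and non-targeting controls coincide")
    out = 100.0 * (expt - targeting) / denom
    return float(out) if out.ndim == 0 else out


def facs_normalize(mean_expt, mean_background, mean_targeting, mean_nontargeting):
    """Background-subtract all flow-cytometry means, then normalize."""
    return normalized_fluorescence(
        np.asarray(mean_expt, dtype=float) - mean_background,
        mean_targeting - mean_background,
        mean_nontargeting - mean_background,
    )


def find_exponential_window(
    time: np.ndarray, abs600: np.ndarray, span_minutes: float = 210.0
) -> Tuple[float, float]:
    """Earliest contiguous span of the stated length maximizing the R^2 of
    a straight-line fit to log(OD600) — the exponential growth phase."""
    time = np.asarray(time, dtype=float)
    od = np.asarray(abs600, dtype=float)
    if np.any(od <= 0):
        raise ValueError("OD600 must be positive to fit exponential growth")
    log_od = np.log(od)
    best: Optional[Tuple[float, int]] = None
    n = len(time)
    for start_idx in range(n):
        t0 = time[start_idx]
        mask = (time >= t0) & (time <= t0 + span_minutes)
        idx = np.where(mask)[0]
        if time[idx[-1]] - t0 < span_minutes:
            break
        x, y = time[idx], log_od[idx]
        if np.allclose(y, y[0]):
            raise ValueError("OD600 is constant; growth rate undefined")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, start_idx)
    if best is None:
        raise ValueError(f"need at least {span_minutes} minutes of data")
    t_start = float(time[best[1]])
    return (t_start, t_start + span_minutes)


def growth_differentials(
    time: np.ndarray,
    fluor: np.ndarray,
    abs600: np.ndarray,
    exponential_window: Tuple[float, float],
    window_points: int = 4,
    endpoint_exclusion_minutes: float = 20.0,
) -> DifferentialSeries:
    """diff(t) = (F[t+w] - F[t]) / (OD[t+w] - OD[t]) for windows of
    ``window_points`` sampling intervals lying inside the exponential
    span with its first and last ``endpoint_exclusion_minutes`` removed."""
    time = np.asarray(time, dtype=float)
    fluor = np.asarray(fluor, dtype=float)
    od = np.asarray(abs600, dtype=float)
    steps = np.diff(time)
    if not np.allclose(steps, steps[0]):
        raise ValueError("sampling interval must be uniform")
    lo = exponential_window[0] + endpoint_exclusion_minutes
    hi = exponential_window[1] - endpoint_exclusion_minutes
    times, diffs = [], []
    for i in range(len(time) - window_points):
        t_a, t_b = time[i], time[i + window_points]
        if t_a < lo or t_b > hi:
            continue
        d_od = od[i + window_points] - od[i]
        if d_od == 0:
            raise ZeroDivisionError(f"flat OD600 in window starting {t_a} min")
        times.append(t_a)
        diffs.append((fluor[i + window_points] - fluor[i]) / d_od)
    return DifferentialSeries(
        times=np.array(times),
        diffs=np.array(diffs),
        window_minutes=float(window_points * steps[0]),
        exponential_window=tuple(exponential_window),
    )


def normalized_expression(diff_expt, diff_targeting, diff_nontargeting):
    """Normalized GFP expression (%) from representative differentials."""
    return normalized_fluorescence(diff_expt, diff_targeting, diff_nontargeting)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float, float]:
    """Welch's two-tailed t-test: returns (t, Welch-Satterthwaite df, p).

    With zero variance in both groups and equal means the statistic is
    undefined; by convention t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), float(na + nb - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    se2 = va / na + vb / nb
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def _representative_time(series: DifferentialSeries, window: Tuple[float, float]) -> int:
    """Index of the differential closest to the exponential-window midpoint."""
    if len(series.times) == 0:
        raise ValueError("no differentials inside the exponential window")
    mid = 0.5 * (window[0] + window[1])
    return int(np.argmin(np.abs(series.times - mid)))


def analyze_plate(
    table: AssayTable,
    span_minutes: float = 210.0,
    window_points: int = 4,
    representative_time: Optional[float] = None,
) -> pd.DataFrame:
    """Full plate pipeline: exponential window on the non-targeting
    control's OD600, growth differentials per sample, normalized GFP
    expression per experiment sample at the representative time point
    (default: nearest the window midpoint)."""
    if table.abs600 is None:
        raise ValueError("plate analysis requires OD600 series")
    targeting = table.single("targeting_control")
    nontargeting = table.single("nontargeting_control")
    window = find_exponential_window(
        table.time, table.abs600[nontargeting], span_minutes
    )
    series = {
        s: growth_differentials(
            table.time, table.fluor[s], table.abs600[s], window, window_points
        )
        for s in table.fluor
    }
    if representative_time is None:
        rep_idx = _representative_time(series[nontargeting], window)
    else:
        rep_idx = int(
            np.argmin(np.abs(series[nontargeting].times - representative_time))
        )
    rows = []
    d_t = series[targeting].diffs[rep_idx]
    d_nt = series[nontargeting].diffs[rep_idx]
    for s in table.by_role("experiment"):
        rows.append(
            {
                "sample": s,
                "representative_time_min": series[s].times[rep_idx],
                "differential": series[s].diffs[rep_idx],
                "normalized_expression_pct": normalized_expression(
                    series[s].diffs[rep_idx], d_t, d_nt
                ),
            }
        )
    return pd.DataFrame(rows)
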