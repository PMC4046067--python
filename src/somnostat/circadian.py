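"""Chi-square periodogram period estimation for wheel-running count series.

The statistic folds a 1-min count series at each candidate period P (in
whole bins) over the K complete cycles available and compares the variance
of the P column means with the overall variance:

    Q_P = K * P * Var(column means) / Var(data)

Under the null Q_P is approximately chi-square with P - 1 degrees of
freedom, which provides the per-period significance line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, InsufficientDataError

DEFAULT_PERIOD_RANGE_H = (20.0, 28.0)


@dataclass
class ActivitySeries:
    """1-min binned wheel-revolution counts for one lighting condition."""

    counts: np.ndarray
    condition: str = ""
    light_mw_m2: float = 0.0
    bin_min: int = 1
    start_min: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise InputError("counts must be a 1-D series")
        if np.any(self.counts < 0):
            raise InputError("counts must be >= 0")

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        t = self.start_min + np.arange(len(self)) * self.bin_min
        return pd.DataFrame({"timestamp_min": t, "counts": self.counts})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, **kwargs) -> "ActivitySeries":
        df = pd.read_csv(path)
        return cls(counts=df["counts"].to_numpy(),
                   start_min=int(df["timestamp_min"].iloc[0]), **kwargs)


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    q: np.ndarray
    threshold: np.ndarray
    alpha: float
    peak_period_h: float | None
    peak_significant: bool = False
    no_signal: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"period_h": self.periods_h, "Q": self.q, "threshold": self.threshold}
        )


def chi_square_periodogram(
    series: ActivitySeries | np.ndarray,
    period_range_h=DEFAULT_PERIOD_RANGE_H,
    step_min: int = 1,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Chi-square periodogram over candidate periods in whole 1-min bins.

    Only complete cycles are folded (trailing partial cycles are dropped).
    A zero-variance series yields a no-signal result with an empty peak.
    """
    counts = series.counts if isinstance(series, ActivitySeries) else np.asarray(series)
    counts = counts.astype(float)
    n = len(counts)
    lo_bins = int(round(period_range_h[0] * 60))
    hi_bins = int(round(period_range_h[1] * 60))
    if lo_bins < 2 or hi_bins <= lo_bins:
        raise InputError("invalid period range")
    if n < 2 * hi_bins:
        raise InsufficientDataError(
            f"series of {n} bins is shorter than 2x the max candidate period"
        )
    cand = np.arange(lo_bins, hi_bins + 1, step_min)
    q = np.empty(len(cand))
    thresh = np.empty(len(cand))
    var_all_cache = {}
    degenerate = np.var(counts) == 0
    for i, p in enumerate(cand):
        k = n // p
        x = counts[: k * p]
        var_all = var_all_cache.get(k)
        if var_all is None:
            var_all = np.var(x)  # population variance, ddof=0
            var_all_cache[k] = var_all
        if var_all == 0:
            q[i] = 0.0
        else:
            col_means = x.reshape(k, p).mean(axis=0)
            q[i] = k * p * np.var(col_means) / var_all
        thresh[i] = sps.chi2.ppf(1 - alpha, df=p - 1)
    periods_h = cand / 60.0
    if degenerate:
        return PeriodogramResult(periods_h, q, thresh, alpha,
                                 peak_period_h=None, no_signal=True)
    peak_i = int(np.argmax(q))
    return PeriodogramResult(
        periods_h, q, thresh, alpha,
        peak_period_h=float(periods_h[peak_i]),
        peak_significant=bool(q[peak_i] > thresh[peak_i]),
    )


def period_per_condition(
    series_by_condition, last_days: int = 10, **periodogram_kwargs
) -> pd.DataFrame:
    """Peak period per lighting condition from the trailing ``last_days`` days.

    ``series_by_condition`` maps condition label to :class:`ActivitySeries`.
    """
    rows = []
    for label, series in series_by_condition.items():
        need = last_days * 1440 // series.bin_min
        if len(series) < need:
            raise InsufficientDataError(
                f"condition {label!r} has {len(series)} bins, needs >= {need} "
                f"({last_days} days)"
            )
        tail = ActivitySeries(series.counts[-need:], condition=series.condition,
                              light_mw_m2=series.light_mw_m2, bin_min=series.bin_min)
        res = chi_square_periodogram(tail, **periodogram_kwargs)
        rows.append(
            {
                "condition": label,
                "light_mw_m2": series.light_mw_m2,
                "period_h": res.peak_period_h,
                "significant": res.peak_significant,
            }
        )
    return pd.DataFrame(rows)
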