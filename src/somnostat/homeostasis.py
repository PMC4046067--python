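"""Delta-power dynamics, slow-wave energy and waking-band time courses.

Each 12-h analysis window is divided into a fixed number of intervals to
which an equal number of artifact-free epochs of the analysed state
contribute per subject (NREMS for the delta time course, wakefulness for the
sleep-deprivation band curves).  Delta power is the mean power over the
0.98-3.91 Hz bins; slow-wave energy is delta power summed over epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError, InsufficientDataError
from .spectral import DELTA, NREM, SD_BANDS, WAKE, BandDef, SpectralFrame, band_power
from .vigilance import NREM_INTERVALS, SD_WAKE_INTERVALS, DEFAULT_WINDOWS, Hypnogram

#: ZT-hour range of the per-subject normalization reference
#: (NREMS delta power over the last 4 h of the baseline light period)
REFERENCE_WINDOW = (8, 12)


@dataclass
class IntervalPartition:
    """Equal-epoch partition of one window's qualifying epochs."""

    window: str
    state: str
    epoch_indices: list            # list of int arrays, chronological
    mean_zt_h: np.ndarray          # mean ZT hour of each interval's epochs

    @property
    def n_intervals(self) -> int:
        return len(self.epoch_indices)

    def all_epochs(self) -> np.ndarray:
        return np.concatenate(self.epoch_indices)


@dataclass
class DeltaTimecourse:
    """Per-interval NREMS delta power, raw and as % of the baseline reference."""

    table: pd.DataFrame            # window, interval, mean_zt_h, delta_raw, delta_pct
    reference: float

    def window_values(self, window: str, column: str = "delta_raw") -> np.ndarray:
        sub = self.table[self.table["window"] == window].sort_values("interval")
        return sub[column].to_numpy()


def partition_equal_epochs(
    hyp: Hypnogram, window, state: str, n_intervals: int, window_name: str = ""
) -> IntervalPartition:
    """Split a window's artifact-free epochs of ``state`` into equal groups.

    Epochs are taken in chronological order and divided into ``n_intervals``
    contiguous groups of size floor(m/n) or ceil(m/n); when m is not
    divisible by n the earliest intervals receive the extra epochs.
    """
    if n_intervals < 1:
        raise InputError("n_intervals must be >= 1")
    mask = hyp.window_mask(window) & (hyp.states == state) & ~hyp.artifact
    idx = np.nonzero(mask)[0]
    m = len(idx)
    if m < n_intervals:
        raise InsufficientDataError(
            f"{m} qualifying {state} epochs in {window_name or window}, "
            f"need >= {n_intervals}"
        )
    base, rem = divmod(m, n_intervals)
    sizes = [base + 1] * rem + [base] * (n_intervals - rem)
    bounds = np.cumsum([0] + sizes)
    groups = [idx[bounds[i] : bounds[i + 1]] for i in range(n_intervals)]
    mean_zt = np.array([hyp.zt_hours[g].mean() for g in groups])
    return IntervalPartition(window_name or str(window), state, groups, mean_zt)


def _interval_band_means(frame: SpectralFrame, part: IntervalPartition,
                         band: BandDef) -> np.ndarray:
    return np.array(
        [band_power(frame.power[g], band).mean() for g in part.epoch_indices]
    )


def delta_reference(frame: SpectralFrame, hyp: Hypnogram,
                    window=REFERENCE_WINDOW, band: BandDef = DELTA) -> float:
    """Mean NREMS delta power over the reference window (last 4 h of BSL-L)."""
    mask = hyp.window_mask(window) & (hyp.states == NREM) & ~hyp.artifact
    if not mask.any():
        raise InsufficientDataError("no artifact-free NREMS epoch in the reference window")
    ref = float(band_power(frame.power[mask], band).mean())
    if ref <= 0:
        raise ComputationError("delta normalization reference is not positive")
    return ref


def delta_timecourse(
    frame: SpectralFrame,
    hyp: Hypnogram,
    windows: dict | None = None,
    interval_counts: dict | None = None,
    band: BandDef = DELTA,
) -> DeltaTimecourse:
    """NREMS delta power per equal-epoch interval, normalized to baseline.

    The sleep-deprivation window carries no NREMS analysis and is skipped.
    Normalized values are 100 * raw / reference with the reference taken
    from :func:`delta_reference`.
    """
    windows = dict(DEFAULT_WINDOWS) if windows is None else windows
    interval_counts = dict(NREM_INTERVALS) if interval_counts is None else interval_counts
    ref = delta_reference(frame, hyp, band=band)
    rows = []
    for name, n_iv in interval_counts.items():
        part = partition_equal_epochs(hyp, windows[name], NREM, n_iv, window_name=name)
        means = _interval_band_means(frame, part, band)
        for i, (m, zt) in enumerate(zip(means, part.mean_zt_h), start=1):
            rows.append(
                {"window": name, "interval": i, "mean_zt_h": zt,
                 "delta_raw": m, "delta_pct": 100.0 * m / ref}
            )
    return DeltaTimecourse(pd.DataFrame(rows), reference=ref)


def immediate_rebound(tc: DeltaTimecourse) -> float:
    """Delta rebound: first post-SD interval as % of the last pre-SD interval."""
    pre = tc.window_values("BSL-L")
    post = tc.window_values("Rec-D1")
    if len(pre) == 0 or len(post) == 0:
        raise InsufficientDataError("missing BSL-L or Rec-D1 intervals")
    if pre[-1] <= 0:
        raise ComputationError("pre-SD delta power is not positive")
    return 100.0 * post[0] / pre[-1]


def hourly_delta_energy(frame: SpectralFrame, hyp: Hypnogram,
                        band: BandDef = DELTA) -> pd.Series:
    """Delta power summed over each hour's artifact-free NREMS epochs.

    Hours without NREMS contribute zero energy (not missing).
    """
    if frame.n_epochs != len(hyp):
        raise InputError("frame and hypnogram lengths differ")
    hours = (hyp.zt_seconds // 3600).astype(int)
    mask = (hyp.states == NREM) & ~hyp.artifact
    delta = np.where(mask, band_power(frame.power, band), 0.0)
    full = pd.Series(delta).groupby(hours).sum()
    return full.reindex(range(hours.min(), hours.max() + 1), fill_value=0.0)


def swe_accumulation(frame: SpectralFrame, hyp: Hypnogram,
                     band: BandDef = DELTA, start_h: int = 24) -> pd.DataFrame:
    """Accumulated slow-wave-energy difference from baseline, % of baseline total.

    Hourly NREMS delta energy from ``start_h`` on is differenced against the
    same ZT hour of the baseline day, cumulatively summed, and scaled by
    100 / (total delta energy of the 24-h baseline day).
    """
    energy = hourly_delta_energy(frame, hyp, band)
    baseline = energy.loc[0:23]
    if len(baseline) != 24:
        raise InputError("baseline day is incomplete")
    total = baseline.sum()
    if total <= 0:
        raise ComputationError("baseline delta energy is not positive")
    after = energy.loc[energy.index >= start_h]
    diffs = after.to_numpy() - baseline.loc[after.index % 24].to_numpy()
    return pd.DataFrame(
        {
            "hour": after.index.to_numpy(),
            "delta_energy": after.to_numpy(),
            "baseline_energy": baseline.loc[after.index % 24].to_numpy(),
            "accumulated_pct": 100.0 * np.cumsum(diffs) / total,
        }
    )


def waking_band_timecourse(
    frame: SpectralFrame,
    hyp: Hypnogram,
    bands=SD_BANDS,
    mode: str = "hourly",
    sd_window=(24, 36),
    baseline_window=(0, 12),
    n_intervals: int = SD_WAKE_INTERVALS,
) -> pd.DataFrame:
    """Waking band power during SD as % of baseline-light wakefulness.

    ``mode='hourly'`` averages artifact-free wake epochs per ZT hour;
    ``mode='intervals'`` uses ``n_intervals`` equal-wake-epoch intervals.
    Each band is referenced to its own mean over artifact-free wake epochs
    in the baseline window.
    """
    if mode not in ("hourly", "intervals"):
        raise InputError(f"unknown mode {mode!r}")
    base_mask = hyp.window_mask(baseline_window) & (hyp.states == WAKE) & ~hyp.artifact
    if not base_mask.any():
        raise InsufficientDataError("no artifact-free wake epoch in baseline window")
    rows = []
    for band in bands:
        ref = float(band_power(frame.power[base_mask], band).mean())
        if ref <= 0:
            raise ComputationError(f"baseline wake power in {band.name} is not positive")
        if mode == "intervals":
            part = partition_equal_epochs(hyp, sd_window, WAKE, n_intervals,
                                          window_name="SD-L")
            means = _interval_band_means(frame, part, band)
            for i, (m, zt) in enumerate(zip(means, part.mean_zt_h), start=1):
                rows.append({"band": band.name, "interval": i, "mean_zt_h": zt,
                             "pct_baseline": 100.0 * m / ref})
        else:
            lo_h, hi_h = sd_window
            for i, h in enumerate(range(int(lo_h), int(hi_h)), start=1):
                mask = (hyp.window_mask((h, h + 1)) & (hyp.states == WAKE)
                        & ~hyp.artifact)
                if not mask.any():
                    raise InsufficientDataError(f"no wake epoch in ZT hour {h}")
                m = float(band_power(frame.power[mask], band).mean())
                rows.append({"band": band.name, "interval": i,
                             "mean_zt_h": h + 0.5, "pct_baseline": 100.0 * m / ref})
    return pd.DataFrame(rows)
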