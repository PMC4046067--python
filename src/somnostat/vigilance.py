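"""Vigilance-state time budgets and baseline-referenced accumulated differences.

A hypnogram is a contiguous sequence of 4-s epochs scored W/N/R with an
artifact flag, anchored to zeitgeber time (ZT 0 = light onset).  The 72-h
protocol partitions into six 12-h windows: baseline light/dark, sleep
deprivation in light, and three recovery blocks.

Artifact epochs keep their scored state for time budgets; only spectral
analyses exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .spectral import NREM, REM, STATES, WAKE

log = logging.getLogger(__name__)

EPOCH_S = 4
EPOCHS_PER_HOUR = 3600 // EPOCH_S  # 900

#: the six half-open 12-h protocol windows in ZT hours
DEFAULT_WINDOWS = {
    "BSL-L": (0, 12),
    "BSL-D": (12, 24),
    "SD-L": (24, 36),
    "Rec-D1": (36, 48),
    "Rec-L": (48, 60),
    "Rec-D2": (60, 72),
}

#: windows analysed with NREMS equal-epoch intervals, and their interval counts
NREM_INTERVALS = {"BSL-L": 12, "BSL-D": 5, "Rec-D1": 9, "Rec-L": 11, "Rec-D2": 6}
SD_WAKE_INTERVALS = 36


@dataclass(frozen=True)
class ProtocolWindows:
    """Named half-open ZT-hour intervals partitioning the recording."""

    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))

    def __post_init__(self) -> None:
        edges = sorted(self.windows.values())
        for (a, b) in edges:
            if b <= a:
                raise InputError(f"window ({a}, {b}) is empty or inverted")
        for (_, b1), (a2, _) in zip(edges[:-1], edges[1:]):
            if b1 != a2:
                raise InputError("protocol windows must be contiguous")

    def __getitem__(self, name: str):
        return self.windows[name]

    def items(self):
        return self.windows.items()

    @property
    def span_h(self) -> float:
        edges = sorted(self.windows.values())
        return edges[-1][1] - edges[0][0]


@dataclass
class Hypnogram:
    """Contiguous 4-s-epoch state sequence with artifact flags."""

    zt_seconds: np.ndarray
    states: np.ndarray
    artifact: np.ndarray
    epoch_s: int = EPOCH_S

    def __post_init__(self) -> None:
        self.zt_seconds = np.asarray(self.zt_seconds, dtype=np.int64)
        self.states = np.asarray(self.states, dtype="<U1")
        self.artifact = np.asarray(self.artifact, dtype=bool)
        n = len(self.zt_seconds)
        if len(self.states) != n or len(self.artifact) != n:
            raise InputError("zt_seconds, states and artifact must have equal length")
        if n > 1 and not np.all(np.diff(self.zt_seconds) == self.epoch_s):
            raise InputError(f"epochs must be contiguous with {self.epoch_s}-s spacing")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise InputError(f"invalid states: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def zt_hours(self) -> np.ndarray:
        return self.zt_seconds / 3600.0

    def window_mask(self, window) -> np.ndarray:
        lo_h, hi_h = window
        return (self.zt_hours >= lo_h) & (self.zt_hours < hi_h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(len(self)),
                "zt_seconds": self.zt_seconds,
                "state": self.states,
                "artifact": self.artifact.astype(int),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Hypnogram":
        df = pd.read_csv(path, sep="\t")
        return cls(
            zt_seconds=df["zt_seconds"].to_numpy(),
            states=df["state"].to_numpy(),
            artifact=df["artifact"].to_numpy().astype(bool),
        )


def rems_of_tst(rems_pct: float, nrems_pct: float):
    """REMS as % of total sleep time from REMS and NREMS % of recording time.

    Returns ``None`` when total sleep time is zero (e.g. during enforced
    wakefulness, where the quantity is undefined).
    """
    tst = rems_pct + nrems_pct
    if tst <= 0:
        return None
    return 100.0 * rems_pct / tst


def state_percentages(hyp: Hypnogram, window, bin_h: float = 12) -> pd.DataFrame:
    """Per-bin % of recording time in each state plus REMS/TST.

    ``window`` is a half-open (lo_h, hi_h) ZT interval which must be covered
    by the hypnogram and divide evenly into ``bin_h``-hour bins.  Artifact
    epochs count toward recording time with their scored state.  REMS/TST is
    NaN for bins with zero sleep.
    """
    lo_h, hi_h = window
    span = hi_h - lo_h
    if bin_h > span:
        raise InputError(f"bin_h={bin_h} longer than window span {span}")
    if abs(span / bin_h - round(span / bin_h)) > 1e-9:
        raise InputError(f"bin_h={bin_h} does not evenly divide window span {span}")
    zt_h = hyp.zt_hours
    if zt_h[0] > lo_h or zt_h[-1] + hyp.epoch_s / 3600.0 < hi_h:
        raise InputError("window not covered by hypnogram")
    rows = []
    n_bins = int(round(span / bin_h))
    for b in range(n_bins):
        b_lo = lo_h + b * bin_h
        mask = (zt_h >= b_lo) & (zt_h < b_lo + bin_h)
        total = int(mask.sum())
        pct = {s: 100.0 * np.count_nonzero(hyp.states[mask] == s) / total for s in STATES}
        rows.append(
            {
                "bin_start_h": b_lo,
                "bin_h": bin_h,
                "pct_wake": pct[WAKE],
                "pct_nrems": pct[NREM],
                "pct_rems": pct[REM],
                "rems_tst": rems_of_tst(pct[REM], pct[NREM]),
            }
        )
    df = pd.DataFrame(rows)
    df["rems_tst"] = df["rems_tst"].astype(float)  # None -> NaN
    return df


def minutes_in_state_per_hour(hyp: Hypnogram, state: str) -> pd.Series:
    """Minutes spent in ``state`` for each complete ZT hour of the recording."""
    if state not in STATES:
        raise InputError(f"unknown state {state!r}")
    hours = (hyp.zt_seconds // 3600).astype(int)
    df = pd.DataFrame({"hour": hours, "hit": (hyp.states == state).astype(int)})
    g = df.groupby("hour")["hit"]
    counts, sizes = g.sum(), g.size()
    complete = sizes == EPOCHS_PER_HOUR
    if not complete.all():
        log.warning("excluding %d incomplete hour(s)", int((~complete).sum()))
    return (counts[complete] * hyp.epoch_s / 60.0).rename("minutes")


def accumulated_state_difference(
    hyp: Hypnogram, state: str, baseline_day: int = 0, start_h: int = 24
) -> pd.DataFrame:
    """Hourly accumulated minutes in ``state`` relative to the baseline day.

    For each complete hour from ``start_h`` on, the difference between the
    minutes spent in the state and the minutes at the same ZT hour of the
    baseline day is cumulatively summed.
    """
    minutes = minutes_in_state_per_hour(hyp, state)
    base_lo = baseline_day * 24
    baseline = minutes.loc[(minutes.index >= base_lo) & (minutes.index < base_lo + 24)]
    if len(baseline) != 24:
        raise InputError("baseline day is incomplete")
    after = minutes.loc[minutes.index >= start_h]
    diffs = after.to_numpy() - baseline.loc[base_lo + after.index % 24].to_numpy()
    return pd.DataFrame(
        {
            "hour": after.index.to_numpy(),
            "minutes": after.to_numpy(),
            "baseline_minutes": baseline.loc[base_lo + after.index % 24].to_numpy(),
            "accumulated_min": np.cumsum(diffs),
        }
    )
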