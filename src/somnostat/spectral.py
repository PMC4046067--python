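"""Per-epoch EEG power spectra on the fixed analysis grid.

Epochs are 4 s of signal sampled at 250 Hz (1000 samples), Hann-windowed and
zero-padded to a 1024-point transform, which puts adjacent bins 250/1024 =
0.244 Hz apart.  The analysis grid retains bins 4..196 (0.98-47.85 Hz),
193 bins in total.  All downstream band definitions (delta, upper-theta,
beta-2, gamma-1) live here as :class:`BandDef` instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

SAMPLE_HZ = 250
EPOCH_S = 4
N_FFT = 1024
EPOCH_SAMPLES = SAMPLE_HZ * EPOCH_S  # 1000, zero-padded to N_FFT

#: index range of retained transform bins (inclusive)
BIN_LO = 4
BIN_HI = 196
N_BINS = BIN_HI - BIN_LO + 1  # 193

WAKE, NREM, REM = "W", "N", "R"
STATES = (WAKE, NREM, REM)


def bin_frequency(k):
    """Center frequency (Hz) of transform bin ``k``.

    ``k`` may be a scalar or array; valid indices are 0..512 (one-sided
    spectrum of a 1024-point transform).
    """
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k > N_FFT // 2):
        raise InputError(f"bin index out of range 0..{N_FFT // 2}: {k}")
    out = k * (SAMPLE_HZ / N_FFT)
    return float(out) if out.ndim == 0 else out


#: center frequencies (Hz) of the 193 retained bins
BIN_FREQS = bin_frequency(np.arange(BIN_LO, BIN_HI + 1))


@dataclass(frozen=True)
class BandDef:
    """A frequency band with inclusive bin-center bounds in Hz."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise InputError(f"band {self.name}: lo must be < hi")

    def bins(self, freqs: np.ndarray = BIN_FREQS) -> np.ndarray:
        """Indices (into ``freqs``) whose center lies in [lo, hi].

        Centers are compared after rounding to 2 decimals so that printed
        band edges such as 0.98 Hz select the 0.9766 Hz bin.  Bands
        extending past the retained grid are clipped to it.
        """
        f = np.round(np.asarray(freqs), 2)
        idx = np.nonzero((f >= round(self.lo_hz, 2)) & (f <= round(self.hi_hz, 2)))[0]
        if idx.size == 0:
            raise InputError(f"band {self.name} selects no bins on the grid")
        return idx


DELTA = BandDef("delta", 0.98, 3.91)            # bins 4..16
THETA = BandDef("theta", 5.0, 9.0)              # REM theta search window
UPPER_THETA = BandDef("upper_theta", 8.5, 11.0)
BETA_2 = BandDef("beta_2", 20.0, 35.0)
GAMMA_1 = BandDef("gamma_1", 35.0, 48.0)        # clipped to 47.85 Hz

SD_BANDS = (UPPER_THETA, BETA_2, GAMMA_1)


@dataclass
class SpectralFrame:
    """Epoch x bin power matrix on the retained grid."""

    power: np.ndarray
    bin_freqs: np.ndarray = field(default_factory=lambda: BIN_FREQS.copy())
    sample_hz: int = SAMPLE_HZ
    epoch_s: int = EPOCH_S

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2 or self.power.shape[1] != len(self.bin_freqs):
            raise InputError(
                f"power must be (n_epochs, {len(self.bin_freqs)}), got {self.power.shape}"
            )
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise InputError("power values must be finite and >= 0")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


def epoch_psd(signal: np.ndarray) -> np.ndarray:
    """Squared-magnitude periodogram of one 4-s epoch, retained bins only.

    The 1000-sample epoch is Hann-windowed and zero-padded to 1024 points;
    the returned vector covers bins 4..196 (0.98-47.85 Hz).
    """
    x = np.asarray(signal, dtype=float)
    if x.shape != (EPOCH_SAMPLES,):
        raise InputError(f"epoch must have exactly {EPOCH_SAMPLES} samples, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InputError("epoch contains non-finite samples")
    w = np.hanning(EPOCH_SAMPLES)
    spec = np.fft.rfft(x * w, n=N_FFT)
    p = np.abs(spec) ** 2
    return p[BIN_LO : BIN_HI + 1]


def _select_epochs(hyp, state: str, window=None) -> np.ndarray:
    """Boolean mask of artifact-free epochs of ``state`` (optionally in a ZT window)."""
    mask = (hyp.states == state) & ~hyp.artifact
    if window is not None:
        lo_h, hi_h = window
        zt_h = hyp.zt_seconds / 3600.0
        mask &= (zt_h >= lo_h) & (zt_h < hi_h)
    return mask


def state_spectrum(frame: SpectralFrame, hyp, state: str, window=None):
    """Mean spectrum of a vigilance state, expressed as % of total power.

    Averages power over the artifact-free epochs of ``state`` (within the
    half-open ZT-hour ``window`` if given), then expresses each bin as a
    percentage of the summed power across all retained bins, so the result
    sums to 100.  Returns ``None`` when no qualifying epoch exists.
    """
    if state not in STATES:
        raise InputError(f"unknown state {state!r}")
    if frame.n_epochs != len(hyp.states):
        raise InputError("frame and hypnogram lengths differ")
    mask = _select_epochs(hyp, state, window)
    if not mask.any():
        return None
    mean = frame.power[mask].mean(axis=0)
    total = mean.sum()
    if total <= 0:
        return None
    return 100.0 * mean / total


def band_power(spectrum: np.ndarray, band: BandDef, freqs: np.ndarray = BIN_FREQS):
    """Mean power over the band's bins (last axis of ``spectrum``)."""
    idx = band.bins(freqs)
    return np.asarray(spectrum, dtype=float)[..., idx].mean(axis=-1)


def theta_peak_frequency(rems_spectrum, lo_hz: float = 5.0, hi_hz: float = 9.0,
                         freqs: np.ndarray = BIN_FREQS, global_max: bool = False):
    """REMS theta peak frequency: bin center of maximal power in 5-9 Hz.

    Ties are broken toward the lower frequency.  ``global_max=True`` searches
    the whole grid instead of the theta window.  Returns ``None`` for an
    empty spectrum.
    """
    if rems_spectrum is None:
        return None
    spec = np.asarray(rems_spectrum, dtype=float)
    if spec.size == 0:
        return None
    if global_max:
        idx = np.arange(len(freqs))
    else:
        idx = BandDef("tpf_search", lo_hz, hi_hz).bins(freqs)
    sub = spec[idx]
    return float(freqs[idx[int(np.argmax(sub))]])
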