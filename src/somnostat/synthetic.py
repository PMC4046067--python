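"""Synthetic cohort generator for the full 72-h protocol.

Produces hypnograms (semi-Markov bout model), epoch spectra (state-conditional
templates with a two-process homeostat driving the NREMS delta component),
wheel-running count series with light-dependent free-running periods, and
expression matrices with planted fold changes.  Genotype parameter sets are
calibration values shipped in ``data/default_params.yaml``; identical seeds
give bit-identical outputs.

The homeostatic drive S rises toward its upper asymptote during wakefulness
and decays toward the lower asymptote during sleep:

    awake:  S <- UA - (UA - S) * exp(-dt / tau_rise)
    asleep: S <- LA + (S - LA) * exp(-dt / tau_decay)

When a rebound gain g is configured, the drive of the first post-SD
equal-epoch NREMS interval is pinned to g times the mean drive of the last
pre-SD interval (so the measured immediate rebound recovers 100*g exactly in
the noise-free limit), and S continues its decay from that level.
"""

from __future__ import annotations

import importlib.resources
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .diffexpr import ExpressionMatrix
from .circadian import ActivitySeries
from .errors import ConfigurationError, InputError
from .homeostasis import partition_equal_epochs
from .spectral import (BIN_FREQS, DELTA, NREM, REM, SD_BANDS, WAKE,
                       SpectralFrame)
from .vigilance import Hypnogram, ProtocolWindows

# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class HomeostatParams:
    """Two-process drive: asymptotes and time constants (hours)."""

    lower: float = 0.6
    upper: float = 2.8
    tau_rise_h: float = 8.0
    tau_decay_h: float = 1.5
    s0: float = 1.6

    def __post_init__(self) -> None:
        if self.tau_rise_h <= 0 or self.tau_decay_h <= 0:
            raise ConfigurationError("homeostat time constants must be > 0")
        if not self.lower < self.upper:
            raise ConfigurationError("homeostat needs lower < upper asymptote")


@dataclass(frozen=True)
class SDBandGains:
    """Peak multiplicative gains of the SD waking bands plus ramp shape.

    The gain ramps linearly from 1 to its peak over the first ``onset_h``
    hours of SD and stays at the peak thereafter (immediate, lasting
    increase).
    """

    upper_theta: float = 1.0
    beta_2: float = 1.0
    gamma_1: float = 1.0
    onset_h: float = 0.5

    def peak(self, band_name: str) -> float:
        return {"upper_theta": self.upper_theta, "beta_2": self.beta_2,
                "gamma_1": self.gamma_1}[band_name]


@dataclass
class GenotypeParams:
    """Generator parameters for one genotype (shipped defaults are
    calibration values, not claims)."""

    label: str
    state_occupancy: dict            # window -> (wake, nrems, rems) fractions
    bout_scale: dict                 # window -> (W, N, R) mean bout epochs
    homeostat: HomeostatParams = field(default_factory=HomeostatParams)
    rebound_gain: float | None = None
    sd_band_gains: SDBandGains = field(default_factory=SDBandGains)
    tpf_hz: float = 7.08
    artifact_rate: float = 0.03
    icc_fraction: float = 0.48
    period_hr: float = 23.7
    light_slope: float = 0.12
    dark_delta_pct: float | None = None

    def __post_init__(self) -> None:
        occ = {}
        for win, frac in self.state_occupancy.items():
            frac = np.asarray(frac, dtype=float)
            if frac.shape != (3,) or np.any(frac < 0):
                raise ConfigurationError(
                    f"{self.label}/{win}: occupancy must be 3 nonnegative fractions")
            s = frac.sum()
            if abs(s - 1.0) > 0.02:
                raise ConfigurationError(
                    f"{self.label}/{win}: occupancy sums to {s:.4f}, not 1")
            occ[win] = tuple(frac / s)
        self.state_occupancy = occ
        if not 0 <= self.artifact_rate < 1:
            raise ConfigurationError("artifact_rate must be in [0, 1)")
        if not 0 <= self.icc_fraction <= 1:
            raise ConfigurationError("icc_fraction must be in [0, 1]")
        if not 20 <= self.period_hr <= 28:
            raise ConfigurationError("period_hr must be in [20, 28] h")


@dataclass
class SimConfig:
    """Cohort-level simulation settings; the seed determines all outputs."""

    seed: int = 0
    n_subjects_per_genotype: int = 8
    protocol: ProtocolWindows = field(default_factory=ProtocolWindows)
    epoch_s: int = 4
    sample_hz: int = 250            # metadata only; spectra are synthesized
    bin_freqs: np.ndarray = field(default_factory=lambda: BIN_FREQS.copy())
    noise_sigma: float = 0.15       # lognormal sigma of per-bin noise

    @property
    def n_epochs(self) -> int:
        return int(self.protocol.span_h * 3600 / self.epoch_s)


def _subject_key(subject_id) -> int:
    if isinstance(subject_id, (int, np.integer)):
        return int(subject_id)
    return zlib.crc32(str(subject_id).encode())


def _rng(config: SimConfig, subject_id, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, _subject_key(subject_id), stream])


# ---------------------------------------------------------------------------
# hypnogram

SD_WINDOW_NAME = "SD-L"
SD_NREM_CAP = 0.02


def _transition_probs(p, bouts):
    """Semi-Markov transition probabilities hitting the target occupancy.

    Visit rates are v = p / L.  The wake visit rate is clamped into its
    feasible range (every wake bout is entered from N or R and R is entered
    only from N); the wake bout scale absorbs the adjustment so the time
    shares stay at their targets.
    """
    p_w, p_n, p_r = p
    l_w, l_n, l_r = (float(b) for b in bouts)
    if p_n == 0 and p_r > 0:
        raise ConfigurationError("REMS requires NREMS (R is entered only from N)")
    if p_n == 0:
        return {"L": (l_w, l_n, l_r), "q": 0.0, "r": 0.0}
    v_n = p_n / l_n
    v_r = p_r / l_r if p_r > 0 else 0.0
    v_w = p_w / l_w if p_w > 0 else 0.0
    if p_w > 0:
        v_w = float(np.clip(v_w, max(v_n - v_r, 1e-12), v_n))
        l_w = p_w / v_w
    q = float(np.clip(v_r / v_n, 0.0, 1.0))
    r = float(np.clip((v_w - v_n + v_r) / v_r, 0.0, 1.0)) if v_r > 0 else 0.0
    return {"L": (l_w, l_n, l_r), "q": q, "r": r}


def _bout_length(rng, mean: float) -> int:
    return int(rng.geometric(min(1.0, 1.0 / max(mean, 1.0))))


def _simulate_window_states(rng, n_ep: int, p, bouts, start_state: str) -> np.ndarray:
    p_w, p_n, p_r = p
    if p_n == 0 and p_r == 0:
        return np.full(n_ep, WAKE, dtype="<U1")
    tp = _transition_probs(p, bouts)
    l_w, l_n, l_r = tp["L"]
    means = {WAKE: l_w, NREM: l_n, REM: l_r}
    out = np.empty(n_ep, dtype="<U1")
    filled = 0
    state = start_state
    while filled < n_ep:
        length = min(_bout_length(rng, means[state]), n_ep - filled)
        out[filled : filled + length] = state
        filled += length
        if state == WAKE:
            state = NREM
        elif state == NREM:
            state = REM if (p_r > 0 and rng.random() < tp["q"]) else WAKE
        else:  # REM
            state = WAKE if rng.random() < tp["r"] else NREM
    return out


def simulate_hypnogram(params: GenotypeParams, config: SimConfig,
                       subject_id=0) -> Hypnogram:
    """Semi-Markov 72-h hypnogram honoring the configured occupancies.

    During the sleep-deprivation window only wakefulness occurs apart from a
    small NREMS leak (capped at 2 % of the window, no REMS); everywhere else
    REMS is entered only from NREMS.
    """
    rng = _rng(config, subject_id, 0)
    windows = sorted(config.protocol.items(), key=lambda kv: kv[1][0])
    states = np.empty(config.n_epochs, dtype="<U1")
    pos = 0
    prev_state = None
    for name, (lo_h, hi_h) in windows:
        if name not in params.state_occupancy:
            raise ConfigurationError(f"{params.label}: no occupancy for window {name}")
        n_ep = int(round((hi_h - lo_h) * 3600 / config.epoch_s))
        p = params.state_occupancy[name]
        if name == SD_WINDOW_NAME:
            block = np.full(n_ep, WAKE, dtype="<U1")
            cap = int(SD_NREM_CAP * n_ep)
            n_leak = min(int(rng.binomial(n_ep, p[1])), cap)
            if n_leak:
                block[rng.choice(n_ep, size=n_leak, replace=False)] = NREM
        else:
            if pos == 0:
                start = rng.choice(np.array([WAKE, NREM, REM]), p=np.asarray(p))
            elif prev_state == SD_WINDOW_NAME:
                start = NREM  # sleep onset after enforced wakefulness
            else:
                start = states[pos - 1]
            if start == REM and pos > 0 and states[pos - 1] == WAKE:
                start = NREM
            bouts = params.bout_scale.get(name)
            if bouts is None:
                raise ConfigurationError(f"{params.label}: no bout scale for {name}")
            block = _simulate_window_states(rng, n_ep, p, bouts, start)
        states[pos : pos + n_ep] = block
        pos += n_ep
        prev_state = SD_WINDOW_NAME if name == SD_WINDOW_NAME else None
    art_rng = _rng(config, subject_id, 1)
    artifact = art_rng.random(config.n_epochs) < params.artifact_rate
    zt = np.arange(config.n_epochs, dtype=np.int64) * config.epoch_s
    return Hypnogram(zt_seconds=zt, states=states, artifact=artifact,
                     epoch_s=config.epoch_s)


# ---------------------------------------------------------------------------
# spectra

_BG_SCALE = 60.0
_BG_KNEE_HZ = 4.0
_BG_FLOOR = 1.0
_DELTA_SCALE = 80.0
_DELTA_MU_HZ = 2.2
_DELTA_SD_HZ = 1.3
_THETA_AMP = 70.0
_THETA_SD_HZ = 0.35


def _background(freqs: np.ndarray) -> np.ndarray:
    return _BG_SCALE / (1.0 + (freqs / _BG_KNEE_HZ) ** 2) + _BG_FLOOR


def homeostat_trajectory(states: np.ndarray, hp: HomeostatParams,
                         epoch_s: int = 4, s0: float | None = None) -> np.ndarray:
    """Per-epoch homeostatic drive S for a state sequence."""
    a_r = np.exp(-epoch_s / (hp.tau_rise_h * 3600.0))
    a_d = np.exp(-epoch_s / (hp.tau_decay_h * 3600.0))
    s = hp.s0 if s0 is None else s0
    out = np.empty(len(states))
    awake = states == WAKE
    for i in range(len(states)):
        if awake[i]:
            s = hp.upper - (hp.upper - s) * a_r
        else:
            s = hp.lower + (s - hp.lower) * a_d
        out[i] = s
    return out


def _delta_drive(hyp: Hypnogram, params: GenotypeParams,
                 protocol: ProtocolWindows) -> np.ndarray:
    """Homeostat drive with the rebound pin and dark-delta calibration applied."""
    s = homeostat_trajectory(hyp.states, params.homeostat, epoch_s=hyp.epoch_s)
    drive = s.copy()
    windows = dict(protocol.items())
    if params.rebound_gain is not None:
        pre = partition_equal_epochs(hyp, windows["BSL-L"], NREM, 12, "BSL-L")
        post = partition_equal_epochs(hyp, windows["Rec-D1"], NREM, 9, "Rec-D1")
        m0 = float(s[pre.epoch_indices[-1]].mean())
        first = post.epoch_indices[0]
        pinned = params.rebound_gain * m0
        drive[first] = pinned
        # resume the decay dynamics from the pinned level
        resume = int(first[-1]) + 1
        if resume < len(s):
            cont = homeostat_trajectory(hyp.states[resume:], params.homeostat,
                                        epoch_s=hyp.epoch_s, s0=pinned)
            drive[resume:] = cont
    if params.dark_delta_pct is not None:
        free = (hyp.states == NREM) & ~hyp.artifact
        light = free & hyp.window_mask(windows["BSL-L"])
        dark = free & hyp.window_mask(windows["BSL-D"])
        if light.any() and dark.any():
            ratio = drive[dark].mean() / drive[light].mean()
            factor = (params.dark_delta_pct / 100.0) / ratio
            drive[(hyp.states == NREM) & hyp.window_mask(windows["BSL-D"])] *= factor
    return drive


def simulate_spectra(hyp: Hypnogram, params: GenotypeParams, config: SimConfig,
                     subject_id=0, noise_sigma: float | None = None) -> SpectralFrame:
    """State-conditional epoch spectra on the retained grid.

    NREMS epochs carry a delta component proportional to the homeostatic
    drive; REMS epochs a theta peak at the configured frequency; wake epochs
    during SD get the time-profiled band gains.  Multiplicative lognormal
    noise is applied to every bin (sigma from the config unless overridden).
    """
    if len(hyp) != config.n_epochs:
        raise InputError("hypnogram length does not match the protocol")
    sigma = config.noise_sigma if noise_sigma is None else noise_sigma
    freqs = config.bin_freqs
    n_ep, n_bins = len(hyp), len(freqs)
    power = np.tile(_background(freqs), (n_ep, 1))

    # NREMS: delta bins replaced by drive-scaled profile
    delta_idx = DELTA.bins(freqs)
    delta_profile = _DELTA_SCALE * np.exp(
        -((freqs[delta_idx] - _DELTA_MU_HZ) ** 2) / (2 * _DELTA_SD_HZ**2))
    drive = _delta_drive(hyp, params, config.protocol)
    nrem = hyp.states == NREM
    power[np.ix_(nrem, delta_idx)] = drive[nrem, None] * delta_profile[None, :]

    # REMS: additive theta peak
    rem = hyp.states == REM
    theta_bump = _THETA_AMP * np.exp(
        -((freqs - params.tpf_hz) ** 2) / (2 * _THETA_SD_HZ**2))
    power[rem] += theta_bump[None, :]

    # SD wake epochs: ramped band gains
    sd_window = dict(config.protocol.items())[SD_WINDOW_NAME]
    sd_wake = (hyp.states == WAKE) & hyp.window_mask(sd_window)
    if sd_wake.any():
        u_h = hyp.zt_hours[sd_wake] - sd_window[0]
        ramp = (np.clip(u_h / params.sd_band_gains.onset_h, 0.0, 1.0)
                if params.sd_band_gains.onset_h > 0 else np.ones_like(u_h))
        for band in SD_BANDS:
            peak = params.sd_band_gains.peak(band.name)
            gain = 1.0 + (peak - 1.0) * ramp
            idx = band.bins(freqs)
            power[np.ix_(sd_wake, idx)] *= gain[:, None]

    if sigma > 0:
        rng = _rng(config, subject_id, 2)
        power *= np.exp(rng.normal(0.0, sigma, size=(n_ep, n_bins)))
    return SpectralFrame(power=power, bin_freqs=freqs,
                         sample_hz=config.sample_hz, epoch_s=config.epoch_s)


# ---------------------------------------------------------------------------
# wheel-running activity


def free_running_period_h(params: GenotypeParams, intensity_mw_m2: float) -> float:
    """Constant-condition period: base period plus the light-dependent increment."""
    return params.period_hr + params.light_slope * np.log1p(intensity_mw_m2)


def simulate_activity(params: GenotypeParams, light_schedule, seed: int = 0,
                      amplitude: float = 20.0, baseline: float = 0.5,
                      poisson: bool = True) -> list:
    """1-min wheel counts for a sequence of constant-light blocks.

    ``light_schedule`` is a sequence of (intensity_mw_m2, days) pairs (or
    dicts with those keys plus an optional label).  Counts are Poisson around
    a square activity profile: active during the subjective night half of
    each cycle.  With ``poisson=False`` the rounded deterministic profile is
    returned.
    """
    rng = np.random.default_rng(seed)
    out = []
    t0_min = 0
    for i, block in enumerate(light_schedule):
        if isinstance(block, dict):
            intensity, days = block["intensity"], block["days"]
            label = block.get("label", f"block{i}")
        else:
            intensity, days = block
            label = f"block{i}"
        if days <= 0:
            raise InputError("block duration must be positive")
        n_min = int(round(days * 1440))
        period_h = free_running_period_h(params, intensity)
        phase = ((t0_min + np.arange(n_min)) / 60.0) % period_h
        rate = np.where(phase >= period_h / 2, baseline + amplitude, baseline)
        counts = rng.poisson(rate) if poisson else np.round(rate).astype(int)
        out.append(ActivitySeries(counts=counts, condition=label,
                                  light_mw_m2=float(intensity),
                                  start_min=t0_min))
        t0_min += n_min
    return out


# ---------------------------------------------------------------------------
# expression matrices and grouped values


def simulate_expression(n_genes: int, n_per_group: int, de_fraction: float,
                        fc_log2: float, seed: int = 0, up_fraction: float = 2 / 3,
                        baseline_mean: float = 8.0, baseline_sd: float = 1.5,
                        noise_sd: float = 0.5, array_offset_sd: float = 0.7,
                        tissue: str = "") -> ExpressionMatrix:
    """Two-group log2 expression matrix with planted fold changes.

    A ``de_fraction`` of genes is shifted by +/- ``fc_log2`` in the first
    group (a majority up-regulated), and every array receives a scaling
    offset so percentile-shift normalization is nontrivial.  Truth labels
    are recorded on the returned matrix.
    """
    if not 0 <= de_fraction <= 1:
        raise InputError("de_fraction must be in [0, 1]")
    if n_per_group < 2:
        raise InputError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    n_samples = 2 * n_per_group
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    n_de = int(round(de_fraction * n_genes))
    n_up = int(round(up_fraction * n_de))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    up_idx, down_idx = de_idx[:n_up], de_idx[n_up:]
    vals[up_idx, :n_per_group] += fc_log2
    vals[down_idx, :n_per_group] -= fc_log2
    vals += rng.normal(0.0, array_offset_sd, size=n_samples)[None, :]
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    samples = [f"g1_s{i}" for i in range(n_per_group)] + \
              [f"g2_s{i}" for i in range(n_per_group)]
    groups = pd.Series(["g1"] * n_per_group + ["g2"] * n_per_group, index=samples)
    truth = pd.DataFrame({"de": False, "direction": ""},
                         index=pd.Index(genes, name="gene"))
    truth.iloc[up_idx, 0] = True
    truth.iloc[up_idx, 1] = "up"
    truth.iloc[down_idx, 0] = True
    truth.iloc[down_idx, 1] = "down"
    values = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(values=values, groups=groups, tissue=tissue, truth=truth)


def simulate_grouped_values(icc_fraction: float, n_per_group: int = 8,
                            n_groups: int = 2, seed: int = 0,
                            scale: float = 1.0, center: float = 0.0) -> list:
    """Grouped values whose variance decomposition matches ``icc_fraction``.

    Fixed, exactly realized group means are combined with mean-centered
    within-group noise; the mean separation is chosen so the plug-in
    one-way decomposition (expected between mean square at the given group
    count and size) reproduces the configured between-group variance share.
    """
    if not 0 <= icc_fraction <= 1:
        raise InputError("icc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    e = np.arange(n_groups) - (n_groups - 1) / 2.0
    if icc_fraction == 1.0:
        sw = 0.0
        mu = e  # any distinct means give ICC 1 with zero within-variance
    else:
        sw = 1.0 - icc_fraction
        sb = icc_fraction * sw / (1.0 - icc_fraction)
        target_msb = n_per_group * sb + sw
        var1 = float(np.var(e, ddof=1))
        mu = e * np.sqrt(target_msb / (n_per_group * var1))
    groups = []
    for i in range(n_groups):
        g = rng.normal(0.0, np.sqrt(sw), size=n_per_group) if sw > 0 else \
            np.zeros(n_per_group)
        g = g - g.mean() + mu[i]
        groups.append(center + scale * g)
    return groups


# ---------------------------------------------------------------------------
# shipped genotype defaults


def default_genotypes() -> dict:
    """Load the shipped genotype calibration parameter sets."""
    ref = importlib.resources.files("somnostat").joinpath("data/default_params.yaml")
    raw = yaml.safe_load(ref.read_text())
    out = {}
    for label, d in raw["genotypes"].items():
        out[label] = genotype_from_dict(label, d)
    return out


def genotype_from_dict(label: str, d: dict) -> GenotypeParams:
    return GenotypeParams(
        label=label,
        state_occupancy={k: tuple(v) for k, v in d["state_occupancy"].items()},
        bout_scale={k: tuple(v) for k, v in d["bout_scale"].items()},
        homeostat=HomeostatParams(**d.get("homeostat", {})),
        rebound_gain=d.get("rebound_gain"),
        sd_band_gains=SDBandGains(**d.get("sd_band_gains", {})),
        tpf_hz=d.get("tpf_hz", 7.08),
        artifact_rate=d.get("artifact_rate", 0.03),
        icc_fraction=d.get("icc_fraction", 0.48),
        period_hr=d.get("period_hr", 23.7),
        light_slope=d.get("light_slope", 0.12),
        dark_delta_pct=d.get("dark_delta_pct"),
    )


def genotype_to_dict(p: GenotypeParams) -> dict:
    d = asdict(p)
    d["state_occupancy"] = {k: list(v) for k, v in p.state_occupancy.items()}
    d["bout_scale"] = {k: list(v) for k, v in p.bout_scale.items()}
    return d
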