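"""End-to-end run orchestration: config loading, stage sequencing, manifests.

A run directory holds tidy long-format tables for every stage plus a
``manifest.json`` recording the seed, a canonical config hash and package
versions, so identical configs produce identical runs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .errors import ConfigurationError, InsufficientDataError
from .homeostasis import (delta_timecourse, immediate_rebound, swe_accumulation,
                          waking_band_timecourse)
from .io import canonical_json, write_json
from .spectral import BIN_FREQS, REM, state_spectrum
from .stats import icc_between_groups, paired_return_to_baseline, per_bin_kruskal_wallis
from .synthetic import (SimConfig, default_genotypes, genotype_from_dict,
                        genotype_to_dict, simulate_expression, simulate_hypnogram,
                        simulate_spectra)
from .diffexpr import classify_de, fold_change_ranking, percentile_shift_normalize
from .vigilance import (DEFAULT_WINDOWS, ProtocolWindows, accumulated_state_difference,
                        state_percentages)

log = logging.getLogger(__name__)

REQUIRED_WINDOWS = tuple(DEFAULT_WINDOWS)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    n_subjects_per_genotype: int = 8
    noise_sigma: float = 0.15
    genotypes: dict = field(default_factory=default_genotypes)
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    alpha: float = 0.05
    pfp_threshold: float = 0.015
    n_perm: int = 100
    top_n: int = 200
    expression: dict | None = None  # {n_genes, de_fraction, fc_log2}

    def __post_init__(self) -> None:
        for name in REQUIRED_WINDOWS:
            if name not in self.windows:
                raise ConfigurationError(f"protocol.windows missing field {name!r}")
        self.protocol = ProtocolWindows(dict(self.windows))
        if self.n_subjects_per_genotype < 1:
            raise ConfigurationError("n_subjects_per_genotype must be >= 1")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects_per_genotype": self.n_subjects_per_genotype,
            "noise_sigma": self.noise_sigma,
            "genotypes": {k: genotype_to_dict(v) for k, v in self.genotypes.items()},
            "windows": {k: list(v) for k, v in self.windows.items()},
            "alpha": self.alpha,
            "pfp_threshold": self.pfp_threshold,
            "n_perm": self.n_perm,
            "top_n": self.top_n,
            "expression": self.expression,
        }


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("seed", "n_subjects_per_genotype", "noise_sigma", "alpha",
                "pfp_threshold", "n_perm", "top_n", "expression"):
        if key in raw:
            kwargs[key] = raw[key]
    if "windows" in raw:
        kwargs["windows"] = {k: tuple(v) for k, v in raw["windows"].items()}
    geno = raw.get("genotypes", "default")
    if geno == "default":
        kwargs["genotypes"] = default_genotypes()
    else:
        kwargs["genotypes"] = {k: genotype_from_dict(k, d) for k, d in geno.items()}
    return RunConfig(**kwargs)


def _subject_index(g: int, s: int) -> int:
    return 1000 * g + s


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Simulate every cohort and run all analysis stages into a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(seed=config.seed,
                    n_subjects_per_genotype=config.n_subjects_per_genotype,
                    protocol=config.protocol, noise_sigma=config.noise_sigma)
    vig12, vig2, accum = [], [], []
    delta_rows, rebound_rows, swe_rows, band_rows = [], [], [], []
    rems_spectra: dict[str, list] = {}
    final_swe: dict[str, list] = {}
    skipped = []
    timings = {}
    for g, (label, params) in enumerate(config.genotypes.items()):
        t0 = time.perf_counter()
        rems_spectra[label] = []
        final_swe[label] = []
        for s in range(config.n_subjects_per_genotype):
            sid = _subject_index(g, s)
            hyp = simulate_hypnogram(params, sim, subject_id=sid)
            frame = simulate_spectra(hyp, params, sim, subject_id=sid)
            meta = {"genotype": label, "subject": s}
            for name, win in config.protocol.items():
                df = state_percentages(hyp, win, bin_h=12).assign(window=name, **meta)
                vig12.append(df)
                df2 = state_percentages(hyp, win, bin_h=2).assign(window=name, **meta)
                vig2.append(df2)
            for state in ("N", "R"):
                adf = accumulated_state_difference(hyp, state).assign(state=state, **meta)
                accum.append(adf)
            try:
                tc = delta_timecourse(frame, hyp, windows=config.windows)
                delta_rows.append(tc.table.assign(**meta))
                rebound_rows.append({**meta, "rebound_pct": immediate_rebound(tc)})
            except InsufficientDataError as exc:
                skipped.append({**meta, "stage": "delta_timecourse", "reason": str(exc)})
            swe = swe_accumulation(frame, hyp)
            swe_rows.append(swe.assign(**meta))
            final_swe[label].append(float(swe["accumulated_pct"].iloc[-1]))
            try:
                wb = waking_band_timecourse(frame, hyp, mode="hourly")
                band_rows.append(wb.assign(**meta))
            except InsufficientDataError as exc:
                skipped.append({**meta, "stage": "waking_bands", "reason": str(exc)})
            spec = state_spectrum(frame, hyp, REM, window=config.windows["BSL-L"])
            if spec is not None:
                rems_spectra[label].append(spec)
        timings[label] = round(time.perf_counter() - t0, 3)

    tables = {
        "vigilance_12h.tsv": pd.concat(vig12, ignore_index=True),
        "vigilance_2h.tsv": pd.concat(vig2, ignore_index=True),
        "accumulated_states.tsv": pd.concat(accum, ignore_index=True),
        "delta_timecourse.tsv": pd.concat(delta_rows, ignore_index=True),
        "rebound.tsv": pd.DataFrame(rebound_rows),
        "swe.tsv": pd.concat(swe_rows, ignore_index=True),
        "waking_bands.tsv": pd.concat(band_rows, ignore_index=True),
    }

    # group statistics on the per-subject summaries
    spectra_by_group = {k: np.array(v) for k, v in rems_spectra.items() if v}
    if len(spectra_by_group) >= 2 and all(len(v) >= 2 for v in spectra_by_group.values()):
        tables["kw_per_bin.tsv"] = per_bin_kruskal_wallis(spectra_by_group, BIN_FREQS)
        labels = list(spectra_by_group)[-2:]
        icc_rows = []
        for j, f in enumerate(BIN_FREQS):
            res = icc_between_groups([spectra_by_group[l][:, j] for l in labels])
            icc_rows.append({"freq_hz": float(f), "icc": res.icc,
                             "ci_low": res.ci_low, "ci_high": res.ci_high})
        tables["icc_per_bin.tsv"] = pd.DataFrame(icc_rows)
    ret_rows = []
    for label, vals in final_swe.items():
        if len(vals) >= 2:
            try:
                t, p = paired_return_to_baseline(vals)
                ret_rows.append({"genotype": label, "n": len(vals),
                                 "mean_final_pct": float(np.mean(vals)), "t": t, "p": p})
            except Exception as exc:  # degenerate cohorts logged, not fatal
                skipped.append({"genotype": label, "stage": "swe_return",
                                "reason": str(exc)})
    if ret_rows:
        tables["swe_return.tsv"] = pd.DataFrame(ret_rows)

    if config.expression:
        expr = simulate_expression(seed=config.seed,
                                   n_per_group=config.n_subjects_per_genotype,
                                   **config.expression)
        norm = percentile_shift_normalize(expr)
        res, summary = classify_de(norm, alpha=config.alpha,
                                   pfp_threshold=config.pfp_threshold,
                                   n_perm=config.n_perm, seed=config.seed)
        tables["diffexpr.tsv"] = res.reset_index()
        tables["diffexpr_top.tsv"] = fold_change_ranking(res, config.top_n).reset_index()
        tables["diffexpr_summary.tsv"] = pd.DataFrame(
            [{"contrast": "-".join(summary.contrast), "n_de": summary.n_de,
              "n_up": summary.n_up, "n_down": summary.n_down}])

    for name, df in tables.items():
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.8g")
    cfg = config.to_dict()
    manifest = {
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(canonical_json(cfg).encode()).hexdigest(),
        "versions": {"somnostat": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "tables": {name: len(df) for name, df in tables.items()},
        "skipped": skipped,
    }
    write_json(manifest, outdir / "manifest.json")
    for label, dt in timings.items():
        log.info("stage timing: genotype %s simulated+analysed in %.3fs", label, dt)
    return outdir
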