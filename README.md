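# somnostat

Sleep-homeostasis, circadian and expression analytics for epoch-scored
rodent EEG protocols, with a matched synthetic-data generator so every
analysis stage is verifiable end to end without animal recordings.

The pipeline covers a 72-h protocol (24 h baseline, 12 h sleep deprivation
in light, 36 h recovery) scored in 4-s epochs:

- **`spectral`** — per-epoch power spectra on the fixed 0.98–47.85 Hz grid
  (1024-point transform of 4-s / 250-Hz epochs, Hann window, 0.244-Hz bins),
  state-conditional normalized spectra, band powers (δ, upper-θ, β-2, γ-1)
  and REMS θ-peak frequency.
- **`vigilance`** — W/N/R time budgets per 2-h or 12-h bin, REMS as % of
  total sleep time, and hourly accumulated state differences from baseline.
- **`homeostasis`** — equal-epoch interval partitions per 12-h window
  (12/5/9/11/6 NREMS intervals; 36 wake intervals during SD), the normalized
  NREMS δ-power time course, immediate post-SD δ rebound, slow-wave-energy
  accumulation, and waking-band time courses during SD.
- **`circadian`** — χ² periodogram of 1-min wheel-running series with
  per-period significance lines, and trailing-10-day period estimates per
  constant-light condition.
- **`stats`** — one-way random-effects ICC with F-pivot CI, per-bin
  Kruskal–Wallis tests, rank-based SNK stepwise post hoc, and the paired
  return-to-baseline t test.
- **`diffexpr`** — 75th-percentile shift normalization, dual-criterion
  differential expression (BH-adjusted t/ANOVA **and/or** rank-product
  PFP < 0.015), and |fold-change| top-N ranking.
- **`synthetic`** — genotype-parameterized generator for hypnograms
  (semi-Markov bouts, R entered only from N, enforced wakefulness with a
  ≤2 % NREMS leak during SD), epoch spectra driven by a two-process
  homeostat, free-running wheel activity, grouped values with a configured
  ICC fraction, and expression matrices with planted fold changes.
  Shipped defaults live in `src/somnostat/data/default_params.yaml` and are
  calibration values.
- **`pipeline` / `cli`** — YAML-configured end-to-end runs with
  deterministic manifests.

## CLI

```sh
somnostat simulate --genotype genotype_a --seed 1 --subjects 2 --out runs/sim
somnostat vigilance --hypnogram runs/sim/genotype_a_s0_hypnogram.tsv
somnostat periodogram --activity runs/sim/genotype_a_activity_0mw.csv
somnostat run-all --seed 1 --out runs/full        # full default pipeline
somnostat run-all --config myrun.yaml --out runs/custom
```

`simulate --spectra` additionally writes the (large) epoch × bin spectra
TSVs consumed by `somnostat spectra` and `somnostat homeostasis`.
All tabular outputs are tidy TSV; each run directory contains a
`manifest.json` with the seed, a canonical config hash and library
versions — identical configs yield byte-identical runs.

EDF ingestion is not included; hypnograms and spectra enter as the
documented plain-text containers (`Hypnogram.read_tsv`,
`somnostat.io.read_spectra_tsv`).

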