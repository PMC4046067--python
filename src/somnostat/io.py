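"""Plain-text readers/writers for the pipeline's data containers.

Hypnograms and expression matrices carry their own read/write methods; this
module adds the epoch x bin spectra container (TSV with a bin-frequency
header row) and small JSON sidecar helpers.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .errors import InputError
from .spectral import SpectralFrame


def write_spectra_tsv(frame: SpectralFrame, path) -> None:
    """Write an epoch x bin power matrix; columns are bin center frequencies."""
    cols = [f"f{f:.4f}" for f in frame.bin_freqs]
    df = pd.DataFrame(frame.power, columns=cols)
    df.insert(0, "epoch_index", np.arange(frame.n_epochs))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_spectra_tsv(path) -> SpectralFrame:
    df = pd.read_csv(path, sep="\t")
    fcols = [c for c in df.columns if c.startswith("f")]
    if not fcols:
        raise InputError(f"{path}: no frequency columns found")
    freqs = np.array([float(c[1:]) for c in fcols])
    return SpectralFrame(power=df[fcols].to_numpy(), bin_freqs=freqs)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), cls=_NumpyEncoder)
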