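"""Plain-text artifact I/O: feature-series CSV with JSON sidecars.

A feature series serializes as a two-column CSV (``frame_index,value``,
NaN sentinels written as ``nan``) next to a ``<stem>.meta.json`` sidecar
carrying the name, units, and the provenance needed to trace the file
back to a run (rate, window, hop, config hash, seed).
"""

from __future__ import annotations

import json
import os

import numpy as np

from .features import FeatureSeries

__all__ = ["write_series", "read_series"]


def write_series(path, series: FeatureSeries, provenance: dict | None = None) -> None:
    values = series.values
    with open(path, "w") as fh:
        fh.write("frame_index,value\n")
        for i, v in enumerate(values):
            fh.write(f"{i},{float(v)!r}\n")  # repr: round-trips full precision
    sidecar = {
        "name": series.name,
        "units": series.units,
        "length": int(values.size),
        **(series.meta or {}),
        **(provenance or {}),
    }
    stem, _ = os.path.splitext(str(path))
    with open(stem + ".meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_series(path) -> FeatureSeries:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    values = data[:, 1] if data.ndim == 2 else np.atleast_1d(data)[1:]
    stem, _ = os.path.splitext(str(path))
    meta_path = stem + ".meta.json"
    name, units, meta = "pitch", "", {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
        name = meta.pop("name", name)
        units = meta.pop("units", units)
    return FeatureSeries(name, values, units, meta)
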