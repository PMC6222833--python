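"""Readers and writers for the package's plain-text interchange formats.

All tabular files are whitespace- or comma-delimited text; lines starting with
``#`` are comments. A *run manifest* (YAML) ties a window table to one sample
file per window and records temperature and generator provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import Grid2D, SampleSet, Surface2D, WindowSpec


def _read_table(path, names) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None, skipinitialspace=True)
    first = df.iloc[0].astype(str).str.strip().tolist()
    if first[: len(names)] == list(names)[: len(first)] or first[0] == names[0]:
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, : len(names)] if df.shape[1] >= len(names) else df
    df.columns = list(names)[: df.shape[1]]
    return df.apply(pd.to_numeric)


def read_window_table(path) -> list[WindowSpec]:
    """Read windows from a delimited file with columns index, center1, center2, k1, k2."""
    df = _read_table(path, ["index", "center1", "center2", "k1", "k2"])
    return [
        WindowSpec(int(r.index), (float(r.center1), float(r.center2)), (float(r.k1), float(r.k2)))
        for r in df.itertuples()
    ]


def write_window_table(path, windows: Sequence[WindowSpec]) -> None:
    with open(path, "w") as fh:
        fh.write("# index center1 center2 k1 k2\n")
        for w in windows:
            fh.write(f"{w.index} {w.center[0]:.6g} {w.center[1]:.6g} "
                     f"{w.force_constants[0]:.6g} {w.force_constants[1]:.6g}\n")


def read_samples_file(path, window_index: int):
    """Read one window's frames: columns frame, eta1, eta2, u_low [, u_high].

    Returns (window_index array, rc array, u_low array, u_high array or None).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    ncol = df.shape[1]
    if ncol < 4:
        raise ValueError(f"{path}: expected >= 4 columns (frame, eta1, eta2, u_low)")
    names = ["frame", "eta1", "eta2", "u_low"] + (["u_high"] if ncol >= 5 else [])
    df = df.iloc[:, : len(names)]
    df.columns = names
    if isinstance(df["frame"].iloc[0], str):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.apply(pd.to_numeric)
    n = len(df)
    rc = df[["eta1", "eta2"]].to_numpy(float)
    u_low = df["u_low"].to_numpy(float)
    u_high = df["u_high"].to_numpy(float) if "u_high" in df else None
    return np.full(n, window_index, dtype=np.int64), rc, u_low, u_high


def write_samples_file(path, rc, u_low, u_high=None) -> None:
    cols = "# frame eta1 eta2 u_low" + (" u_high" if u_high is not None else "")
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for i in range(len(u_low)):
            row = f"{i} {rc[i, 0]:.8g} {rc[i, 1]:.8g} {u_low[i]:.10g}"
            if u_high is not None:
                row += f" {u_high[i]:.10g}"
            fh.write(row + "\n")


def write_manifest(path, window_table: str, sample_files: dict[int, str],
                   temperature: float, extra: dict | None = None) -> None:
    doc = {
        "window_table": str(window_table),
        "temperature": float(temperature),
        "samples": {int(k): str(v) for k, v in sample_files.items()},
    }
    if extra:
        doc["provenance"] = extra
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("window_table", "temperature", "samples"):
        if key not in doc:
            raise ValueError(f"manifest missing required key {key!r}")
    return doc


def load_sampleset(manifest_path) -> SampleSet:
    """Assemble a :class:`SampleSet` from a run manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    doc = read_manifest(manifest_path)
    base = manifest_path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    windows = read_window_table(resolve(doc["window_table"]))
    by_index = {w.index: w for w in windows}
    widx_parts, rc_parts, ul_parts, uh_parts = [], [], [], []
    any_high = False
    for idx, f in sorted(doc["samples"].items()):
        if int(idx) not in by_index:
            raise ValueError(f"manifest sample file for unknown window {idx}")
        wi, rc, ul, uh = read_samples_file(resolve(f), int(idx))
        widx_parts.append(wi)
        rc_parts.append(rc)
        ul_parts.append(ul)
        uh_parts.append(uh)
        any_high = any_high or uh is not None
    u_high = None
    if any_high:
        u_high = np.concatenate(
            [np.full(len(w), np.nan) if uh is None else uh for w, uh in zip(widx_parts, uh_parts)]
        )
    return SampleSet(
        windows,
        np.concatenate(widx_parts),
        np.concatenate(rc_parts),
        np.concatenate(ul_parts),
        float(doc["temperature"]),
        u_high=u_high,
    )


def write_surface(path, surface: Surface2D, sidecar: dict | None = None) -> None:
    """Write a surface as TSV (eta1, eta2, value, variance, count, entropy) + JSON sidecar."""
    df = surface.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = dict(sidecar or {})
    meta.setdefault("axis1", surface.grid.axis1.tolist())
    meta.setdefault("axis2", surface.grid.axis2.tolist())
    meta.setdefault("bin_width", list(surface.grid.bin_width))
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_surface(path) -> Surface2D:
    df = pd.read_csv(path, sep="\t")
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    grid = Grid2D(np.array(meta["axis1"]), np.array(meta["axis2"]), tuple(meta["bin_width"]))
    shape = grid.shape

    def reshape(col):
        return df[col].to_numpy().reshape(shape)

    return Surface2D(
        grid,
        reshape("value"),
        variance=reshape("variance"),
        count=reshape("count").astype(np.int64),
        entropy=reshape("entropy"),
        occupied=reshape("occupied").astype(bool),
    )


def read_charge_file(path):
    """Read one frame's solvent point charges: columns x, y, z, q (Å, e)."""
    df = _read_table(path, ["x", "y", "z", "q"])
    arr = df.to_numpy(float)
    return arr[:, :3], arr[:, 3]
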