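"""Readers, writers, configuration files, and provenance manifests.

Video input/output uses lossless containers only: multi-page TIFF stacks
(``.tif``/``.tiff``) or directories of PNG frames, both bit-exact across
round trips.  Tabular outputs are plain CSV; contours/spines and large
runs can additionally be bundled into one HDF5 file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig, config_from_dict, config_to_dict

__all__ = [
    "load_config", "save_config", "write_video", "iter_video", "read_video",
    "write_truth", "read_truth", "write_manifest", "save_bundle",
]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def write_video(frames, path) -> None:
    """Write frames to a TIFF stack or a PNG directory (lossless).

    ``frames`` yields ``(index, uint8 array)`` or plain arrays.
    """
    path = Path(path)
    arrays = [f[1] if isinstance(f, tuple) else f for f in frames]
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, np.stack(arrays), compression="zlib",
                         photometric="minisblack")
    else:
        import imageio.v3 as iio
        path.mkdir(parents=True, exist_ok=True)
        for k, arr in enumerate(arrays):
            iio.imwrite(path / f"frame_{k:06d}.png", arr)


def iter_video(path):
    """Yield ``(index, uint8 frame)`` from a TIFF stack or PNG directory."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio
        for k, p in enumerate(sorted(path.glob("frame_*.png"))):
            yield k, iio.imread(p)
    else:
        import tifffile
        with tifffile.TiffFile(path) as tf:
            for k, page in enumerate(tf.pages):
                yield k, page.asarray()


def read_video(path) -> np.ndarray:
    return np.stack([f for _, f in iter_video(path)])


def write_truth(truth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.frames.to_csv(outdir / "truth_frames.csv", index=False)
    truth.turns.to_csv(outdir / "truth_turns.csv", index=False)
    truth.events.to_csv(outdir / "truth_events.csv", index=False)


def read_truth(outdir):
    from .simulate import GroundTruth

    outdir = Path(outdir)
    return GroundTruth(
        frames=pd.read_csv(outdir / "truth_frames.csv"),
        turns=pd.read_csv(outdir / "truth_turns.csv"),
        events=pd.read_csv(outdir / "truth_events.csv"),
        config=None,
    )


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_manifest(path, cfg: PipelineConfig, seed: int,
                   inputs: dict | None = None) -> dict:
    """Provenance sidecar: tool version, config hash, input hashes, seed."""
    cfg_json = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    manifest = {
        "tool": "larvatrack",
        "version": __version__,
        "seed": int(seed),
        "config_sha256": _sha256(cfg_json.encode()),
        "inputs": {},
    }
    for name, p in (inputs or {}).items():
        p = Path(p)
        if p.is_file():
            manifest["inputs"][name] = _sha256(p.read_bytes())
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def save_bundle(path, tracks_df: pd.DataFrame | None = None,
                events_df: pd.DataFrame | None = None,
                contours: dict | None = None,
                spines: dict | None = None) -> None:
    """HDF5 bundle for large runs; contours/spines live here only."""
    import h5py

    with h5py.File(path, "w") as h5:
        if tracks_df is not None:
            grp = h5.create_group("tracks")
            for col in tracks_df.columns:
                vals = tracks_df[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)
        if events_df is not None and len(events_df):
            grp = h5.create_group("events")
            for col in events_df.columns:
                vals = events_df[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)
        for name, mapping in (("contours", contours), ("spines", spines)):
            if mapping:
                grp = h5.create_group(name)
                for key, arr in mapping.items():
                    grp.create_dataset(str(key), data=np.asarray(arr))
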