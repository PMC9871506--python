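"""Scene and mask I/O: multi-band TIFF rasters with JSON sidecars.

A scene is stored as a 5-band float32 TIFF (band order B, G, R, RE, NIR)
next to a ``<stem>.json`` sidecar holding acquisition metadata and the
sample-region / panel layout. Ground truth, when saved, goes to
``<stem>.truth.tif`` (canopy cover fraction) with its labels and per-sample
true means folded into the sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic_data import GroundTruth, MultispectralScene, PanelRegion, SampleRegion


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_scene(scene: MultispectralScene, path, truth: GroundTruth | None = None) -> Path:
    """Write a scene (and optionally its ground truth) to ``path``."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(scene.bands, np.float32))
    meta = {
        "kind": scene.kind,
        "day": scene.day,
        "agl": scene.agl,
        "gsd_cm": scene.gsd_cm,
        "regions": [dataclasses.asdict(r) for r in scene.regions],
        "panels": [dataclasses.asdict(p) for p in scene.panels],
    }
    if truth is not None:
        truth_path = path.with_suffix(".truth.tif")
        tifffile.imwrite(truth_path, truth.cover_fraction.astype(np.float32))
        meta["truth"] = {
            "cover_tif": truth_path.name,
            "labels": truth.labels,
            "true_band_means": {k: list(map(float, v)) for k, v in truth.true_band_means.items()},
            "empty_canopy": truth.empty_canopy,
        }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_scene(path) -> tuple[MultispectralScene, GroundTruth | None]:
    """Read a scene written by :func:`write_scene`."""
    path = Path(path)
    bands = tifffile.imread(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    scene = MultispectralScene(
        bands=np.asarray(bands, np.float32),
        kind=meta["kind"],
        day=meta["day"],
        agl=meta["agl"],
        gsd_cm=meta["gsd_cm"],
        regions=[SampleRegion(**r) for r in meta["regions"]],
        panels=[PanelRegion(**p) for p in meta["panels"]],
    )
    truth = None
    if "truth" in meta:
        t = meta["truth"]
        cover = tifffile.imread(path.parent / t["cover_tif"]).astype(np.float32)
        truth = GroundTruth(
            mask=cover >= 0.5,
            cover_fraction=cover,
            labels=t["labels"],
            true_band_means={k: np.asarray(v, float) for k, v in t["true_band_means"].items()},
            empty_canopy=t["empty_canopy"],
        )
    return scene, truth


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a boolean canopy mask as a single-band 0/1 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask, np.uint8))
    return path


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)
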