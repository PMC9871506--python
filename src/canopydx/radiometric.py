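"""Radiometric calibration: digital numbers to surface reflectance.

The camera's downwelling light sensor provides, per band X, a light-sensor
signal ``X_LS`` and two calibration coefficients ``pCam_X`` and ``pLS_X``
referenced to the NIR band, plus a NIR interconversion factor ``rho_NIR``.
A pixel's reflectance is

    X_ref = X_DN * pCam_X / (X_LS * pLS_X) * rho_NIR

clipped to [0, 1]. The on-site 10% and 90% calibration panels are used to
verify the calibration after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .bands import BAND_NAMES


@dataclass
class BandRaster:
    """Single-band image, either raw digital numbers or reflectance."""

    band: str
    values: np.ndarray
    kind: str = "dn"  # "dn" | "reflectance"

    def __post_init__(self):
        if self.band not in BAND_NAMES:
            raise ValueError(f"band must be one of {BAND_NAMES}, got {self.band!r}")
        if self.kind not in ("dn", "reflectance"):
            raise ValueError("kind must be 'dn' or 'reflectance'")
        self.values = np.asarray(self.values, float)
        if self.values.size == 0:
            raise ValueError("raster must be non-empty")


@dataclass
class CalibrationParams:
    """Per-band light-sensor calibration coefficients.

    ``x_ls``: light-sensor signal per band (> 0); ``p_cam`` / ``p_ls``:
    camera- and sensor-side coefficients per band; ``rho_nir``: NIR
    interconversion factor applied in every band.
    """

    x_ls: dict[str, float]
    p_cam: dict[str, float]
    p_ls: dict[str, float]
    rho_nir: float = 1.0

    def __post_init__(self):
        if self.rho_nir <= 0:
            raise ValueError("rho_nir must be > 0")
        for band in set(self.x_ls) | set(self.p_ls):
            if self.x_ls.get(band, 1.0) <= 0:
                raise ValueError(f"x_ls must be > 0 (band {band})")
            if self.p_ls.get(band, 1.0) <= 0:
                raise ValueError(f"p_ls must be > 0 (band {band})")

    @classmethod
    def identity(cls) -> "CalibrationParams":
        ones = {b: 1.0 for b in BAND_NAMES}
        return cls(x_ls=dict(ones), p_cam=dict(ones), p_ls=dict(ones), rho_nir=1.0)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"x_ls": self.x_ls, "p_cam": self.p_cam, "p_ls": self.p_ls,
                 "rho_nir": self.rho_nir},
                fh, sort_keys=False,
            )


def calibrate_band(dn: BandRaster, params: CalibrationParams) -> BandRaster:
    """Convert a digital-number band to reflectance.

    Applies ``X_ref = X_DN * pCam_X / (X_LS * pLS_X) * rho_NIR`` element-wise
    and clips to [0, 1]. Linear in ``X_DN`` below the clip point.
    """
    if dn.kind != "dn":
        raise ValueError("input raster is already reflectance")
    b = dn.band
    for name, table in (("x_ls", params.x_ls), ("p_cam", params.p_cam), ("p_ls", params.p_ls)):
        if b not in table:
            raise KeyError(f"calibration parameter {name} missing for band {b}")
    scale = params.p_cam[b] / (params.x_ls[b] * params.p_ls[b]) * params.rho_nir
    ref = np.clip(dn.values * scale, 0.0, 1.0)
    return BandRaster(band=b, values=ref, kind="reflectance")


def calibrate_scene(bands_dn: dict[str, np.ndarray], params: CalibrationParams) -> dict[str, np.ndarray]:
    """Calibrate a dict of per-band DN arrays; returns reflectance arrays."""
    return {
        b: calibrate_band(BandRaster(band=b, values=v, kind="dn"), params).values
        for b, v in bands_dn.items()
    }


@dataclass
class PanelReport:
    """Per-band, per-panel verification of the radiometric calibration."""

    table: pd.DataFrame  # columns: panel_nominal, band, mean, rel_error, passed
    tolerance: float

    @property
    def passed(self) -> bool:
        return bool(self.table["passed"].all())


def verify_panels(scene, panel_regions=None, tolerance: float = 0.05) -> PanelReport:
    """Check scene reflectance against the nominal panel values.

    For each panel region and band, reports the mean observed reflectance
    and its relative error versus the nominal value, pass/fail at
    ``tolerance`` (default 5% relative).
    """
    panels = panel_regions if panel_regions is not None else scene.panels
    if not panels:
        raise ValueError("no panel regions supplied")
    rows = []
    for panel in panels:
        sl = panel.slices
        patch = scene.bands[(slice(None),) + sl]
        if patch[0].size == 0:
            raise ValueError("empty panel region")
        for j, band in enumerate(BAND_NAMES):
            mean = float(patch[j].mean())
            rel = (mean - panel.nominal) / panel.nominal
            rows.append({
                "panel_nominal": panel.nominal,
                "band": band,
                "mean": mean,
                "rel_error": rel,
                "passed": abs(rel) <= tolerance,
            })
    return PanelReport(table=pd.DataFrame(rows), tolerance=tolerance)
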