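"""Canopy masking and per-sample spectral feature extraction.

The feature set is the 20 variables used for deficiency diagnosis: the five
band reflectances (B, G, R, RE, NIR) plus fifteen vegetation indices (VIs).
A pixel-level support-vector classifier separates crop crown from soil
background; features are then averaged per pot region over canopy pixels
only.

VI means are computed pixel-wise and then averaged over the canopy mask
(``pixelwise=True``), with the index-of-mean-bands alternative available
behind a flag. Pixels where an index is undefined (zero denominator,
negative radicand) are excluded from that sample's mean and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .bands import BAND_NAMES

__all__ = [
    "VI_NAMES",
    "FEATURE_COLUMNS",
    "compute_index",
    "compute_all_indices",
    "train_pixel_classifier",
    "build_mask",
    "extract_features",
    "PixelClassifier",
    "CanopyMask",
]

#: the fifteen vegetation indices, in reporting order
VI_NAMES: tuple[str, ...] = (
    "NDVI",
    "RVI",
    "EVI",
    "DVI",
    "RDVI",
    "SAVI",
    "GNDVI",
    "NDRE",
    "OSAVI",
    "GRVI",
    "LCI",
    "NDWI",
    "BNDVI",
    "BVI",
    "BRVI",
)

#: the full 20-variable diagnostic feature set
FEATURE_COLUMNS: tuple[str, ...] = BAND_NAMES + VI_NAMES


def _safe_div(num, den):
    """Element-wise num/den with zero denominators propagated as NaN."""
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, np.nan, num / den)
    return out


def compute_index(name: str, bands, rdvi_form: str = "printed"):
    """Compute one vegetation index from a B/G/R/RE/NIR band set.

    ``bands`` is a mapping from band name to scalar or aligned array.
    Undefined values (zero denominators; for RDVI a non-positive radicand)
    come back as NaN, never silently zeroed.

    RDVI follows the renormalised-difference form (NIR−R)/√(NIR−R) by
    default; ``rdvi_form="literature"`` switches to (NIR−R)/√(NIR+R).
    """
    B, G, R = bands["B"], bands["G"], bands["R"]
    RE, NIR = bands["RE"], bands["NIR"]
    B, G, R, RE, NIR = (np.asarray(x, float) for x in (B, G, R, RE, NIR))

    if name == "NDVI":
        out = _safe_div(NIR - R, NIR + R)
    elif name == "RVI":
        out = _safe_div(NIR, R)
    elif name == "EVI":
        out = 2.5 * _safe_div(NIR - R, NIR + 6.0 * R - 7.5 * B + 1.0)
    elif name == "DVI":
        out = NIR - R
    elif name == "RDVI":
        if rdvi_form == "printed":
            with np.errstate(invalid="ignore"):
                rad = np.where(NIR - R > 0, np.sqrt(np.maximum(NIR - R, 0)), np.nan)
            out = _safe_div(NIR - R, rad)
        elif rdvi_form == "literature":
            with np.errstate(invalid="ignore"):
                rad = np.where(NIR + R > 0, np.sqrt(np.maximum(NIR + R, 0)), np.nan)
            out = _safe_div(NIR - R, rad)
        else:
            raise ValueError("rdvi_form must be 'printed' or 'literature'")
    elif name == "SAVI":
        out = 1.5 * _safe_div(NIR - R, NIR + R + 0.5)
    elif name == "GNDVI":
        out = _safe_div(NIR - G, NIR + G)
    elif name == "NDRE":
        out = _safe_div(NIR - RE, NIR + RE)
    elif name == "OSAVI":
        out = _safe_div(NIR - R, NIR + R + 0.16)
    elif name == "GRVI":
        out = _safe_div(NIR, G)
    elif name == "LCI":
        out = _safe_div(NIR - RE, NIR - R)
    elif name == "NDWI":
        out = _safe_div(G - NIR, G + NIR)
    elif name == "BNDVI":
        out = _safe_div(NIR - B, NIR + B)
    elif name == "BVI":
        out = _safe_div(NIR, B)
    elif name == "BRVI":
        out = _safe_div(R, B)
    else:
        raise KeyError(f"unknown vegetation index {name!r}")
    if out.ndim == 0:
        return float(out)
    return out


def compute_all_indices(bands, rdvi_form: str = "printed") -> dict:
    return {name: compute_index(name, bands, rdvi_form=rdvi_form) for name in VI_NAMES}


# ---------------------------------------------------------------------------
# pixel classification / masking


@dataclass
class PixelClassifier:
    """Binary canopy/background margin classifier on 5-band pixel vectors."""

    pipeline: Pipeline
    holdout_accuracy: float
    classifier_id: str = "linear-svm"

    def predict(self, pixels: np.ndarray) -> np.ndarray:
        """Return a boolean canopy flag per pixel row of shape (n, 5)."""
        return self.pipeline.predict(pixels).astype(bool)


@dataclass
class CanopyMask:
    """Boolean canopy grid aligned with its source scene."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_canopy(self) -> int:
        return int(self.mask.sum())


def train_pixel_classifier(pixels: np.ndarray, labels, seed: int = 0,
                           holdout: float = 0.25) -> PixelClassifier:
    """Fit a linear support-vector canopy/background classifier.

    ``pixels`` is (n, 5) reflectance; ``labels`` is boolean (True = canopy)
    or any 2-class vector coercible to bool. A stratified hold-out fraction
    reports pixel accuracy. Raises ``ValueError`` on single-class input.
    """
    pixels = np.asarray(pixels, float)
    y = np.asarray(labels).astype(bool)
    if pixels.ndim != 2 or pixels.shape[1] != len(BAND_NAMES):
        raise ValueError(f"pixels must be (n, {len(BAND_NAMES)})")
    if len(np.unique(y)) < 2:
        raise ValueError("need both canopy and background pixels to train")
    if min(np.bincount(y.astype(int))) < 50:
        warnings.warn("fewer than 50 labelled pixels in a class; accuracy estimate unstable")

    X_tr, X_te, y_tr, y_te = train_test_split(
        pixels, y, test_size=holdout, stratify=y, random_state=seed
    )
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", LinearSVC(C=1.0, random_state=seed)),
    ])
    pipe.fit(X_tr, y_tr)
    acc = float((pipe.predict(X_te) == y_te).mean())
    return PixelClassifier(pipeline=pipe, holdout_accuracy=acc)


def build_mask(scene, classifier: PixelClassifier) -> CanopyMask:
    """Classify every scene pixel as canopy or background."""
    bands = scene.bands
    if bands.shape[0] != len(BAND_NAMES):
        raise ValueError("scene must have 5 aligned bands")
    h, w = bands.shape[1:]
    flat = bands.reshape(len(BAND_NAMES), -1).T
    pred = classifier.predict(flat).reshape(h, w)
    return CanopyMask(
        mask=pred,
        provenance={
            "classifier_id": classifier.classifier_id,
            "holdout_accuracy": classifier.holdout_accuracy,
        },
    )


# ---------------------------------------------------------------------------
# per-sample feature extraction


def extract_features(
    scene,
    mask,
    layout=None,
    min_pixels: int = 30,
    pixelwise: bool = True,
    rdvi_form: str = "printed",
) -> pd.DataFrame:
    """Average bands and vegetation indices per pot region over canopy pixels.

    ``mask`` is a :class:`CanopyMask` or a bare boolean array aligned with
    the scene; ``layout`` defaults to the scene's own region list. Rows with
    fewer than ``min_pixels`` canopy pixels are kept but flagged. Per-VI
    counts of undefined (excluded) pixels are reported in the
    ``vi_undefined_counts`` column.
    """
    m = mask.mask if isinstance(mask, CanopyMask) else np.asarray(mask, bool)
    if m.shape != scene.shape:
        raise ValueError(f"mask shape {m.shape} != scene shape {scene.shape}")
    regions = layout if layout is not None else scene.regions

    rows = []
    for region in regions:
        sl = region.slices
        rmask = m[sl]
        npix = int(rmask.sum())
        row = {
            "sample_id": region.sample_id,
            "label": region.label,
            "day": scene.day,
            "agl": scene.agl,
            "n_pixels": npix,
            "flagged": npix < min_pixels,
        }
        undef: dict[str, int] = {}
        if npix == 0:
            row.update({name: np.nan for name in FEATURE_COLUMNS})
        else:
            pix = {
                name: scene.bands[j][sl][rmask].astype(float)
                for j, name in enumerate(BAND_NAMES)
            }
            for name in BAND_NAMES:
                row[name] = float(pix[name].mean())
            if pixelwise:
                for vi in VI_NAMES:
                    vals = compute_index(vi, pix, rdvi_form=rdvi_form)
                    bad = int(np.sum(~np.isfinite(vals)))
                    if bad:
                        undef[vi] = bad
                    row[vi] = float(np.nanmean(vals)) if bad < npix else np.nan
            else:
                means = {name: row[name] for name in BAND_NAMES}
                for vi in VI_NAMES:
                    val = compute_index(vi, means, rdvi_form=rdvi_form)
                    row[vi] = float(val) if np.isfinite(val) else np.nan
        row["vi_undefined_counts"] = undef
        rows.append(row)
    return pd.DataFrame(rows)
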