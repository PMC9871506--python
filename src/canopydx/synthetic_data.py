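"""Synthetic multispectral canopy scenes for a pot-culture nutrient-stress trial.

This module simulates the imaging side of a nutrient-deficiency experiment on
potted *Ligusticum chuanxiong*: a grid of pot samples photographed from a UAV
at 5 m or 10 m above ground, in five spectral bands (B/G/R/RE/NIR), over a
time series of stress days. Four diagnostic groups are modelled — CK
(control), ND (nitrogen-deficient), PD (phosphorus-deficient) and KD
(potassium-deficient) — plus the re-supplemented recovery groups NS/PS/KS.

The spectral model is deliberately simple and fully parameterised:

* every canopy pixel of a pot is the class/day band-mean, plus a per-pot
  random brightness offset (shared across bands), plus independent per-pixel
  Gaussian noise, clipped to [0, 1];
* nitrogen deficiency raises visible reflectance (pigment loss), lowers NIR
  and thins the canopy; phosphorus/potassium deficiency lowers visible
  reflectance (darker, older foliage) and slightly raises NIR, so
  NIR/visible ratio indices increase;
* effects ramp up piecewise-linearly from a class-specific onset day (ND at
  day 15, PD/KD at day 22) to a plateau at day 38;
* recovery groups track their deficient parent until re-supplementation at
  day 30, then relax linearly back towards CK;
* canopies are rendered as filled ellipses with jittered axis ratios on a
  soil background, with sub-pixel coverage computed by supersampling, so a
  coarser ground-sampling distance (higher flight altitude) yields a larger
  fraction of mixed canopy/soil edge pixels;
* two radiometric calibration panels (nominal reflectance 0.10 and 0.90) are
  rendered into every scene.

Everything is deterministic given ``(config, day, agl, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .bands import BAND_NAMES

TREATMENT_CLASSES: tuple[str, ...] = ("CK", "ND", "PD", "KD")
RECOVERY_CLASSES: tuple[str, ...] = ("NS", "PS", "KS")
ALL_CLASSES: tuple[str, ...] = TREATMENT_CLASSES + RECOVERY_CLASSES

#: recovery group -> deficient parent group
RECOVERY_PARENT: dict[str, str] = {"NS": "ND", "PS": "PD", "KS": "KD"}

_CLASS_INDEX = {c: i for i, c in enumerate(ALL_CLASSES)}


class _ByClassDay:
    """Read-only ``obj[class, day]`` view over a per-class/day schedule."""

    def __init__(self, fn):
        self._fn = fn

    def __getitem__(self, key):
        cls, day = key
        return self._fn(cls, day)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic trial.

    Reflectances are unitless in [0, 1]; days count from the start of the
    stress treatment; GSD is in cm/pixel; pot geometry is in cm.
    """

    #: CK canopy mean reflectance per band, constant across days.
    ck_profile: tuple[float, ...] = (0.05, 0.10, 0.06, 0.30, 0.50)
    #: per-class full-effect (plateau) band deltas added to the CK profile.
    plateau_delta: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "ND": (0.030, 0.050, 0.050, -0.020, -0.100),
            "PD": (-0.015, -0.030, -0.020, 0.010, 0.030),
            "KD": (-0.012, -0.025, -0.018, 0.005, 0.025),
        }
    )
    #: soil background reflectance per band.
    soil_spectrum: tuple[float, ...] = (0.14, 0.20, 0.24, 0.28, 0.32)
    #: CK canopy coverage of the pot region, and per-class plateau deltas.
    ck_coverage: float = 0.55
    coverage_delta: dict[str, float] = field(
        default_factory=lambda: {"ND": -0.20, "PD": -0.05, "KD": -0.08}
    )
    #: first stress day with a nonzero effect, per deficient class.
    onset_day: dict[str, int] = field(
        default_factory=lambda: {"ND": 15, "PD": 22, "KD": 22}
    )
    #: day at which effects stop growing.
    plateau_day: int = 38
    #: recovery groups are re-supplemented on this day and relax towards CK.
    recovery_start_day: int = 30
    #: day by which a recovery group is fully back at the CK profile.
    recovery_full_day: int = 58
    #: per-pixel Gaussian reflectance noise (independent across bands).
    pixel_noise_sd: float = 0.01
    #: per-pot random brightness offset (shared across bands).
    pot_effect_sd: float = 0.005
    #: samples per treatment class.
    n_per_class: int = 48
    #: nominal calibration-panel reflectances.
    panel_reflectances: tuple[float, float] = (0.10, 0.90)
    #: flight altitude (m) -> ground sampling distance (cm/pixel).
    gsd_by_agl: dict[float, float] = field(
        default_factory=lambda: {5.0: 0.265, 10.0: 0.529}
    )
    #: side of the square pot region, cm.
    region_cm: float = 30.0
    #: side of each calibration panel, cm.
    panel_cm: float = 20.0

    def __post_init__(self):
        for name, vec in [("ck_profile", self.ck_profile), ("soil_spectrum", self.soil_spectrum)]:
            arr = np.asarray(vec, float)
            if arr.shape != (5,) or np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must be 5 reflectances in [0, 1]")
        if not 0 < self.ck_coverage <= 1:
            raise ValueError("ck_coverage must be in (0, 1]")
        if self.pixel_noise_sd < 0 or self.pot_effect_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")

    # -- effect schedule ---------------------------------------------------

    def effect_level(self, cls: str, day: float) -> float:
        """Fractional effect size in [0, 1] for ``cls`` at ``day``.

        Piecewise linear: 0 before onset, ramping to 1 at the plateau day.
        Recovery groups follow their parent, then relax linearly to 0
        between re-supplementation and full recovery.
        """
        if cls == "CK":
            return 0.0
        if cls in RECOVERY_PARENT:
            parent = RECOVERY_PARENT[cls]
            base = self.effect_level(parent, min(day, self.recovery_start_day))
            if day <= self.recovery_start_day:
                return base
            span = self.recovery_full_day - self.recovery_start_day
            relax = max(0.0, 1.0 - (day - self.recovery_start_day) / span)
            return base * relax
        if cls not in self.plateau_delta:
            raise KeyError(f"unknown class {cls!r}")
        onset = self.onset_day[cls]
        if day < onset:
            return 0.0
        return min(1.0, (day - onset) / (self.plateau_day - onset))

    def profile(self, cls: str, day: float) -> np.ndarray:
        """Canopy mean reflectance 5-vector for ``cls`` at ``day``."""
        base = np.asarray(self.ck_profile, float)
        lev = self.effect_level(cls, day)
        if lev == 0.0:
            return base.copy()
        key = RECOVERY_PARENT.get(cls, cls)
        return base + lev * np.asarray(self.plateau_delta[key], float)

    def coverage(self, cls: str, day: float) -> float:
        """Canopy cover fraction of the pot region for ``cls`` at ``day``."""
        lev = self.effect_level(cls, day)
        key = RECOVERY_PARENT.get(cls, cls)
        delta = self.coverage_delta.get(key, 0.0)
        return float(np.clip(self.ck_coverage + lev * delta, 0.0, 1.0))

    @property
    def class_profiles(self) -> _ByClassDay:
        """Indexable view: ``config.class_profiles["ND", 22]`` -> 5-vector."""
        return _ByClassDay(self.profile)

    @property
    def canopy_coverage(self) -> _ByClassDay:
        return _ByClassDay(self.coverage)

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("ck_profile", "soil_spectrum", "panel_reflectances"):
            if key in d:
                d[key] = tuple(d[key])
        if "plateau_delta" in d:
            d["plateau_delta"] = {k: tuple(v) for k, v in d["plateau_delta"].items()}
        if "gsd_by_agl" in d:
            d["gsd_by_agl"] = {float(k): float(v) for k, v in d["gsd_by_agl"].items()}
        return cls(**d)


def reference_config() -> SyntheticConfig:
    """Default configuration of the simulated trial.

    48 samples per treatment class; ND separates from CK beginning at stress
    day 15 and PD/KD at day 22, with effects plateauing at day 38, where the
    configured class separation on the informative NIR/visible ratio indices
    exceeds four within-class standard deviations.
    """
    return SyntheticConfig()


def null_config() -> SyntheticConfig:
    """Configuration with every class effect removed (all groups ≡ CK)."""
    zeros = (0.0,) * 5
    return dataclasses.replace(
        reference_config(),
        plateau_delta={"ND": zeros, "PD": zeros, "KD": zeros},
        coverage_delta={"ND": 0.0, "PD": 0.0, "KD": 0.0},
    )


# ---------------------------------------------------------------------------
# scene containers


@dataclass
class SampleRegion:
    """Axis-aligned pot region in pixel space (half-open rows/cols)."""

    sample_id: str
    label: str
    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass
class PanelRegion:
    """Calibration panel region with its nominal reflectance."""

    nominal: float
    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass
class MultispectralScene:
    """Aligned 5-band raster plus acquisition metadata and region layout."""

    bands: np.ndarray  # (5, H, W) float32
    kind: str  # "reflectance" or "dn"
    day: int
    agl: float
    gsd_cm: float
    regions: list[SampleRegion]
    panels: list[PanelRegion]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.bands[BAND_NAMES.index(name)]


@dataclass
class GroundTruth:
    """Simulator-side truth for validating downstream stages.

    ``mask`` marks majority-canopy pixels (cover fraction >= 0.5);
    ``cover_fraction`` is the continuous canopy cover per pixel, so pure
    canopy is ``cover_fraction == 1`` and mixed edge pixels are strictly
    between 0 and 1. ``true_band_means`` holds each pot's noiseless canopy
    reflectance (class profile + pot offset).
    """

    mask: np.ndarray  # (H, W) bool
    cover_fraction: np.ndarray  # (H, W) float32
    labels: dict[str, str]  # sample_id -> class
    true_band_means: dict[str, np.ndarray]  # sample_id -> 5-vector
    empty_canopy: list[str]  # sample ids whose region has no pure canopy pixel


# ---------------------------------------------------------------------------
# rendering


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


_SUPER = 4  # supersampling factor for sub-pixel canopy coverage


def _ellipse_cover(region_px: int, coverage: float, aspect: float) -> np.ndarray:
    """Per-pixel canopy cover fraction of an axis-aligned centred ellipse.

    The ellipse area equals ``coverage`` times the region area; ``aspect``
    jitters the axis ratio at constant area. Coverage is measured on a
    ``_SUPER``x``_SUPER`` subgrid per pixel.
    """
    s = region_px
    # pi * a * b = coverage * s^2, with a = r * aspect, b = r / aspect
    r = s * np.sqrt(coverage / np.pi)
    a, b = r * aspect, r / aspect
    n = s * _SUPER
    coords = (np.arange(n) + 0.5) / _SUPER  # pixel-space coordinates
    cy = cx = s / 2.0
    yy = ((coords - cy) / b) ** 2
    xx = ((coords - cx) / a) ** 2
    inside = (yy[:, None] + xx[None, :]) <= 1.0
    return inside.reshape(s, _SUPER, s, _SUPER).mean(axis=(1, 3))


def _class_day_seed_key(cls: str, sample_index: int, day: int) -> tuple[int, ...]:
    return (_CLASS_INDEX[cls], int(sample_index), int(day))


def _pot_offset(config: SyntheticConfig, seed: int, cls: str, i: int, day: int) -> float:
    rng = _rng(seed, 1, *_class_day_seed_key(cls, i, day))
    return float(rng.normal(0.0, config.pot_effect_sd))


def generate_scene(
    config: SyntheticConfig,
    day: int,
    agl: float,
    seed: int,
    include_recovery: bool = False,
) -> tuple[MultispectralScene, GroundTruth]:
    """Render one acquisition: all pots of all classes on a soil background.

    Pots are laid out on a square grid of ``region_cm`` cells; two
    calibration panels sit in a strip above the grid. Deterministic given
    ``(config, day, agl, seed)``.

    Raises ``KeyError`` for an AGL with no configured GSD and ``ValueError``
    for ``day < 1``.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    agl = float(agl)
    if agl not in config.gsd_by_agl:
        raise KeyError(
            f"no GSD configured for AGL {agl} m (known: {sorted(config.gsd_by_agl)})"
        )
    gsd = config.gsd_by_agl[agl]
    region_px = max(4, int(round(config.region_cm / gsd)))
    panel_px = max(4, int(round(config.panel_cm / gsd)))
    margin = max(2, region_px // 16)

    classes = list(TREATMENT_CLASSES) + (list(RECOVERY_CLASSES) if include_recovery else [])
    if include_recovery and day < config.recovery_start_day:
        classes = list(TREATMENT_CLASSES)
    samples = [(cls, i) for cls in classes for i in range(config.n_per_class)]

    ncols = int(np.ceil(np.sqrt(len(samples))))
    nrows = int(np.ceil(len(samples) / ncols))
    cell = region_px + margin
    panel_strip = panel_px + 2 * margin
    height = panel_strip + nrows * cell + margin
    width = max(ncols * cell + margin, 2 * (panel_px + 2 * margin))

    soil = np.asarray(config.soil_spectrum, float)
    bands = np.empty((5, height, width), dtype=np.float64)
    bands[:] = soil[:, None, None]

    cover = np.zeros((height, width), dtype=np.float32)
    regions: list[SampleRegion] = []
    labels: dict[str, str] = {}
    true_means: dict[str, np.ndarray] = {}
    empty: list[str] = []

    for k, (cls, i) in enumerate(samples):
        r, c = divmod(k, ncols)
        row0 = panel_strip + r * cell + margin
        col0 = c * cell + margin
        sid = f"{cls}-{i:03d}"
        region = SampleRegion(sid, cls, row0, col0, row0 + region_px, col0 + region_px)
        regions.append(region)
        labels[sid] = cls

        offset = _pot_offset(config, seed, cls, i, day)
        prof = config.profile(cls, day) + offset
        true_means[sid] = prof.copy()

        jrng = _rng(seed, 3, *_class_day_seed_key(cls, i, day))
        aspect = float(jrng.uniform(0.87, 1.15))
        frac = _ellipse_cover(region_px, config.coverage(cls, day), aspect)
        cover[region.slices] = frac
        if not np.any(frac >= 1.0):
            empty.append(sid)

        # mix canopy and soil by sub-pixel cover fraction
        patch = frac[None, :, :] * prof[:, None, None] + (1.0 - frac[None, :, :]) * soil[:, None, None]
        bands[(slice(None),) + region.slices] = patch

    # panels in the top strip
    panels = []
    for j, nominal in enumerate(config.panel_reflectances):
        col0 = margin + j * (panel_px + 2 * margin)
        panels.append(PanelRegion(float(nominal), margin, col0, margin + panel_px, col0 + panel_px))
        bands[:, margin : margin + panel_px, col0 : col0 + panel_px] = float(nominal)

    if config.pixel_noise_sd > 0:
        noise_rng = _rng(seed, 2, day, int(round(agl * 10)))
        bands += noise_rng.normal(0.0, config.pixel_noise_sd, size=bands.shape)
    np.clip(bands, 0.0, 1.0, out=bands)

    scene = MultispectralScene(
        bands=bands.astype(np.float32),
        kind="reflectance",
        day=day,
        agl=agl,
        gsd_cm=gsd,
        regions=regions,
        panels=panels,
    )
    truth = GroundTruth(
        mask=cover >= 0.5,
        cover_fraction=cover,
        labels=labels,
        true_band_means=true_means,
        empty_canopy=empty,
    )
    return scene, truth


# ---------------------------------------------------------------------------
# fast feature-table path


def generate_feature_dataset(
    config: SyntheticConfig,
    days,
    agl: float,
    seed: int,
    include_recovery: bool = False,
    n_pixels: int | None = None,
):
    """Draw the per-sample feature table directly, skipping rendering.

    For each pot the same noise model as :func:`generate_scene` is sampled —
    pot offset shared across bands, independent per-pixel Gaussian noise,
    clipped to [0, 1] — over the number of pure-canopy pixels the rendered
    geometry would contain, and band means plus pixel-wise vegetation-index
    means are computed exactly as the image path would over the pure canopy
    mask. Distributionally equivalent to rendering + extraction; the pot
    offsets are drawn from the same per-(class, pot, day) streams, so the two
    paths share their pot-level randomness at equal seed.

    Returns a :class:`pandas.DataFrame` with one row per sample per day.
    """
    import pandas as pd

    from .canopy_features import VI_NAMES, compute_index

    days = list(days)
    if not days:
        raise ValueError("days list must not be empty")
    agl = float(agl)
    if agl not in config.gsd_by_agl:
        raise KeyError(f"no GSD configured for AGL {agl} m")
    gsd = config.gsd_by_agl[agl]
    region_px = max(4, int(round(config.region_cm / gsd)))

    rows = []
    for day in days:
        classes = list(TREATMENT_CLASSES) + (
            list(RECOVERY_CLASSES) if include_recovery and day >= config.recovery_start_day else []
        )
        for cls in classes:
            prof_base = config.profile(cls, day)
            covg = config.coverage(cls, day)
            if n_pixels is None:
                # pure-canopy pixel count of the rendered ellipse, shrunk by
                # the mixed-edge band (perimeter x ~1 px at the chosen
                # supersampling); the exact count varies with axis jitter.
                area = covg * region_px**2
                perim = 2 * np.pi * np.sqrt(area / np.pi)
                npix = max(1, int(round(area - perim)))
            else:
                npix = int(n_pixels)
            for i in range(config.n_per_class):
                offset = _pot_offset(config, seed, cls, i, day)
                prng = _rng(seed, 6, *_class_day_seed_key(cls, i, day))
                pix = prof_base[None, :] + offset
                pix = pix + prng.normal(0.0, config.pixel_noise_sd, size=(npix, 5))
                np.clip(pix, 0.0, 1.0, out=pix)
                band_means = pix.mean(axis=0)
                bandset = {name: pix[:, j] for j, name in enumerate(BAND_NAMES)}
                row = {
                    "sample_id": f"{cls}-{i:03d}",
                    "label": cls,
                    "day": day,
                    "agl": agl,
                    "n_pixels": npix,
                }
                row.update({name: band_means[j] for j, name in enumerate(BAND_NAMES)})
                for vi in VI_NAMES:
                    vals = compute_index(vi, bandset)
                    row[vi] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
                rows.append(row)
    return pd.DataFrame(rows)
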