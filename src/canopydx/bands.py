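"""Band definitions shared across the package.

The multispectral camera modelled here carries five single-band sensors:
blue (450 nm), green (560 nm), red (650 nm), red edge (730 nm) and
near-infrared (850 nm). All reflectances are unitless in [0, 1].
"""

from __future__ import annotations

#: Canonical band order used for every 5-vector / 5-band raster.
BAND_NAMES: tuple[str, ...] = ("B", "G", "R", "RE", "NIR")

#: Band centre wavelengths in nm, for documentation and plotting.
BAND_WAVELENGTHS_NM: dict[str, int] = {
    "B": 450,
    "G": 560,
    "R": 650,
    "RE": 730,
    "NIR": 850,
}

BAND_INDEX: dict[str, int] = {name: i for i, name in enumerate(BAND_NAMES)}
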