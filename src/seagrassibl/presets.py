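"""Published model constants: boundary lines and per-species parameters.

The species table stores the printed calibration values (theta in radians
at printed precision; growth/decay rate bounds in day^-1).  Derived
quantities (tan, sin, cos of theta) are always computed at full precision
from the stored theta.
"""

from __future__ import annotations

from .model import IBLine, SpeciesParams, make_isometric_params

__all__ = ["IBL_PRESETS", "SPECIES_PRESETS", "load_preset", "available_presets"]

#: boundary lines b = beta0 + beta1 * d per taxon group
IBL_PRESETS: dict[str, IBLine] = {
    "seagrass": IBLine(beta0=4.569, beta1=-0.438),
    "plants": IBLine(beta0=4.87, beta1=-0.33),
    "algae": IBLine(beta0=6.69, beta1=-0.67),
}

#: species -> (theta [rad], r_max [day^-1], r_min [day^-1])
_SPECIES_TABLE: dict[str, tuple[float, float, float]] = {
    "C. nodosa": (1.052, 0.029, -0.03),
    "H. wrightii": (1.04, 0.055, -0.075),
    "T. testudinum": (0.948, 0.065, -0.065),
    "Z. japonica": (0.966, 0.04, -0.055),
    "Z. marina": (0.836, 0.043, -0.043),
    "Z. noltii": (0.874, 0.03, -0.025),
}

SPECIES_PRESETS: dict[str, SpeciesParams] = {
    name: SpeciesParams.from_theta(name, theta, r_max=r_max, r_min=r_min)
    for name, (theta, r_max, r_min) in _SPECIES_TABLE.items()
}


def available_presets() -> list[str]:
    """Names accepted by :func:`load_preset`."""
    return [*SPECIES_PRESETS, "H0", *IBL_PRESETS]


def load_preset(name: str) -> SpeciesParams | IBLine:
    """Look up a species, the isometric null model ('H0'), or a boundary line.

    Matching is case-insensitive.  Unknown names raise ``KeyError`` listing
    every available preset.
    """
    lowered = name.strip().lower()
    if lowered == "h0":
        return make_isometric_params()
    for key, params in SPECIES_PRESETS.items():
        if key.lower() == lowered:
            return params
    for key, line in IBL_PRESETS.items():
        if key.lower() == lowered:
            return line
    raise KeyError(
        f"unknown preset {name!r}; available: {', '.join(available_presets())}"
    )
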