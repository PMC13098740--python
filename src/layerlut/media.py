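"""Layered optical media, bundled tissue/phantom presets, and skin-tone classification.

A medium is an ordered top-to-bottom stack of :class:`OpticalLayer` objects above a
semi-infinite bottom layer.  Per-layer absorption (``mua``) and reduced scattering
(``musp``) are stored per wavelength (nm) so that a single medium describes all the
wavelengths used by an instrument; anisotropy ``g``, refractive index ``n`` and the
blood-flow index ``bfi`` are taken as wavelength independent.

Units throughout: lengths in mm, ``mua``/``musp`` in mm^-1, ``bfi`` in mm^2/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "OpticalLayer",
    "LayeredMedium",
    "SkinToneClass",
    "classify_ita",
    "tissue_medium",
    "phantom_medium",
    "homogeneous_medium",
    "default_muscle",
    "FD_WAVELENGTHS",
    "DCS_WAVELENGTH",
    "SKIN_TONES",
]

#: Wavelengths (nm) at which the FD presets tabulate optical properties.
FD_WAVELENGTHS = (730.0, 830.0)
#: DCS laser wavelength (nm).  Optical properties are tabulated at 730/830 nm only;
#: by convention the 830 nm values stand in for 850 nm in the correlation model.
DCS_WAVELENGTH = 850.0

SKIN_TONES = ("light", "medium", "dark")

#: ITA (individual typology angle) thresholds in degrees.  Strictly above the upper
#: threshold is light, strictly below the lower one is dark; the closed interval
#: in between (boundaries included) is medium.
ITA_LIGHT_DEG = 41.0
ITA_DARK_DEG = 10.0


@dataclass(frozen=True)
class OpticalLayer:
    """One tissue or phantom layer.

    ``thickness_mm`` is ``math.inf`` for the semi-infinite bottom layer.  ``mua`` and
    ``musp`` map wavelength (nm) to coefficients in mm^-1.
    """

    name: str
    thickness_mm: float
    mua: dict[float, float]
    musp: dict[float, float]
    g: float
    n: float
    bfi: float = 0.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (self.thickness_mm > 0 or math.isinf(self.thickness_mm)):
            raise ValueError(f"layer {self.name!r}: thickness must be positive")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"layer {self.name!r}: g must be in [0, 1)")
        if self.n < 1.0:
            raise ValueError(f"layer {self.name!r}: n must be >= 1")
        if self.bfi < 0.0:
            raise ValueError(f"layer {self.name!r}: bfi must be >= 0")
        for wl, v in self.mua.items():
            if v < 0:
                raise ValueError(f"layer {self.name!r}: mua({wl}) < 0")
        for wl, v in self.musp.items():
            if v < 0:
                raise ValueError(f"layer {self.name!r}: musp({wl}) < 0")

    @property
    def semi_infinite(self) -> bool:
        return math.isinf(self.thickness_mm)

    def mus(self, wavelength: float) -> float:
        """Scattering coefficient mus = musp / (1 - g) at a wavelength, mm^-1."""
        return self.musp[wavelength] / (1.0 - self.g)

    def with_(self, **kwargs) -> "OpticalLayer":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LayeredMedium:
    """Ordered top-to-bottom stack of layers; exactly the last is semi-infinite."""

    layers: tuple[OpticalLayer, ...]
    ambient_n: float = 1.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("medium needs at least one layer")
        if not self.layers[-1].semi_infinite:
            raise ValueError("the last layer must be semi-infinite")
        for lay in self.layers[:-1]:
            if lay.semi_infinite:
                raise ValueError("only the last layer may be semi-infinite")
        wl0 = self.wavelengths
        for lay in self.layers:
            if tuple(sorted(lay.mua)) != wl0 or tuple(sorted(lay.musp)) != wl0:
                raise ValueError("all layers must tabulate the same wavelengths")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.layers[0].mua))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def simulation_layers(self) -> tuple[OpticalLayer, ...]:
        """Layers with zero-thickness entries dropped (a no-op for transport)."""
        return tuple(l for l in self.layers if l.semi_infinite or l.thickness_mm > 0)

    def property_arrays(self, wavelength: float):
        """Per-layer (thickness, mua, musp, g, n, bfi) lists at one wavelength.

        Zero-thickness layers are dropped.  Raises ``KeyError`` for an
        untabulated wavelength.
        """
        lays = self.simulation_layers()
        thick = [l.thickness_mm for l in lays]
        mua = [l.mua[wavelength] for l in lays]
        musp = [l.musp[wavelength] for l in lays]
        g = [l.g for l in lays]
        n = [l.n for l in lays]
        bfi = [l.bfi for l in lays]
        return thick, mua, musp, g, n, bfi

    def with_bottom(self, **kwargs) -> "LayeredMedium":
        """Return a copy whose bottom layer has fields replaced."""
        new_bottom = self.layers[-1].with_(**kwargs)
        return replace(self, layers=self.layers[:-1] + (new_bottom,))

    def replace_layer(self, index: int, layer: OpticalLayer) -> "LayeredMedium":
        lays = list(self.layers)
        lays[index] = layer
        return replace(self, layers=tuple(lays))

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "ambient_n": self.ambient_n,
            "meta": dict(self.meta),
            "layers": [
                {
                    "name": l.name,
                    "thickness_mm": ("inf" if l.semi_infinite else l.thickness_mm),
                    "mua_per_mm": {f"{wl:g}": v for wl, v in sorted(l.mua.items())},
                    "musp_per_mm": {f"{wl:g}": v for wl, v in sorted(l.musp.items())},
                    "g": l.g,
                    "n": l.n,
                    "bfi_mm2_per_s": l.bfi,
                }
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayeredMedium":
        layers = tuple(
            OpticalLayer(
                name=ld["name"],
                thickness_mm=(math.inf if ld["thickness_mm"] == "inf" else float(ld["thickness_mm"])),
                mua={float(k): float(v) for k, v in ld["mua_per_mm"].items()},
                musp={float(k): float(v) for k, v in ld["musp_per_mm"].items()},
                g=float(ld["g"]),
                n=float(ld["n"]),
                bfi=float(ld.get("bfi_mm2_per_s", 0.0)),
            )
            for ld in d["layers"]
        )
        return cls(layers=layers, ambient_n=float(d.get("ambient_n", 1.0)), meta=dict(d.get("meta", {})))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LayeredMedium":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SkinToneClass:
    """Categorical skin tone (light / medium / dark), optionally carrying the ITA."""

    label: str
    ita_deg: float | None = None

    def __post_init__(self) -> None:
        if self.label not in SKIN_TONES:
            raise ValueError(f"unknown skin tone label {self.label!r}")
        if self.ita_deg is not None:
            if not math.isfinite(self.ita_deg):
                raise ValueError("ita_deg must be finite")
            if _label_for_ita(self.ita_deg) != self.label:
                raise ValueError(
                    f"label {self.label!r} inconsistent with ITA {self.ita_deg} deg"
                )


def _label_for_ita(ita_deg: float) -> str:
    if ita_deg > ITA_LIGHT_DEG:
        return "light"
    if ita_deg < ITA_DARK_DEG:
        return "dark"
    return "medium"


def classify_ita(ita_deg: float) -> SkinToneClass:
    """Classify an individual typology angle (degrees) into light/medium/dark.

    ITA > 41 deg is light and ITA < 10 deg is dark; everything in the closed
    interval [10, 41] (boundaries included) is medium.
    """
    ita_deg = float(ita_deg)
    if not math.isfinite(ita_deg):
        raise ValueError("ITA must be a finite number of degrees")
    return SkinToneClass(label=_label_for_ita(ita_deg), ita_deg=ita_deg)


# ---------------------------------------------------------------------------
# Tissue presets (skin tone dependent skin layer, adipose, muscle).
# Skin optical properties derive from spatial-frequency-domain-imaging surveys
# keyed to Fitzpatrick bands (<16 light, 16-26 medium, >26 dark), carried here
# as provenance metadata; runtime classification is by ITA.
# ---------------------------------------------------------------------------

_TISSUE_SKIN = {
    # tone: (mua730, mua830, musp730, musp830)
    "light": (0.019, 0.006, 1.34, 1.17),
    "medium": (0.051, 0.017, 1.34, 1.17),
    "dark": (0.149, 0.044, 1.34, 1.17),
}
_TISSUE_SKIN_G = 0.9
_TISSUE_SKIN_N = 1.40
#: Baseline BFi of upper subcutaneous tissue (skin + adipose), mm^2/s.
SUBCUTANEOUS_BFI = 0.6e-6

_TISSUE_ADIPOSE = (0.010, 0.010, 1.19, 1.09)
_TISSUE_ADIPOSE_G = 0.9
_TISSUE_ADIPOSE_N = 1.44

_TISSUE_MUSCLE_G = 0.9
_TISSUE_MUSCLE_N = 1.38

_FITZPATRICK_BAND = {"light": "<16", "medium": "16-26", "dark": ">26"}


def default_muscle(
    mua_730: float = 0.020,
    mua_830: float = 0.020,
    musp_730: float = 0.65,
    musp_830: float = 0.60,
    bfi: float = 5.0e-6,
) -> OpticalLayer:
    """A representative resting skeletal-muscle bottom layer.

    The inverse-model axes span mua 0.01-0.2 mm^-1, musp 0.1-1.0 mm^-1 and
    BFi 0.1-40e-6 mm^2/s; these defaults sit in the interior of those ranges at
    values typical of resting muscle oximetry (total [Hb+Mb] ~ 100 uM, StO2 ~ 65%).
    """
    return OpticalLayer(
        name="muscle",
        thickness_mm=math.inf,
        mua={730.0: mua_730, 830.0: mua_830},
        musp={730.0: musp_730, 830.0: musp_830},
        g=_TISSUE_MUSCLE_G,
        n=_TISSUE_MUSCLE_N,
        bfi=bfi,
    )


def homogeneous_medium(
    n: float = 1.4,
    g: float = 0.9,
    mua_730: float = 0.02,
    mua_830: float = 0.02,
    musp_730: float = 0.6,
    musp_830: float = 0.6,
    bfi: float = 1e-6,
    ambient_n: float = 1.0,
) -> LayeredMedium:
    """Single semi-infinite layer, the template for single-layer inverse models.

    The mua/musp values are placeholders: LUT building sweeps the bottom (here
    the only) layer's musp and fills the mua axis by reweighting.
    """
    layer = OpticalLayer(
        name="homogeneous",
        thickness_mm=math.inf,
        mua={730.0: mua_730, 830.0: mua_830},
        musp={730.0: musp_730, 830.0: musp_830},
        g=g,
        n=n,
        bfi=bfi,
    )
    return LayeredMedium(
        layers=(layer,), ambient_n=ambient_n, meta={"kind": "homogeneous"}
    )


def _as_tone_label(skin_tone) -> str:
    if isinstance(skin_tone, SkinToneClass):
        return skin_tone.label
    label = str(skin_tone)
    if label not in SKIN_TONES:
        raise ValueError(f"unknown skin tone label {label!r}")
    return label


def tissue_medium(
    skin_tone,
    adipose_thickness_mm: float,
    muscle_layer: OpticalLayer | None = None,
    ambient_n: float = 1.0,
) -> LayeredMedium:
    """Three-layer in-vivo medium: 1 mm skin (tone-dependent), adipose, muscle.

    ``adipose_thickness_mm`` outside [0, 6] mm is accepted with a warning (the
    preset tables were assembled for thicknesses up to 6 mm).
    """
    label = _as_tone_label(skin_tone)
    adipose_thickness_mm = float(adipose_thickness_mm)
    if adipose_thickness_mm < 0:
        raise ValueError("adipose thickness must be >= 0 mm")
    if adipose_thickness_mm > 6.0:
        warnings.warn(
            f"adipose thickness {adipose_thickness_mm} mm is outside the tabulated 0-6 mm range",
            stacklevel=2,
        )
    a730, a830, s730, s830 = _TISSUE_SKIN[label]
    skin = OpticalLayer(
        name=f"skin_{label}",
        thickness_mm=1.0,
        mua={730.0: a730, 830.0: a830},
        musp={730.0: s730, 830.0: s830},
        g=_TISSUE_SKIN_G,
        n=_TISSUE_SKIN_N,
        bfi=SUBCUTANEOUS_BFI,
        meta={"fitzpatrick_band": _FITZPATRICK_BAND[label]},
    )
    layers = [skin]
    if adipose_thickness_mm > 0:
        m730, m830, sp730, sp830 = _TISSUE_ADIPOSE
        layers.append(
            OpticalLayer(
                name="adipose",
                thickness_mm=adipose_thickness_mm,
                mua={730.0: m730, 830.0: m830},
                musp={730.0: sp730, 830.0: sp830},
                g=_TISSUE_ADIPOSE_G,
                n=_TISSUE_ADIPOSE_N,
                bfi=SUBCUTANEOUS_BFI,
            )
        )
    layers.append(muscle_layer if muscle_layer is not None else default_muscle())
    return LayeredMedium(
        layers=tuple(layers),
        ambient_n=ambient_n,
        meta={"kind": "tissue", "skin_tone": label, "adipose_thickness_mm": adipose_thickness_mm},
    )


# ---------------------------------------------------------------------------
# Phantom presets (silicone skin/adipose mimics; silicone or intralipid bottom).
# ---------------------------------------------------------------------------

_PHANTOM_SKIN = {
    # tone: (mua730, mua830, musp730, musp830)
    "light": (0.010, 0.007, 1.62, 1.27),
    "medium": (0.059, 0.040, 1.36, 1.09),
    "dark": (0.106, 0.073, 0.78, 0.60),
}
_PHANTOM_ADIPOSE = (0.008, 0.006, 1.49, 1.27)
_PHANTOM_G = 0.9
_PHANTOM_N = 1.4
_PHANTOM_BOTTOMS = {
    # label: (nominal thickness mm, mua730, mua830, musp730, musp830, g, n, bfi)
    "silicone_muscle": (30.0, 0.041, 0.072, 0.42, 0.38, 0.9, 1.4, 0.0),
    "intralipid_muscle": (50.0, 0.007, 0.006, 0.40, 0.34, 0.61, 1.37, 1.05e-6),
}
#: Thin-phantom slab thicknesses available for stacking (mm).
PHANTOM_SLAB_MM = (1.0, 2.0, 4.0)


def _stackable(thickness: float) -> bool:
    """Whether a thickness is composable from 1/2/4 mm slabs (i.e. a positive integer)."""
    return thickness > 0 and abs(thickness - round(thickness)) < 1e-9


def phantom_medium(
    skin_phantom_tone,
    adipose_thickness_mm: float,
    bottom: str = "silicone_muscle",
    ambient_n: float = 1.0,
) -> LayeredMedium:
    """Stacked-phantom medium: 1 mm skin mimic, adipose mimic, bulk bottom phantom.

    All silicone layers carry BFi = 0; the intralipid bottom carries its measured
    Brownian BFi.  The bottom slab is modelled as semi-infinite (its nominal
    physical thickness is kept as metadata).
    """
    label = _as_tone_label(skin_phantom_tone)
    if bottom not in _PHANTOM_BOTTOMS:
        raise ValueError(f"unknown bottom phantom {bottom!r}")
    adipose_thickness_mm = float(adipose_thickness_mm)
    if adipose_thickness_mm < 0:
        raise ValueError("adipose thickness must be >= 0 mm")
    if adipose_thickness_mm > 0 and not _stackable(adipose_thickness_mm):
        warnings.warn(
            f"adipose thickness {adipose_thickness_mm} mm is not composable from "
            f"{PHANTOM_SLAB_MM} mm slabs; accepted as an idealized stack",
            stacklevel=2,
        )
    a730, a830, s730, s830 = _PHANTOM_SKIN[label]
    layers = [
        OpticalLayer(
            name=f"skin_phantom_{label}",
            thickness_mm=1.0,
            mua={730.0: a730, 830.0: a830},
            musp={730.0: s730, 830.0: s830},
            g=_PHANTOM_G,
            n=_PHANTOM_N,
            bfi=0.0,
        )
    ]
    if adipose_thickness_mm > 0:
        m730, m830, sp730, sp830 = _PHANTOM_ADIPOSE
        layers.append(
            OpticalLayer(
                name="adipose_phantom",
                thickness_mm=adipose_thickness_mm,
                mua={730.0: m730, 830.0: m830},
                musp={730.0: sp730, 830.0: sp830},
                g=_PHANTOM_G,
                n=_PHANTOM_N,
                bfi=0.0,
            )
        )
    nominal, b730, b830, bs730, bs830, bg, bn, bbfi = _PHANTOM_BOTTOMS[bottom]
    layers.append(
        OpticalLayer(
            name=bottom,
            thickness_mm=math.inf,
            mua={730.0: b730, 830.0: b830},
            musp={730.0: bs730, 830.0: bs830},
            g=bg,
            n=bn,
            bfi=bbfi,
            meta={"nominal_thickness_mm": nominal},
        )
    )
    return LayeredMedium(
        layers=tuple(layers),
        ambient_n=ambient_n,
        meta={
            "kind": "phantom",
            "skin_tone": label,
            "adipose_thickness_mm": adipose_thickness_mm,
            "bottom": bottom,
        },
    )
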