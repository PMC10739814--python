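"""Scene descriptions for the synthetic measurement campaign.

A scene is a named list of source components with an exposure time.  The
presets emulate the experimental conditions of a thermal-neutron field
imaging study: a B4C target emitting 478 keV boron-capture prompt gammas
(PGs) at one of three lateral positions 130 mm in front of the camera,
plus the persistent backgrounds seen by the instrument --

* ``AG``        511 keV annihilation gammas from the room,
* ``Cd558``     558 keV line from neutron capture on Cd inside the camera,
* ``PCB478``    478 keV PGs from boron in the camera's own circuit boards,
* ``continuum`` a smooth scattered-gamma continuum,
* ``H2200``     2.2 MeV hydrogen-capture line (water-tank scene only).

Component intensities are phenomenological presets (events recorded by the
camera per second), not transport predictions; they are fixed so that a 2 h
acquisition yields selected-event totals of a few thousand and so that the
PG signal weakens as the target moves to larger X (the thermal flux falls
along +X).

This module also carries the closed-form worked quantities of the study:
the natural-abundance B-10 mass of a B4C target, the PG branching draw, and
the clinical treatment-time equivalence of the bench exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Spatial",
    "SourceComponent",
    "Scene",
    "preset_scene",
    "PRESET_NAMES",
    "b10_mass",
    "equivalent_treatment_time",
    "simulate_capture_emissions",
]

# isotopic / atomic masses, u
M_B10 = 10.013
M_B11 = 11.009
M_C = 12.011

#: natural B-10 number abundance used throughout
NATURAL_B10_ABUNDANCE = 0.200

#: 478 keV prompt-gamma emission probability per capture
PG_BRANCHING = 0.94


@dataclass(frozen=True)
class Spatial:
    """Spatial emission distribution of a component.

    kind: "point" | "box" | "cylinder" | "internal_camera".
    ``center`` mm; ``half_sizes`` (box) mm; ``radius``/``height`` (cylinder,
    axis along z) mm.  ``internal_camera`` samples uniformly inside the
    detector stack volume (resolved against the camera geometry at
    generation time).
    """

    kind: str
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    half_sizes: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.0
    height: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"point", "box", "cylinder", "internal_camera"}:
            raise ValueError(f"unknown spatial kind {self.kind!r}")
        if self.kind == "box" and min(self.half_sizes) <= 0:
            raise ValueError("box half-sizes must be positive")
        if self.kind == "cylinder" and (self.radius <= 0 or self.height <= 0):
            raise ValueError("cylinder dimensions must be positive")


@dataclass(frozen=True)
class SourceComponent:
    """One emission component of a scene.

    ``line_kev`` is the emission-line energy for line components; continuum
    components instead carry ``e_range`` (uniform total-energy range, keV)
    and ``line_kev = None``.  ``intensity`` is the expected rate of recorded
    two-hit events from this component (1/s).  ``intrinsic_fwhm`` broadens
    the line before detector response (keV; 0 = none).
    """

    label: str
    spatial: Spatial
    intensity: float
    line_kev: float | None = None
    e_range: tuple[float, float] | None = None
    intrinsic_fwhm: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if (self.line_kev is None) == (self.e_range is None):
            raise ValueError("exactly one of line_kev / e_range must be set")


@dataclass(frozen=True)
class Scene:
    name: str
    components: tuple[SourceComponent, ...]
    exposure_s: float = 7200.0
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("scene needs at least one component")
        if self.exposure_s <= 0:
            raise ValueError("exposure must be positive")

    def component(self, label: str) -> SourceComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(label)

    def has_component(self, label: str) -> bool:
        return any(c.label == label for c in self.components)

    def without(self, label: str) -> "Scene":
        comps = tuple(c for c in self.components if c.label != label)
        return replace(self, components=comps)

    def with_exposure(self, exposure_s: float) -> "Scene":
        return replace(self, exposure_s=exposure_s)


# --------------------------------------------------------------------------
# preset scenes
# --------------------------------------------------------------------------

#: target plane distance from the first scatterer, mm
TARGET_Z = 130.0

#: relative thermal-flux factor at target X = -120 / -20 / +80 mm
FLUX_FACTORS = {-120.0: 1.0, -20.0: 0.8, 80.0: 0.12}

# base intensities, recorded events / s (phenomenological presets)
_PG_BASE = 0.22
_AG_RATE = 1.5
_CD_RATE = 1.0
_PCB_RATE = 0.23
_CONTINUUM_RATE = 18.0
_H2200_RATE = 2.0
_GRAPHITE_CONTINUUM_BOOST = 1.005
_GRAPHITE_PCB_BOOST = 1.0
_WATER_CONTINUUM_BOOST = 1.2
_WATER_PG_RATE = 0.15

CONTINUUM_RANGE = (300.0, 600.0)

PRESET_NAMES = (
    "b4c_x-12",
    "b4c_x-2",
    "b4c_x8",
    "graphite",
    "no_target",
    "water_tank",
)


def _backgrounds(
    continuum_scale: float = 1.0, pcb_scale: float = 1.0
) -> tuple[SourceComponent, ...]:
    internal = Spatial("internal_camera")
    return (
        SourceComponent(
            "AG",
            Spatial("box", center=(0.0, 0.0, TARGET_Z), half_sizes=(150.0, 80.0, 80.0)),
            _AG_RATE,
            line_kev=511.0,
        ),
        SourceComponent("Cd558", internal, _CD_RATE, line_kev=558.0),
        SourceComponent("PCB478", internal, _PCB_RATE * pcb_scale, line_kev=478.0),
        SourceComponent(
            "continuum",
            internal,
            _CONTINUUM_RATE * continuum_scale,
            e_range=CONTINUUM_RANGE,
        ),
    )


def _b4c_scene(x_mm: float) -> Scene:
    name = f"b4c_x{x_mm / 10:+.0f}".replace("+", "")
    target = SourceComponent(
        "PG_target",
        Spatial("cylinder", center=(x_mm, 0.0, TARGET_Z), radius=25.0, height=60.0),
        _PG_BASE * FLUX_FACTORS[x_mm],
        line_kev=478.0,
    )
    return Scene(
        name=name,
        components=(target,) + _backgrounds(),
        notes=f"100 g B4C cylinder at X = {x_mm / 10:.0f} cm, Z = 13 cm",
    )


def preset_scene(name: str) -> Scene:
    """Return one of the six preset scenes (2 h exposure each).

    Raises ``KeyError`` listing the presets for an unknown name.
    """
    if name == "b4c_x-12":
        return _b4c_scene(-120.0)
    if name == "b4c_x-2":
        return _b4c_scene(-20.0)
    if name == "b4c_x8":
        return _b4c_scene(80.0)
    if name == "no_target":
        return Scene(
            name="no_target",
            components=_backgrounds(),
            notes="backgrounds only",
        )
    if name == "graphite":
        return Scene(
            name="graphite",
            components=_backgrounds(
                _GRAPHITE_CONTINUUM_BOOST, _GRAPHITE_PCB_BOOST
            ),
            notes="graphite scatter block at X = -2 cm: backgrounds plus a "
            "slight scattered-continuum increase, no PG emission",
        )
    if name == "water_tank":
        target = SourceComponent(
            "PG_target",
            Spatial(
                "box", center=(-20.0, 0.0, TARGET_Z), half_sizes=(3.5, 48.0, 11.0)
            ),
            _WATER_PG_RATE,
            line_kev=478.0,
        )
        h2200 = SourceComponent(
            "H2200",
            Spatial(
                "box", center=(0.0, 0.0, TARGET_Z), half_sizes=(50.0, 50.0, 50.0)
            ),
            _H2200_RATE,
            line_kev=2200.0,
        )
        return Scene(
            name="water_tank",
            components=(target, h2200) + _backgrounds(_WATER_CONTINUUM_BOOST),
            notes="20 g B4C slab submerged in a 10 cm water cube",
        )
    raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


# --------------------------------------------------------------------------
# closed-form worked quantities
# --------------------------------------------------------------------------

def b10_mass(
    total_mass_g: float,
    compound: str = "B4C",
    abundance_number_fraction: float = NATURAL_B10_ABUNDANCE,
) -> float:
    """Mass of B-10 in ``total_mass_g`` of boron carbide.

    The mass fraction is the product of the boron mass fraction of B4C and
    the B-10 mass fraction of natural boron:

        f = [4 m(B)/(4 m(B) + m(C))] * [a m(10B) / (a m(10B) + (1-a) m(11B))]

    with m(B) the abundance-weighted mean boron mass and ``a`` the B-10
    number abundance.  At natural abundance (a = 0.200) this gives 14.5 g of
    B-10 per 100 g of B4C.
    """
    if total_mass_g <= 0:
        raise ValueError("total mass must be positive")
    if not 0.0 <= abundance_number_fraction <= 1.0:
        raise ValueError("abundance must lie in [0, 1]")
    if compound != "B4C":
        raise ValueError("only B4C is supported")
    a = abundance_number_fraction
    m_b = a * M_B10 + (1.0 - a) * M_B11
    boron_fraction = 4.0 * m_b / (4.0 * m_b + M_C)
    b10_of_boron = a * M_B10 / m_b if a > 0 else 0.0
    return total_mass_g * boron_fraction * b10_of_boron


def equivalent_treatment_time(
    exp_flux: float,
    exp_b10_g: float,
    exp_duration_s: float,
    clin_flux: float = 1e9,
    clin_ppm: float = 80.0,
    clin_volume_cm3: float = 100.0,
    tissue_density_g_cm3: float = 1.0,
) -> float:
    """Clinical seconds producing as many capture reactions as the bench run.

    The capture count is taken proportional to (thermal flux) x (B-10 mass);
    clinically the B-10 mass is concentration (ppm by weight) x tumour mass.
    The defaults describe a typical treatment (1e9 n/cm2/s, 80 ppm, 100 cm3):
    a bench exposure of 1e3 n/cm2/s on 1 g of B-10 for 7200 s is then worth
    about one second of treatment.
    """
    args = (
        exp_flux,
        exp_b10_g,
        exp_duration_s,
        clin_flux,
        clin_ppm,
        clin_volume_cm3,
        tissue_density_g_cm3,
    )
    if min(args) <= 0:
        raise ValueError("all arguments must be positive")
    clin_b10_g = clin_ppm * 1e-6 * clin_volume_cm3 * tissue_density_g_cm3
    return (exp_flux * exp_b10_g * exp_duration_s) / (clin_flux * clin_b10_g)


def simulate_capture_emissions(
    n_captures: int,
    branching: float = PG_BRANCHING,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Number of captures (out of ``n_captures``) that emit a 478 keV PG.

    A single binomial draw with the PG branching probability (default 94%).
    """
    if not 0.0 <= branching <= 1.0:
        raise ValueError("branching must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return int(rng.binomial(int(n_captures), branching))
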