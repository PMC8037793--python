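"""Aneurysm morphometry, coil volume and packing-density calculations.

The clinical predictor studied here is the *first coil volume packing
density* (1st VPD): the fraction of the aneurysm sac volume occupied by the
first embolization coil, expressed as a percentage.  The aneurysm volume is
approximated from caliper measurements on angiograms with a shape-specific
closed form (sphere, ellipsoid, or sum of two ellipsoidal lobes), and each
coil is treated as a cylinder of wire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

MM_PER_INCH = 25.4


class AneurysmShape(str, Enum):
    SPHERICAL = "spherical"
    ELLIPSOID = "ellipsoid"
    BILOBED = "bilobed"


@dataclass(frozen=True)
class AneurysmMorphometry:
    """Caliper measurements of a saccular aneurysm, all lengths in mm.

    Parameters
    ----------
    height_H : dome height
    width_S : dome width
    depth_D : dome depth
    neck_N : neck width
    parent_P : parent-artery diameter
    hmax : largest dome dimension perpendicular to the neck
    shape : sac shape class used to pick the volume formula
    bilobed_components : per-lobe ``(diameter, height)`` pairs, required for
        bilobed sacs
    """

    height_H: float
    width_S: float
    depth_D: float
    neck_N: float
    parent_P: float
    hmax: float
    shape: AneurysmShape = AneurysmShape.SPHERICAL
    bilobed_components: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        for name in ("height_H", "width_S", "depth_D", "neck_N", "parent_P"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be positive, got {value!r}")
        if self.hmax < 0:
            raise ValueError(f"hmax must be non-negative, got {self.hmax!r}")
        if self.shape is AneurysmShape.BILOBED:
            if not self.bilobed_components:
                raise ValueError("bilobed shape requires bilobed_components")
            for d, h in self.bilobed_components:
                if d <= 0 or h <= 0:
                    raise ValueError(
                        f"bilobed_components entries must be positive, got ({d}, {h})"
                    )


@dataclass(frozen=True)
class CoilSpec:
    """A single embolization coil: wire diameter (inches) and length (mm)."""

    wire_diameter_inch: float
    length_mm: float
    is_first_coil: bool = False

    def __post_init__(self) -> None:
        if self.wire_diameter_inch <= 0:
            raise ValueError(
                f"wire_diameter_inch must be positive, got {self.wire_diameter_inch!r}"
            )
        if self.length_mm < 0:
            raise ValueError(f"length_mm must be non-negative, got {self.length_mm!r}")

    @property
    def wire_diameter_mm(self) -> float:
        return self.wire_diameter_inch * MM_PER_INCH


@dataclass(frozen=True)
class PackingResult:
    aneurysm_volume_mm3: float
    total_coil_volume_mm3: float
    first_coil_volume_mm3: float
    packing_density_pct: float
    first_vpd_pct: float


@dataclass(frozen=True)
class MorphometricIndices:
    aspect_ratio_AR: float
    size_ratio_SR: float
    neck_parent_ratio: float


def _ellipsoid_volume(diameter: float, height: float) -> float:
    return math.pi * diameter**2 * height / 6.0


def aneurysm_volume(morph: AneurysmMorphometry) -> float:
    """Sac volume in mm³ from the shape-specific closed form.

    Spherical sacs use pi*d^3/6 with d the largest of (H, S, D); ellipsoid
    sacs use pi*d^2*h/6 with d = max(S, D) and h = H; bilobed sacs sum the
    ellipsoid formula over the two measured lobes.
    """
    if morph.shape is AneurysmShape.SPHERICAL:
        d = max(morph.height_H, morph.width_S, morph.depth_D)
        return math.pi * d**3 / 6.0
    if morph.shape is AneurysmShape.ELLIPSOID:
        d = max(morph.width_S, morph.depth_D)
        return _ellipsoid_volume(d, morph.height_H)
    assert morph.bilobed_components is not None
    return sum(_ellipsoid_volume(d, h) for d, h in morph.bilobed_components)


def coil_volume(spec: CoilSpec) -> float:
    """Cylindrical wire volume pi*d^2*L/4 in mm³ (d converted inch -> mm)."""
    d = spec.wire_diameter_mm
    return math.pi * d**2 * spec.length_mm / 4.0


def packing_metrics(
    aneurysm_volume_mm3: float, coils: Sequence[CoilSpec]
) -> PackingResult:
    """Packing density and 1st VPD (both %) for a coil set in a given sac.

    PD = 100 * (sum of coil volumes) / sac volume;
    1st VPD = 100 * (first-coil volume) / sac volume.

    Exactly one coil must be flagged ``is_first_coil`` when the list is
    non-empty.
    """
    if not (aneurysm_volume_mm3 > 0):
        raise ValueError(
            f"aneurysm_volume_mm3 must be positive, got {aneurysm_volume_mm3!r}"
        )
    coils = list(coils)
    n_first = sum(1 for c in coils if c.is_first_coil)
    if coils and n_first != 1:
        raise ValueError(
            f"exactly one coil must be flagged is_first_coil, found {n_first}"
        )
    total = sum(coil_volume(c) for c in coils)
    first = sum(coil_volume(c) for c in coils if c.is_first_coil)
    return PackingResult(
        aneurysm_volume_mm3=aneurysm_volume_mm3,
        total_coil_volume_mm3=total,
        first_coil_volume_mm3=first,
        packing_density_pct=100.0 * total / aneurysm_volume_mm3,
        first_vpd_pct=100.0 * first / aneurysm_volume_mm3,
    )


def first_coil_length_for_vpd(
    target_vpd_pct: float, aneurysm_volume_mm3: float, wire_diameter_inch: float
) -> float:
    """Coil length (mm) needed to reach a target 1st VPD in a given sac.

    Inverts the cylinder-volume and packing-density formulas; useful for
    translating the clinical 1st VPD cut-off into an intraoperative coil
    length for a measured sac.
    """
    if target_vpd_pct < 0:
        raise ValueError("target_vpd_pct must be non-negative")
    if aneurysm_volume_mm3 <= 0:
        raise ValueError("aneurysm_volume_mm3 must be positive")
    d = wire_diameter_inch * MM_PER_INCH
    if d <= 0:
        raise ValueError("wire_diameter_inch must be positive")
    target_volume = target_vpd_pct / 100.0 * aneurysm_volume_mm3
    return target_volume / (math.pi * d**2 / 4.0)


def morphometric_indices(morph: AneurysmMorphometry) -> MorphometricIndices:
    """Aspect ratio (Hmax/N), size ratio (H/P) and neck/parent ratio (N/P)."""
    if morph.neck_N <= 0 or morph.parent_P <= 0:
        raise ValueError("neck_N and parent_P must be positive")
    return MorphometricIndices(
        aspect_ratio_AR=morph.hmax / morph.neck_N,
        size_ratio_SR=morph.height_H / morph.parent_P,
        neck_parent_ratio=morph.neck_N / morph.parent_P,
    )
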