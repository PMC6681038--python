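"""Exact-mass algebra for PMP-labelled monosaccharides.

Reducing sugars condense with two molecules of 1-phenyl-3-methyl-5-pyrazolone
(PMP, C10H10N2O) at the anomeric carbon, releasing one water.  The resulting
bis-PMP derivative ionizes by protonation, so the quasimolecular ion is

    m/z([M+H]+) = M(sugar) + 2 M(PMP) - M(H2O) + m(proton)

with all masses monoisotopic.  Common monosaccharides fall into six mass
classes (hexose, hexosamine, pentose, tetrose, methylpentose, hexuronic
acid); within a class the derivatives are isobaric and must be separated
chromatographically.

This module holds the elemental-composition arithmetic, the atomic-mass
constants, and the ppm-error bookkeeping that every other module builds on.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ElementalComposition",
    "SugarClassSpec",
    "MASS_H",
    "MASS_C",
    "MASS_N",
    "MASS_O",
    "MASS_PROTON",
    "PMP",
    "WATER",
    "AMMONIA",
    "FORMALDEHYDE",
    "SUGAR_CLASSES",
    "sugar_class",
    "monoisotopic_mass",
    "derivative_neutral",
    "derivative_mz",
    "ppm_error",
    "round_half_up",
]

# Monoisotopic atomic masses (Da), CODATA/IUPAC.  Single source of truth for
# every m/z computed in this package.  The proton mass is distinct from the
# hydrogen-atom mass (electron mass matters at the fourth decimal of m/z).
MASS_H = 1.00782503207
MASS_C = 12.0
MASS_N = 14.0030740048
MASS_O = 15.9949146196
MASS_PROTON = 1.007276466879


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as analytical reports conventionally do.

    Python's built-in ``round`` is banker's rounding; reported m/z, ppm and
    percentage values here use half-up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts over C, H, N, O.

    Supports element-wise addition, subtraction (which must not go
    negative -- a fragment cannot lose atoms it does not have) and
    non-negative integer scaling.
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0

    def __post_init__(self) -> None:
        for el in ("c", "h", "n", "o"):
            v = getattr(self, el)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"atom count {el}={v!r} must be a non-negative integer")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return ElementalComposition(self.c + other.c, self.h + other.h,
                                    self.n + other.n, self.o + other.o)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return ElementalComposition(self.c - other.c, self.h - other.h,
                                    self.n - other.n, self.o - other.o)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int):
            return NotImplemented
        if k < 0:
            raise ValueError("scaling factor must be non-negative")
        return ElementalComposition(self.c * k, self.h * k, self.n * k, self.o * k)

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def formula(self) -> str:
        parts = []
        for el, count in (("C", self.c), ("H", self.h), ("N", self.n), ("O", self.o)):
            if count == 1:
                parts.append(el)
            elif count > 1:
                parts.append(f"{el}{count}")
        return "".join(parts) or "(empty)"


# Recurring neutral species.
PMP = ElementalComposition(c=10, h=10, n=2, o=1)
WATER = ElementalComposition(h=2, o=1)
AMMONIA = ElementalComposition(h=3, n=1)
FORMALDEHYDE = ElementalComposition(c=1, h=2, o=1)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass in Da: sum of atom counts times atomic masses."""
    return (comp.c * MASS_C + comp.h * MASS_H
            + comp.n * MASS_N + comp.o * MASS_O)


@dataclass(frozen=True)
class SugarClassSpec:
    """One of the six monosaccharide mass classes.

    ``base_composition`` is the free (underivatized) sugar; ``carbon_count``
    is the backbone length, which controls which C-C cleavage fragments a
    derivative can produce.
    """

    class_name: str
    base_composition: ElementalComposition
    carbon_count: int

    def __post_init__(self) -> None:
        if self.carbon_count not in (4, 5, 6):
            raise ValueError(f"carbon_count must be 4, 5 or 6, got {self.carbon_count}")


SUGAR_CLASSES: dict[str, SugarClassSpec] = {
    "hexose": SugarClassSpec("hexose", ElementalComposition(6, 12, 0, 6), 6),
    "hexosamine": SugarClassSpec("hexosamine", ElementalComposition(6, 13, 1, 5), 6),
    "pentose": SugarClassSpec("pentose", ElementalComposition(5, 10, 0, 5), 5),
    "tetrose": SugarClassSpec("tetrose", ElementalComposition(4, 8, 0, 4), 4),
    "methylpentose": SugarClassSpec("methylpentose", ElementalComposition(6, 12, 0, 5), 6),
    "hexuronic_acid": SugarClassSpec("hexuronic_acid", ElementalComposition(6, 10, 0, 7), 6),
}


def sugar_class(name: str) -> SugarClassSpec:
    try:
        return SUGAR_CLASSES[name]
    except KeyError:
        raise ValueError(
            f"unknown sugar class {name!r}; known: {sorted(SUGAR_CLASSES)}"
        ) from None


def derivative_neutral(spec: SugarClassSpec, labels: int = 2) -> ElementalComposition:
    """Composition of the neutral bis-PMP derivative (sugar + 2 PMP - H2O)."""
    if labels != 2:
        raise ValueError("only bis-PMP derivatives are modelled (labels must be 2)")
    return spec.base_composition + labels * PMP - WATER


def derivative_mz(spec: SugarClassSpec, labels: int = 2) -> float:
    """Theoretical [M+H]+ m/z of the bis-PMP derivative, full precision.

    Round to 4 decimals for display; round to integer for the nominal
    class ions (511, 510, 481, 451, 495, 525).
    """
    return monoisotopic_mass(derivative_neutral(spec, labels)) + MASS_PROTON


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6
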