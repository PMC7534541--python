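"""Crystallographic core: wavelength/angle/momentum-transfer conversions,
d-spacings, systematic absences and reflection-list generation.

Powder peak positions follow from the unit cell alone.  With the scattering
angle ``2θ``, wavelength ``λ`` (Å) and momentum transfer ``s = 4π sin(θ)/λ``
(Å⁻¹), a lattice-plane family ``(hkl)`` of spacing ``d`` diffracts at
``s = 2π/d``.  Only four space groups are required by the screening
application (the tetragonal groups P4₁2₁2, P42₁2, P4₂2₁2 and hexagonal
P6₅22), plus any primitive group without translational symmetry elements as
a "no conditions" fallback; full 230-group machinery is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import gemmi
import numpy as np

__all__ = [
    "HC_KEV_ANGSTROM",
    "LatticeSystem",
    "UnitCell",
    "SpaceGroupRules",
    "Reflection",
    "wavelength_from_energy",
    "s_from_two_theta",
    "two_theta_from_s",
    "d_from_s",
    "s_from_d",
    "two_theta_from_d",
    "d_spacing",
    "is_systematically_absent",
    "generate_reflections",
    "reflections_to_table",
]

#: Conversion constant, E [keV] x lambda [Å] = hc.
HC_KEV_ANGSTROM = 12.3984


class LatticeSystem(str, Enum):
    TETRAGONAL = "tetragonal"
    HEXAGONAL = "hexagonal"
    ORTHORHOMBIC = "orthorhombic"
    CUBIC = "cubic"


_SYSTEM_ANGLES = {
    LatticeSystem.TETRAGONAL: (90.0, 90.0, 90.0),
    LatticeSystem.ORTHORHOMBIC: (90.0, 90.0, 90.0),
    LatticeSystem.CUBIC: (90.0, 90.0, 90.0),
    LatticeSystem.HEXAGONAL: (90.0, 90.0, 120.0),
}


@dataclass(frozen=True)
class UnitCell:
    """A unit cell restricted to the lattice systems the pipeline supports.

    Lengths ``a, b, c`` in Å, angles in degrees.  The constructor enforces
    the metric constraints of the declared system (tetragonal/hexagonal
    ``a = b``, cubic ``a = b = c``, fixed angles).
    """

    system: LatticeSystem
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        system = LatticeSystem(self.system)
        object.__setattr__(self, "system", system)
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("lattice lengths must be positive")
        angles = _SYSTEM_ANGLES[system]
        if not np.allclose((self.alpha, self.beta, self.gamma), angles):
            raise ValueError(f"{system.value} cell requires angles {angles}")
        if system in (LatticeSystem.TETRAGONAL, LatticeSystem.HEXAGONAL):
            if not math.isclose(self.a, self.b, rel_tol=1e-9):
                raise ValueError(f"{system.value} cell requires a = b")
        if system is LatticeSystem.CUBIC:
            if not (math.isclose(self.a, self.b) and math.isclose(self.b, self.c)):
                raise ValueError("cubic cell requires a = b = c")

    @classmethod
    def tetragonal(cls, a: float, c: float) -> "UnitCell":
        return cls(LatticeSystem.TETRAGONAL, a, a, c)

    @classmethod
    def hexagonal(cls, a: float, c: float) -> "UnitCell":
        return cls(LatticeSystem.HEXAGONAL, a, a, c, 90.0, 90.0, 120.0)

    @classmethod
    def orthorhombic(cls, a: float, b: float, c: float) -> "UnitCell":
        return cls(LatticeSystem.ORTHORHOMBIC, a, b, c)

    @classmethod
    def cubic(cls, a: float) -> "UnitCell":
        return cls(LatticeSystem.CUBIC, a, a, a)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


# ---------------------------------------------------------------------------
# scalar conversions


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in Å from energy in keV (λ = hc/E)."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_ANGSTROM / energy_kev


def s_from_two_theta(two_theta_deg, wavelength: float):
    """Momentum transfer s = 4π sin(θ)/λ [Å⁻¹] from scattering angle 2θ [deg]."""
    tt = np.asarray(two_theta_deg, dtype=float)
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if np.any(tt < 0) or np.any(tt >= 180):
        raise ValueError("two_theta must lie in [0, 180) degrees")
    out = 4.0 * np.pi * np.sin(np.radians(tt / 2.0)) / wavelength
    return out if out.ndim else float(out)


def two_theta_from_s(s, wavelength: float):
    """Inverse of :func:`s_from_two_theta`."""
    sv = np.asarray(s, dtype=float)
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    arg = sv * wavelength / (4.0 * np.pi)
    if np.any(arg < 0) or np.any(arg > 1):
        raise ValueError("s outside the accessible range for this wavelength")
    out = 2.0 * np.degrees(np.arcsin(arg))
    return out if out.ndim else float(out)


def d_from_s(s):
    """Real-space spacing d = 2π/s [Å]; an involution with s_from_d."""
    sv = np.asarray(s, dtype=float)
    if np.any(sv <= 0):
        raise ValueError("s must be positive")
    out = 2.0 * np.pi / sv
    return out if out.ndim else float(out)


#: d = 2π/s is its own inverse.
s_from_d = d_from_s


def two_theta_from_d(d: float, wavelength: float) -> float:
    """Bragg angle 2θ [deg] of a plane spacing d [Å]: λ = 2 d sin θ."""
    return two_theta_from_s(s_from_d(d), wavelength)


def d_spacing(cell: UnitCell, hkl: Sequence[int]) -> float:
    """Interplanar spacing d(hkl) in Å for the given cell."""
    h, k, l = (int(v) for v in hkl)
    if h == 0 and k == 0 and l == 0:
        raise ValueError("hkl must not be (0,0,0)")
    return float(cell.to_gemmi().calculate_d([h, k, l]))


# ---------------------------------------------------------------------------
# space groups

# Reflection conditions generated by the translational symmetry elements of
# the supported groups.  Only axial classes are constrained (primitive
# lattices, no glide planes):
#   P41212 (no. 92):  00l: l = 4n;  h00/0k0: even
#   P4212  (no. 90):  h00/0k0: even
#   P42212 (no. 94):  00l: l = 2n;  h00/0k0: even
#   P6522  (no. 179): 00l: l = 6n
_AXIAL_CONDITIONS: dict[str, dict[str, int]] = {
    "P41212": {"00l": 4, "h00": 2},
    "P4212": {"h00": 2},
    "P42212": {"00l": 2, "h00": 2},
    "P6522": {"00l": 6},
}


def _condition_predicate(conds: dict[str, int]) -> Callable[[int, int, int], bool]:
    def absent(h: int, k: int, l: int) -> bool:
        if h == 0 and k == 0 and l != 0 and "00l" in conds:
            return l % conds["00l"] != 0
        if l == 0 and "h00" in conds:
            if k == 0 and h != 0:
                return h % conds["h00"] != 0
            if h == 0 and k != 0:
                return k % conds["h00"] != 0
        return False

    return absent


_SYSTEM_BY_CRYSTAL = {
    "tetragonal": LatticeSystem.TETRAGONAL,
    "hexagonal": LatticeSystem.HEXAGONAL,
    "orthorhombic": LatticeSystem.ORTHORHOMBIC,
    "cubic": LatticeSystem.CUBIC,
}


@dataclass(frozen=True)
class SpaceGroupRules:
    """Symmetry operators plus closed-form reflection conditions for a group.

    ``operators`` are ``(R, t)`` pairs in fractional coordinates.  The
    absence predicate is closed-form (axial reflection conditions); the
    operator set exists so that equivalence classes and multiplicities can
    be derived, and so tests can check the predicate against structure-factor
    cancellation over the operators.
    """

    symbol: str
    system: LatticeSystem
    operators: tuple[tuple[tuple[tuple[int, ...], ...], tuple[float, ...]], ...]
    _absent: Callable[[int, int, int], bool] = field(compare=False, repr=False, default=None)

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupRules":
        """Build rules from a Hermann-Mauguin symbol.

        The four screening-application groups carry hand-written reflection
        conditions; any other *primitive* group whose operators have no
        translation parts (e.g. P422, P622, P222, P432) is accepted with no
        conditions.  Everything else is unsupported.
        """
        key = symbol.replace(" ", "").replace("_", "")
        sg = gemmi.find_spacegroup_by_name(key)
        if sg is None:
            raise ValueError(f"unknown space group symbol: {symbol!r}")
        system = _SYSTEM_BY_CRYSTAL.get(sg.crystal_system_str())
        if system is None:
            raise ValueError(
                f"space group {symbol!r}: crystal system "
                f"{sg.crystal_system_str()!r} is not supported"
            )
        ops = []
        for op in sg.operations():
            rot = tuple(tuple(int(v) // 24 for v in row) for row in op.rot)
            tran = tuple(v / 24.0 for v in op.tran)
            ops.append((rot, tran))
        if key in _AXIAL_CONDITIONS:
            absent = _condition_predicate(_AXIAL_CONDITIONS[key])
        elif all(all(t == 0 for t in tran) for _, tran in ops):
            absent = _condition_predicate({})
        else:
            raise ValueError(
                f"space group {symbol!r} has translational symmetry elements "
                "but no reflection-condition table; supported groups: "
                f"{sorted(_AXIAL_CONDITIONS)} plus translation-free primitive groups"
            )
        return cls(key, system, tuple(ops), absent)

    # -- symmetry on reflections -------------------------------------------

    def equivalents(self, hkl: Sequence[int]) -> frozenset[tuple[int, int, int]]:
        """Orbit of hkl under the Laue group (point operations + Friedel)."""
        h = np.array([int(v) for v in hkl])
        out = set()
        for rot, _ in self.operators:
            r = np.asarray(rot)
            eq = tuple(int(v) for v in h @ r)  # hkl transforms by row-vector product
            out.add(eq)
            out.add(tuple(-v for v in eq))
        return frozenset(out)

    def multiplicity(self, hkl: Sequence[int]) -> int:
        return len(self.equivalents(hkl))

    def representative(self, hkl: Sequence[int]) -> tuple[int, int, int]:
        """Canonical label of an orbit: lexicographically greatest member,
        preferring members with h >= k >= 0."""
        eq = self.equivalents(hkl)
        preferred = [e for e in eq if e[0] >= e[1] >= 0]
        return max(preferred or eq)


def is_systematically_absent(rules: SpaceGroupRules, hkl: Sequence[int]) -> bool:
    """True iff (hkl) is forbidden by the group's reflection conditions."""
    h, k, l = (int(v) for v in hkl)
    if h == 0 and k == 0 and l == 0:
        raise ValueError("hkl must not be (0,0,0)")
    return rules._absent(h, k, l)


# ---------------------------------------------------------------------------
# reflection lists


@dataclass(frozen=True)
class Reflection:
    """One symmetry-distinct powder line."""

    hkl: tuple[int, int, int]
    d: float  # Å
    two_theta: float  # degrees
    s: float  # Å⁻¹
    multiplicity: int
    intensity: float = 0.0


def generate_reflections(
    cell: UnitCell,
    rules: SpaceGroupRules,
    two_theta_range: tuple[float, float],
    wavelength: float,
) -> list[Reflection]:
    """All allowed symmetry-distinct reflections with 2θ inside the range.

    Equivalents are merged into one entry per orbit with the orbit's
    multiplicity; entries are sorted by ascending 2θ (ties broken by the
    representative hkl) so the output is deterministic.
    """
    lo, hi = two_theta_range
    if not (0.0 <= lo < 180.0 and 0.0 < hi <= 180.0):
        raise ValueError("two_theta_range must lie within (0, 180) degrees")
    if cell.system is not rules.system:
        raise ValueError(
            f"cell system {cell.system.value} does not match space group "
            f"system {rules.system.value}"
        )
    if hi <= lo:
        return []
    d_min = wavelength / (2.0 * math.sin(math.radians(hi / 2.0)))
    hmax = int(math.ceil(cell.a / d_min))
    kmax = int(math.ceil(cell.b / d_min))
    # hexagonal reciprocal axes are longer than 1/a; pad the index bound
    if cell.system is LatticeSystem.HEXAGONAL:
        hmax = int(math.ceil(2.0 * cell.a / (math.sqrt(3.0) * d_min)))
        kmax = hmax
    lmax = int(math.ceil(cell.c / d_min))

    seen: dict[frozenset, tuple[int, int, int]] = {}
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            for l in range(-lmax, lmax + 1):
                if h == 0 and k == 0 and l == 0:
                    continue
                orbit = rules.equivalents((h, k, l))
                if orbit in seen:
                    continue
                seen[orbit] = rules.representative((h, k, l))

    out: list[Reflection] = []
    for orbit, rep in seen.items():
        if is_systematically_absent(rules, rep):
            continue
        d = d_spacing(cell, rep)
        if d < d_min:  # quick reject before the arcsin
            continue
        tt = two_theta_from_d(d, wavelength)
        if lo < tt <= hi:
            out.append(Reflection(rep, d, tt, s_from_d(d), len(orbit)))
    out.sort(key=lambda r: (r.two_theta, r.hkl))
    return out


def reflections_to_table(reflections: Sequence[Reflection]) -> str:
    """Tab-separated reflection list: hkl, d (Å), 2θ (deg), s (Å⁻¹), mult."""
    lines = ["h\tk\tl\td_A\ttwo_theta_deg\ts_invA\tmultiplicity"]
    for r in reflections:
        lines.append(
            f"{r.hkl[0]}\t{r.hkl[1]}\t{r.hkl[2]}\t{r.d:.5f}\t"
            f"{r.two_theta:.5f}\t{r.s:.6f}\t{r.multiplicity}"
        )
    return "\n".join(lines) + "\n"
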