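"""Per-element parameters for the ten elements the simulator supports.

The scope is organic chemistry: C, H, N, O plus the heteroatoms S and P and
the four halogens. Each entry carries the valence-electron count used to
normalize synthetic densities, a density decay length, a pair-dispersion
C6 coefficient, a minimum-approach (clamp) radius for the r^-6 attraction,
and covalent / rendering radii.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

__all__ = ["ElementParams", "ElementTable", "SUPPORTED_ELEMENTS", "default_element_table"]

SUPPORTED_ELEMENTS = frozenset({"C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I"})

#: All IUPAC element symbols (Z = 1..103). Geometry I/O accepts any of
#: these; the selection filter then rejects everything outside
#: SUPPORTED_ELEMENTS, mirroring how raw repository structures can contain
#: metals that the collection excludes.
PERIODIC_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr"
    .split()
)

# Density decay lengths grow weakly with covalent radius,
# lambda = 0.24 + r_cov / 20 (A). Valence-density tails fall off as
# exp(-2*kappa*r) with kappa set by the ionization energy, which varies far
# less than atomic size, so lambda sits in a narrow 0.26-0.31 A band:
# heavier atoms reach slightly farther and appear brighter at large tip
# heights, while the density-overlap repulsion stays at chemically sensible
# magnitudes (~0.1-0.5 eV at imaging heights). Every profile is resolvable
# on the default 0.15 A voxel grid.


@dataclass(frozen=True)
class ElementParams:
    """Static parameters of one chemical element.

    C6 values are adapted from the UFF Lennard-Jones table via
    C6 = 2*eps*r0^6 (eV*A^6); render radii are van der Waals radii.
    """

    symbol: str
    atomic_number: int
    valence_electrons: int
    decay_length: float  # A, synthetic-density exponential decay
    c6: float  # eV*A^6, homonuclear dispersion coefficient
    min_approach: float  # A, r^-6 clamp radius
    covalent_radius: float  # A
    render_radius: float  # A, disk radius for height maps

    def __post_init__(self) -> None:
        for field in ("valence_electrons", "decay_length", "c6", "min_approach",
                      "covalent_radius", "render_radius"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{self.symbol}: {field} must be > 0")


def _entry(sym: str, z: int, nval: int, c6: float, r_cov: float, r_vdw: float) -> ElementParams:
    return ElementParams(
        symbol=sym,
        atomic_number=z,
        valence_electrons=nval,
        decay_length=0.24 + r_cov / 20.0,
        c6=c6,
        min_approach=r_cov + 0.6,
        covalent_radius=r_cov,
        render_radius=r_vdw,
    )


class ElementTable:
    """Lookup table mapping element symbols to :class:`ElementParams`.

    Exactly the ten supported organic-chemistry elements are present; any
    other symbol raises ``KeyError``.
    """

    def __init__(self, entries: Dict[str, ElementParams]):
        if set(entries) != set(SUPPORTED_ELEMENTS):
            raise ValueError(
                "ElementTable must contain exactly the supported elements "
                f"{sorted(SUPPORTED_ELEMENTS)}, got {sorted(entries)}"
            )
        self._entries = dict(entries)

    def __getitem__(self, symbol: str) -> ElementParams:
        return self._entries[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def symbols(self) -> frozenset:
        return frozenset(self._entries)


def default_element_table() -> ElementTable:
    """The built-in parameter set.

    C6 from UFF (eps in kcal/mol, r0 in A) converted with C6 = 2*eps*r0^6;
    van der Waals radii from the Bondi compilation.
    """
    return ElementTable({
        "H":  _entry("H", 1, 1, 2.2, 0.31, 1.20),
        "C":  _entry("C", 6, 4, 29.7, 0.76, 1.70),
        "N":  _entry("N", 7, 5, 14.4, 0.71, 1.55),
        "O":  _entry("O", 8, 6, 9.6, 0.66, 1.52),
        "F":  _entry("F", 9, 7, 6.3, 0.57, 1.47),
        "P":  _entry("P", 15, 5, 134.0, 1.07, 1.80),
        "S":  _entry("S", 16, 6, 102.7, 1.05, 1.80),
        "Cl": _entry("Cl", 17, 7, 74.5, 1.02, 1.75),
        "Br": _entry("Br", 35, 7, 117.7, 1.20, 1.85),
        "I":  _entry("I", 53, 7, 244.0, 1.39, 1.98),
    })
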