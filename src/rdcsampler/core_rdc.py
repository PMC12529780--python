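"""Elementary dipolar-coupling quantities.

A dipolar coupling between two nuclear spins k1 and k2 factorizes into a
constant prefactor ``Dc`` set by the gyromagnetic ratios and a reference
internuclear distance, a radial factor ``R = (r0/r)**3`` correcting for the
actual bond length, and the second-order Legendre function
``P2(cos theta) = (3 cos^2 theta - 1) / 2`` of the angle between the
internuclear vector and the magnetic-field direction::

    D = Dc * R * P2(cos theta)

Averaged over an isotropic orientation distribution, ``<P2> = 0`` and the
kHz-scale coupling collapses to zero; a slight anisotropy of the rotational
distribution leaves the Hz-scale residual dipolar coupling (RDC).

Internal units: lengths in nm, time in ps, energies in kJ/mol, RDCs in Hz,
prefactors in kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "Isotope",
    "load_isotope_table",
    "ISOTOPES",
    "BondClass",
    "BOND_CLASSES",
    "RDCTarget",
    "dipolar_prefactor",
    "radial_factor",
    "legendre_p2",
    "rdc_instant",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants in SI and in the nm/ps/kJ-per-mol unit system.

    ``mu0_si`` is the magnetic susceptibility of vacuum in J s^2 C^-2 m^-1,
    ``mu0_md`` the same quantity in kJ mol^-1 ps^2 e^-2 nm^-1; ``h_si`` and
    ``h_md`` are Planck's constant in J s and kJ mol^-1 ps.
    """

    mu0_si: float = 4.0e-7 * math.pi
    mu0_md: float = 1.9425913e-8
    h_si: float = 6.626176e-34
    h_md: float = 0.3990313
    kB: float = 8.31441e-3  # kJ mol^-1 K^-1


CONSTANTS = PhysicalConstants()

_E_CHARGE_C = 1.6021892e-19  # elementary charge, C
_AVOGADRO = 6.022045e23
_ATOMIC_MASS_KG = 1e-3 / _AVOGADRO  # atomic mass unit, kg

# nm/ps/kJ-per-mol counterparts of mu0 and h derived from the SI values via
# exact unit conversion (J -> kJ/mol, s -> ps, C -> e, m -> nm); they agree
# with the rounded values stored in PhysicalConstants to ~1e-7 relative.
_MU0_MD_DERIVED = (
    CONSTANTS.mu0_si * (_AVOGADRO / 1e3) * 1e24 * _E_CHARGE_C ** 2 * 1e-9
)
_H_MD_DERIVED = CONSTANTS.h_si * (_AVOGADRO / 1e3) * 1e12


@dataclass(frozen=True)
class Isotope:
    """A nuclear isotope with its signed gyromagnetic ratio / 2 pi in MHz/T."""

    label: str
    gamma_over_2pi: float


def load_isotope_table(path=None) -> Dict[str, Isotope]:
    """Load the isotope table (TSV: label, gamma_over_2pi_MHz_per_T).

    Defaults to the table shipped with the package; pass a path to swap in
    different tabulated values.
    """
    if path is None:
        src = resources.files("rdcsampler").joinpath("data/isotopes.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: Dict[str, Isotope] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        label, gamma = ln.split("\t")
        table[label] = Isotope(label, float(gamma))
    return table


ISOTOPES = load_isotope_table()


def dipolar_prefactor(gamma1_over_2pi: float, gamma2_over_2pi: float,
                      r0: float, units: str = "SI") -> float:
    """Dipolar-coupling prefactor Dc in kHz.

    ``Dc = -mu0 h / (2 pi r0^3) * (gamma1/2pi) * (gamma2/2pi)`` with the
    gyromagnetic ratios in MHz/T (signed) and the reference length ``r0`` in
    nm.  ``units`` selects whether the constant ``-mu0 h / (2 pi r0^3)`` is
    evaluated in SI or in the nm/ps/kJ-per-mol system; both give the same
    kHz value (a unit-consistency check, not a physical choice).

    Raises ``ValueError`` for non-positive ``r0``.
    """
    if r0 <= 0:
        raise ValueError(f"reference length must be positive, got {r0}")
    g1_hz = gamma1_over_2pi * 1.0e6  # Hz/T
    g2_hz = gamma2_over_2pi * 1.0e6
    if units == "SI":
        # -mu0 h / (2 pi r0^3) in J^2 s^3 C^-2 m^-4; with gamma/2pi in
        # Hz T^-1 = C kg^-1 s the product is in Hz.
        pref = -CONSTANTS.mu0_si * CONSTANTS.h_si / (2.0 * math.pi * (r0 * 1e-9) ** 3)
        return pref * g1_hz * g2_hz * 1e-3  # kHz
    elif units == "MD":
        # Same combination in (kJ/mol)^2 ps^3 e^-2 nm^-4 = u^2 nm^4 ps^-1
        # e^-2 nm^-4 (kJ/mol == u nm^2 ps^-2).  gamma/2pi converts from
        # Hz T^-1 to (ps^-1 per u e^-1 ps^-1) = e u^-1 via the value of one
        # tesla, 1 kg C^-1 s^-1, in u e^-1 ps^-1; the product then comes out
        # in ps^-1 (THz).
        pref_md = -_MU0_MD_DERIVED * _H_MD_DERIVED / (2.0 * math.pi * r0 ** 3)
        tesla_md = (1.0 / _ATOMIC_MASS_KG) * _E_CHARGE_C / 1e12
        g1_md = g1_hz * 1e-12 / tesla_md
        g2_md = g2_hz * 1e-12 / tesla_md
        return pref_md * g1_md * g2_md * 1e12 * 1e-3  # THz -> Hz -> kHz
    raise ValueError(f"unknown unit system {units!r}")


def radial_factor(b: float, r0: float) -> float:
    """Radial factor ``R = (r0/b)**3`` (dimensionless), lengths in nm."""
    if b <= 0 or r0 <= 0:
        raise ValueError(f"lengths must be positive, got b={b}, r0={r0}")
    return (r0 / b) ** 3


def legendre_p2(cos_theta):
    """Second-order Legendre function ``(3 x^2 - 1) / 2`` for x = cos theta.

    Accepts scalars or arrays; |x| may exceed 1 by at most 1e-12 (clamped),
    anything beyond raises ``ValueError``.
    """
    x = np.asarray(cos_theta, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("cos(theta) outside [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    p = 1.5 * x * x - 0.5
    return float(p) if np.ndim(cos_theta) == 0 else p


def rdc_instant(dc_khz, r, p):
    """Instantaneous coupling ``D = Dc * R * P`` in Hz (``Dc`` in kHz)."""
    return np.multiply(np.multiply(dc_khz, r), p) * 1.0e3


@dataclass(frozen=True)
class BondClass:
    """One backbone bond type carrying an RDC.

    ``b0`` is the rigid bond length in nm, ``r0`` the common reference
    length (0.1 nm) so that the radial factor is ``(r0/b0)**3``.  ``dc_khz``
    is the prefactor evaluated at ``r0``; the physically meaningful product
    ``dc_khz * r_factor`` equals the per-class prefactor evaluated at the
    bond length itself.
    """

    label: str
    isotope1: str
    isotope2: str
    b0: float
    r0: float = 0.1
    dc_khz: float = field(init=False)
    r_factor: float = field(init=False)

    def __post_init__(self):
        g1 = ISOTOPES[self.isotope1].gamma_over_2pi
        g2 = ISOTOPES[self.isotope2].gamma_over_2pi
        object.__setattr__(self, "dc_khz", dipolar_prefactor(g1, g2, self.r0))
        object.__setattr__(self, "r_factor", radial_factor(self.b0, self.r0))

    @property
    def dc_r_hz(self) -> float:
        """Scale ``Dc * R`` of this class in Hz (the maximal |RDC| at P = 1)."""
        return self.dc_khz * self.r_factor * 1.0e3


BOND_CLASSES: Dict[str, BondClass] = {
    "N-HN": BondClass("N-HN", "15N", "1H", b0=0.1),
    "CA-HA": BondClass("CA-HA", "13C", "1H", b0=0.109),
    "CA-C": BondClass("CA-C", "13C", "13C", b0=0.153),
    "C-N": BondClass("C-N", "13C", "15N", b0=0.133),
}


@dataclass
class RDCTarget:
    """One target coupling: residue (author numbering), bond type, D0 in Hz.

    ``provenance`` is one of measured | averaged-duplicate |
    artificial-inverted | synthetic.
    """

    residue: int
    bond_class: str
    d0: float
    restrained: bool = False
    provenance: str = "measured"

    def __post_init__(self):
        if self.bond_class not in BOND_CLASSES:
            raise ValueError(f"unknown bond class {self.bond_class!r}")
        if not math.isfinite(self.d0):
            raise ValueError(f"non-finite target RDC for residue {self.residue}")
        bc = BOND_CLASSES[self.bond_class]
        if abs(self.d0) >= abs(bc.dc_khz) * 1e3:
            raise ValueError(
                f"|D0|={abs(self.d0):g} Hz exceeds the dipolar prefactor "
                f"magnitude of class {self.bond_class}"
            )
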