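"""Orthotropic linear elasticity for guard-cell walls.

The wall is described by Young's moduli along three orthogonal material axes
— E1 longitudinal (polar, along the guard-cell tube), E2 circumferential
(azimuthal, the cellulose-microfibril hoop direction), E3 radial (through
the wall thickness) — three shear moduli G12, G13, G23, and a single major
Poisson ratio applied to all axis pairs (ν12 = ν13 = ν23 = ν). Minor ratios
follow from compliance symmetry, ν_ji = ν_ij·E_j/E_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Poisson ratio of the wall estimated from cell-wall network models; held
#: fixed during identification (varying it between 0 and 0.49 has negligible
#: geometric effect).
DEFAULT_POISSON = 0.003


@dataclass(frozen=True)
class OrthotropicMaterial:
    """Engineering constants in MPa (moduli) and dimensionless ν."""

    E1: float
    E2: float
    E3: float
    G12: float
    G13: float
    G23: float
    nu: float = DEFAULT_POISSON

    def __post_init__(self):
        for name in ("E1", "E2", "E3", "G12", "G13", "G23"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def isotropic(cls, E: float, nu: float = DEFAULT_POISSON) -> "OrthotropicMaterial":
        G = E / (2.0 * (1.0 + nu))
        return cls(E, E, E, G, G, G, nu)

    @property
    def moduli(self) -> np.ndarray:
        return np.array([self.E1, self.E2, self.E3,
                         self.G12, self.G13, self.G23])

    def compliance3(self) -> np.ndarray:
        """3×3 normal-block compliance (axes 1, 2, 3); symmetric because the
        minor Poisson ratios are completed as ν_ji = ν_ij·E_j/E_i."""
        E1, E2, E3, nu = self.E1, self.E2, self.E3, self.nu
        return np.array([
            [1.0 / E1, -nu / E1, -nu / E1],
            [-nu / E1, 1.0 / E2, -nu / E2],
            [-nu / E1, -nu / E2, 1.0 / E3],
        ])

    def stiffness6(self) -> np.ndarray:
        """6×6 stiffness in Voigt order (11, 22, 33, 12, 13, 23) with
        engineering shear strains."""
        C = np.zeros((6, 6))
        C[:3, :3] = np.linalg.inv(self.compliance3())
        C[3, 3], C[4, 4], C[5, 5] = self.G12, self.G13, self.G23
        return C

    def is_positive_definite(self) -> bool:
        """Thermodynamic admissibility of the completed stiffness matrix.

        Strong anisotropy with a fixed major ν can violate |ν_ij| <
        √(E_i/E_j); such parameter sets have an indefinite stiffness and are
        physically impossible.
        """
        try:
            np.linalg.cholesky(self.stiffness6())
            return True
        except np.linalg.LinAlgError:
            return False

    def plane_stress_Q(self) -> np.ndarray:
        """In-plane reduced stiffness (σ3 = 0 condensation), Voigt
        (ε11, ε22, γ12); the through-thickness modulus E3 drops out of the
        membrane response, as in any thin-shell theory."""
        S = self.compliance3()[:2, :2]
        Q = np.zeros((3, 3))
        Q[:2, :2] = np.linalg.inv(S)
        Q[2, 2] = self.G12
        return Q

    def bending_modulus(self, angle: float) -> float:
        """Effective uniaxial modulus for bending in an in-plane direction at
        ``angle`` (radians) from the material 1-axis."""
        c2, s2 = np.cos(angle) ** 2, np.sin(angle) ** 2
        inv = (c2 * c2 / self.E1 + s2 * s2 / self.E2
               + c2 * s2 * (1.0 / self.G12 - 2.0 * self.nu / self.E1))
        return 1.0 / inv
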