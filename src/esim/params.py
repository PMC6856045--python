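"""Global parameters of the similarity function and chemistry configuration.

The similarity kernel measures agreement of three physically grounded field
types at observer points placed a fixed ideal distance ``gamma`` outside the
target molecule's van der Waals surface: steric (surface) distance, Coulombic
potential energy of a +0.2 e probe charge, and hydrogen-bond donor/acceptor
distance + direction.  The Gaussian widths and sigmoid steepnesses below set
how sharply similarity falls off with disagreement in each feature type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: Coulomb constant in kcal*Angstrom/(mol*e^2)
COULOMB_CONSTANT = 332.0716

#: Probe point charge (e) used to evaluate the molecular field at observers.
PROBE_CHARGE = 0.2

#: Bondi (1964) van der Waals radii, Angstroms.  A fixed, versioned table:
#: the steric feature subtracts these radii, so the table is part of the
#: method definition, not a tunable.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "As": 1.85,
    "Se": 1.90,
    "Br": 1.85,
    "Kr": 2.02,
    "Te": 2.06,
    "I": 1.98,
    "Xe": 2.16,
}

#: Hydrogen-bond perception rule table (config-exposed; see docs/methods.md).
#: Donors: any H bonded to one of ``donor_heavy``.  Acceptors: O with at most
#: 2 neighbors, or N with at most ``n_acceptor_max_degree`` neighbors; atoms
#: with positive formal charge never accept.
POLAR_RULES: dict = {
    "donor_heavy": ("N", "O", "S"),
    "acceptor_elements": ("N", "O"),
    "n_acceptor_max_degree": 2,
    "o_acceptor_max_degree": 2,
}


@dataclass(frozen=True)
class SimParams:
    """Constants of the similarity function.

    All Gaussian widths follow ``g(x, sigma) = exp(-x^2 / sigma)``; note the
    denominator is sigma itself, not ``2 sigma^2``.  Angles are radians
    internally (``sigma_datheta`` = 0.5 is a radians^2-scale width).
    """

    gamma: float = 4.0          # ideal observer-to-surface distance, A
    sigma_stc: float = 2.0      # steric-distance Gaussian width, A^2
    sigma_coul: float = 8.0     # Coulombic Gaussian width, (kcal/mol)^2
    sigma_da: float = 1.0       # donor/acceptor distance width, A^2
    sigma_datheta: float = 0.5  # donor/acceptor angle width, rad^2
    alpha_da: float = 0.25      # attention-sigmoid steepness, A
    strain_const: float = 0.05  # strain penalty per kcal/mol of conformer energy
    w_shape: float = 1.0
    w_coul: float = 1.0
    w_da: float = 1.0
    probe_charge: float = PROBE_CHARGE
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        for name in ("sigma_stc", "sigma_coul", "sigma_da", "sigma_datheta",
                     "alpha_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("w_shape", "w_coul", "w_da"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_weights(self, w_shape: float = 1.0, w_coul: float = 1.0,
                     w_da: float = 1.0) -> "SimParams":
        """Copy with component weights replaced (ablation experiments)."""
        return replace(self, w_shape=w_shape, w_coul=w_coul, w_da=w_da)


DEFAULT_PARAMS = SimParams()

#: Sentinel distance (A) reported when a molecule has no donor (acceptor):
#: far enough that the attention weight of Eq.-style sigmoids is ~0.
ABSENT_DISTANCE = 1.0e6
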