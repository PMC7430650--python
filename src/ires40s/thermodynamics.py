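"""Free-energy landscapes from rate and equilibrium constants.

Transition-state free energies of activation follow the Eyring-Polanyi
relation

    dG_act = -R T ln( k h / (k_B T) )

with transmission coefficient 1.  Bimolecular rate constants are first
converted to pseudo-first-order constants at a 1 M RNA standard state so
the logarithm is taken of a quantity in s^-1.  Ground-state differences
come from equilibrium constants via dG0 = -R T ln K.

A landscape chains these steps along the reaction coordinate

    40S_in -> (40S_A + IRES) -> TS1 -> [40S-IRES] -> TS2 -> [40S-IRES]*

and, because the final conformationally locked complex is taken as the
functionally decisive state, every variant's profile is shifted so that
its product state sits at zero; differences between variants then read
directly as ddG values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import R, Boltzmann, Planck

from . import units
from .reaction_model import DEFAULT_TEMPERATURE_K, RateConstants

__all__ = [
    "EnergyLandscape",
    "STATES",
    "activation_energy",
    "equilibrium_energy",
    "build_landscape",
]

#: Reaction-coordinate states, left to right.
STATES = ("40S_in", "ground", "TS1", "C1", "TS2", "C2")

#: standard concentration for the bimolecular step, mol/L
STANDARD_CONC_M = 1.0


def activation_energy(
    k: float,
    T: float = DEFAULT_TEMPERATURE_K,
    order: int = 1,
    std_conc: float = STANDARD_CONC_M,
) -> float:
    """Eyring free energy of activation, J/mol.

    Parameters
    ----------
    k : float
        Rate constant in s^-1 (order 1) or M^-1 s^-1 (order 2).
    T : float
        Temperature in kelvin.
    order : int
        Kinetic order of the step; a second-order constant is multiplied
        by ``std_conc`` to a pseudo-first-order rate before the logarithm.
    std_conc : float
        Standard concentration in mol/L for the bimolecular conversion.
    """
    if k <= 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    if T <= 0:
        raise ValueError(f"temperature must be > 0 K, got {T}")
    if order == 2:
        if std_conc <= 0:
            raise ValueError("std_conc must be > 0 for a second-order constant")
        k = k * std_conc
    elif order != 1:
        raise ValueError(f"order must be 1 or 2, got {order}")
    return -R * T * np.log(k * Planck / (Boltzmann * T))


def equilibrium_energy(K: float, T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Standard free-energy difference -RT ln K, J/mol."""
    if K <= 0:
        raise ValueError(f"equilibrium constant must be > 0, got {K}")
    if T <= 0:
        raise ValueError(f"temperature must be > 0 K, got {T}")
    return -R * T * np.log(K)


@dataclass
class EnergyLandscape:
    """Per-variant state free energies along the binding coordinate.

    Energies are in J/mol, anchored so the product state ([40S-IRES]*,
    state ``C2``) is zero for every variant.
    """

    states: tuple[str, ...]
    energies: dict[str, np.ndarray]
    temperature: float
    std_conc: float
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Energies as a (state x variant) DataFrame, J/mol."""
        return pd.DataFrame(
            {name: e for name, e in self.energies.items()}, index=list(self.states)
        )

    def ddG(self, variant: str, reference: str = "WT") -> np.ndarray:
        """Per-state energy of ``variant`` relative to ``reference``."""
        return self.energies[variant] - self.energies[reference]


def _variant_profile(rates: RateConstants, T: float, std_conc: float) -> np.ndarray:
    """Unanchored state energies with the active ground state at zero."""
    k1 = units.second_order_per_M_s(rates.k1)  # M^-1 s^-1
    k_neg1 = units.first_order_per_s(rates.k_neg1)
    k2 = units.first_order_per_s(rates.k2)
    k_neg2 = units.first_order_per_s(rates.k_neg2)
    for name, v in (("k1", k1), ("k_neg1", k_neg1), ("k2", k2), ("k_neg2", k_neg2)):
        if v <= 0:
            raise ValueError(f"non-positive rate constant {name}")

    g_ground = 0.0
    # 40S_in -> 40S_A has dG0 = -RT ln K'_1/2; no transition state is drawn
    # for this slow conformational equilibrium
    g_in = g_ground + R * T * np.log(rates.K_half)
    g_ts1 = g_ground + activation_energy(k1, T, order=2, std_conc=std_conc)
    # step-1 well depth from the dimensionless K1 = k1 * c0 / k-1
    g_c1 = g_ground + equilibrium_energy(k1 * std_conc / k_neg1, T)
    g_ts2 = g_c1 + activation_energy(k2, T, order=1)
    g_c2 = g_c1 + equilibrium_energy(k2 / k_neg2, T)
    return np.array([g_in, g_ground, g_ts1, g_c1, g_ts2, g_c2])


def build_landscape(
    variants: dict[str, RateConstants],
    T: float = DEFAULT_TEMPERATURE_K,
    std_conc: float = STANDARD_CONC_M,
) -> EnergyLandscape:
    """Assemble the product-anchored free-energy landscape per variant.

    A variant with a non-positive constant is recorded in ``errors`` and
    the remaining variants are still produced.
    """
    energies: dict[str, np.ndarray] = {}
    errors: dict[str, str] = {}
    for name, rates in variants.items():
        try:
            profile = _variant_profile(rates, T, std_conc)
        except (ValueError, ZeroDivisionError) as exc:
            errors[name] = str(exc)
            continue
        energies[name] = profile - profile[-1]  # anchor product state at 0
    return EnergyLandscape(
        states=STATES, energies=energies, temperature=T,
        std_conc=std_conc, errors=errors,
    )
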