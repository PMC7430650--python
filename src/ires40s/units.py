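"""Unit conversions between the internal (nM, min) and reporting unit systems.

All kinetics code works in nanomolar and minutes; conversions to s^-1,
uM^-1 s^-1 and M^-1 s^-1 happen only at reporting and thermodynamics
boundaries.
"""

#: seconds per minute
MIN_TO_S = 60.0

#: nM^-1 expressed in uM^-1 (1/nM = 1000/uM)
PER_NM_TO_PER_UM = 1000.0

#: nM^-1 expressed in M^-1
PER_NM_TO_PER_M = 1.0e9


def first_order_per_s(k_per_min: float) -> float:
    """Convert a first-order rate constant from min^-1 to s^-1."""
    return k_per_min / MIN_TO_S


def second_order_per_uM_s(k_per_nM_min: float) -> float:
    """Convert a bimolecular rate constant from nM^-1 min^-1 to uM^-1 s^-1."""
    return k_per_nM_min * PER_NM_TO_PER_UM / MIN_TO_S


def second_order_per_M_s(k_per_nM_min: float) -> float:
    """Convert a bimolecular rate constant from nM^-1 min^-1 to M^-1 s^-1."""
    return k_per_nM_min * PER_NM_TO_PER_M / MIN_TO_S


def second_order_per_nM_min(k_per_uM_s: float) -> float:
    """Convert a bimolecular rate constant from uM^-1 s^-1 to nM^-1 min^-1."""
    return k_per_uM_s * MIN_TO_S / PER_NM_TO_PER_UM
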