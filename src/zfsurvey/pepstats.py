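"""Basic protein statistics: average molecular weight and theoretical pI.

Both quantities follow the EMBOSS Pepstats conventions: average (isotope
averaged) residue masses, and a Henderson--Hasselbalch net-charge model over
the two termini and the seven ionizable side chains (D, E, C, Y, H, K, R)
with the EMBOSS pKa set. The pI is the pH at which the net charge vanishes,
located by bisection on (0, 14).
"""

from __future__ import annotations

__all__ = [
    "AVERAGE_FREE_MASS",
    "EMBOSS_PKA",
    "WATER_MASS",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
]

WATER_MASS = 18.0153

# Average masses of the free amino acids (residue mass + one water), Da.
AVERAGE_FREE_MASS = {
    "A": 89.0941, "R": 174.2028, "N": 132.1191, "D": 133.1039,
    "C": 121.1541, "E": 147.1308, "Q": 146.1460, "G": 75.0672,
    "H": 155.1564, "I": 131.1747, "L": 131.1747, "K": 146.1894,
    "M": 149.2079, "F": 165.1919, "P": 115.1320, "S": 105.0935,
    "T": 119.1204, "W": 204.2285, "Y": 181.1913, "V": 117.1479,
}

# Mean free mass over the 20 standard residues; used for 'X'.
_X_DEFAULT_MASS = sum(AVERAGE_FREE_MASS.values()) / len(AVERAGE_FREE_MASS)

# EMBOSS EpK ionization constants.
EMBOSS_PKA = {
    "nterm": 8.6,
    "cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_ACIDIC = ("C", "D", "E", "Y")
_BASIC = ("H", "K", "R")


def _check_sequence(sequence: str, allow_x: bool = True) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    valid = set(AVERAGE_FREE_MASS)
    if allow_x:
        valid.add("X")
    bad = set(seq) - valid
    if bad:
        raise ValueError(f"non-residue characters in sequence: {sorted(bad)}")
    return seq


def molecular_weight(sequence: str, x_mass: float | None = None) -> float:
    """Average molecular mass in Da of an unmodified linear peptide.

    Sum of free amino-acid masses minus (n-1) condensation waters.
    ``x_mass`` sets the free mass assumed for 'X' (default: mean of the
    20 standard residues).
    """
    seq = _check_sequence(sequence)
    x = _X_DEFAULT_MASS if x_mass is None else x_mass
    total = sum(AVERAGE_FREE_MASS.get(aa, x) for aa in seq)
    return total - (len(seq) - 1) * WATER_MASS


def net_charge(sequence: str, ph: float) -> float:
    """Net charge of the peptide at the given pH (EMBOSS pKa set)."""
    seq = _check_sequence(sequence)
    counts = {aa: seq.count(aa) for aa in _ACIDIC + _BASIC}
    pos = 1.0 / (1.0 + 10 ** (ph - EMBOSS_PKA["nterm"]))
    for aa in _BASIC:
        pos += counts[aa] / (1.0 + 10 ** (ph - EMBOSS_PKA[aa]))
    neg = 1.0 / (1.0 + 10 ** (EMBOSS_PKA["cterm"] - ph))
    for aa in _ACIDIC:
        neg += counts[aa] / (1.0 + 10 ** (EMBOSS_PKA[aa] - ph))
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection to |charge| < tol.

    The charge function is strictly decreasing in pH, so the zero is
    unique; the result always lies in (0, 14).
    """
    seq = _check_sequence(sequence)
    lo, hi = 0.0, 14.0
    # bisect to a fixed narrow bracket: the charge is strictly decreasing,
    # so this pins the zero in pH as well as in charge (flat plateaus
    # around the zero would otherwise stop an |charge|-based exit early)
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    pi = 0.5 * (lo + hi)
    assert abs(net_charge(seq, pi)) < tol
    return pi
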