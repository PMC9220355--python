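"""Energy unit handling.

All internal energies are kilojoules per mole. Quantum-chemistry output is
normally tabulated in Hartree, assay-derived free energies occasionally in
kcal/mol; both are converted on ingest.
"""

from __future__ import annotations

#: 1 hartree in kJ/mol (CODATA 2018).
HARTREE_TO_KJ_PER_MOL = 2625.4996394799

#: Thermochemical calorie.
KCAL_TO_KJ = 4.184

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

_FACTORS = {
    "hartree": HARTREE_TO_KJ_PER_MOL,
    "kj/mol": 1.0,
    "kcal/mol": KCAL_TO_KJ,
}


def convert_energy(value: float, unit: str) -> float:
    """Convert an energy to kJ/mol.

    Parameters
    ----------
    value:
        Energy magnitude in ``unit``.
    unit:
        One of ``hartree``, ``kJ/mol``, ``kcal/mol`` (case-insensitive).

    Returns
    -------
    float
        The energy in kJ/mol; kJ/mol input passes through unchanged.
    """
    key = unit.strip().lower()
    if key not in _FACTORS:
        raise ValueError(
            f"unknown energy unit {unit!r}; expected one of "
            "'hartree', 'kJ/mol', 'kcal/mol'"
        )
    return value * _FACTORS[key]
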