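"""Physical constants and the atomic-mass table.

Unit chain used throughout the quasi-harmonic machinery:

* coordinates in Å, masses in amu (= g/mol), times in ps
* k_B = 0.001987204 kcal/(mol K)
* 1 kcal/mol = 4184 J/mol = 418.4 amu Å²/ps²
* eigenvalues of the mass-weighted covariance therefore carry amu·Å²,
  angular frequencies sqrt(k_B T / λ) come out in rad/ps, and
* ν [cm⁻¹] = ω / (2π c) with c = 2.99792458e-2 cm/ps.
"""

KB_KCAL_PER_MOL_K = 0.001987204
KCAL_PER_MOL_TO_AMU_A2_PS2 = 418.4
C_CM_PER_PS = 2.99792458e-2

#: B = (8 pi^2 / 3) <dr^2> relates an isotropic mean-square displacement
#: to the crystallographic temperature factor.
B_FACTOR_PREFACTOR = 8.0 * 3.141592653589793**2 / 3.0

#: Standard atomic masses (amu), keyed by element symbol.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "MN": 54.938,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
    "CA": 40.078,
    "F": 18.998,
    "BR": 79.904,
    "I": 126.904,
}

#: Two-letter element symbols that may appear in PDB atom names.
TWO_LETTER_ELEMENTS = frozenset(
    e for e in ATOMIC_MASSES if len(e) == 2
)


def mass_of(element: str) -> float:
    """Mass in amu for an element symbol (case-insensitive)."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}") from None
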