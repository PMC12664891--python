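"""Mass arithmetic for the light/heavy iodoacetamide (IAA) label pair.

Both labels alkylate cysteine thiols to a carbamidomethyl adduct
(+C2H3NO).  The heavy reagent substitutes two 13C and two deuterium
atoms, so the heavy and light forms of a peptide differ by a fixed mass
shift independent of sequence.  At charge z the precursor pair is
separated by shift/z in m/z — the quantity that decides whether an
isolation window can co-isolate the two forms.
"""

from __future__ import annotations

from pyteomics import mass

#: number of 12C -> 13C substitutions in the heavy reagent
_N_C13 = 2
#: number of 1H -> 2H substitutions in the heavy reagent
_N_D = 2


def heavy_light_mass_shift(kind: str = "monoisotopic") -> float:
    """Mass difference (Da) between heavy- and light-IAA carbamidomethyl.

    kind="monoisotopic" uses NIST isotope masses; kind="nominal" counts
    mass numbers (exactly 4).
    """
    if kind == "nominal":
        return float(_N_C13 * (13 - 12) + _N_D * (2 - 1))
    if kind == "monoisotopic":
        c12 = mass.nist_mass["C"][12][0]
        c13 = mass.nist_mass["C"][13][0]
        h1 = mass.nist_mass["H"][1][0]
        h2 = mass.nist_mass["H"][2][0]
        return _N_C13 * (c13 - c12) + _N_D * (h2 - h1)
    raise ValueError(f"unknown kind {kind!r}")


def isotopolog_mz_separation(charge: int, kind: str = "monoisotopic") -> float:
    """m/z separation (Th) of the light/heavy precursor pair at a charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return heavy_light_mass_shift(kind) / charge
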