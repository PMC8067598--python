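"""Monoisotopic masses of the nucleoside chemistry behind neutral-loss matching.

Collision-induced dissociation of a protonated 2'-deoxynucleoside (or of a
covalently modified one, a DNA adduct) cleaves the N-glycosidic bond and expels
the sugar as a neutral C5H8O3 fragment -- formally deoxyribose minus water.
The charged product is the (modified) nucleobase.  The precursor-minus-fragment
mass difference is therefore a constant, independent of the modification, and
is the handle this package matches on.

All masses are computed from standard atomic monoisotopic masses via
:mod:`pyteomics.mass`; nothing is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

PROTON_MASS = 1.00727646677  # Da

#: Elemental composition of the neutral sugar fragment lost on CID.
DEOXYRIBOSE_LOSS_FORMULA = "C5H8O3"

# (name, nucleoside formula, nucleobase formula) -- neutral molecules;
# protonation is applied when building ion m/z values.
_NUCLEOSIDES = [
    ("dG", "C10H13N5O4", "C5H5N5O"),
    ("dA", "C10H13N5O3", "C5H5N5"),
    ("dC", "C9H13N3O4", "C4H5N3O"),
    ("dT", "C10H14N2O5", "C5H6N2O2"),
    ("5-me-dC", "C10H15N3O4", "C5H7N3O"),
    ("N6-me-dA", "C11H15N5O3", "C6H7N5"),
    ("8-oxo-dG", "C10H13N5O5", "C5H5N5O2"),
]


def monoisotopic(formula: str) -> float:
    """Monoisotopic mass (Da) of a neutral molecular formula."""
    return float(_pmass.calculate_mass(formula=formula))


def protonated_mz(formula: str) -> float:
    """m/z of the [M+H]+ ion of a neutral formula, z = 1."""
    return monoisotopic(formula) + PROTON_MASS


def deoxyribose_loss_mass() -> float:
    """Monoisotopic mass of the C5H8O3 neutral loss, 116.0473 Da to 4 dp."""
    return monoisotopic(DEOXYRIBOSE_LOSS_FORMULA)


@dataclass(frozen=True)
class NucleosideIon:
    """Protonated nucleoside precursor and its base-ion CID product."""

    name: str
    precursor_mz: float  # [M+H]+ of the nucleoside
    fragment_mz: float   # [M+H]+ of the nucleobase (precursor minus C5H8O3)


def nucleoside_ion_table() -> list[NucleosideIon]:
    """Precursor/fragment ion pairs for the four canonical 2'-deoxynucleosides
    and three modified ones (5-me-dC, N6-me-dA, 8-oxo-dG).

    Every pair differs by exactly :func:`deoxyribose_loss_mass`, which is a
    consistency check on the formulas, not an imposed constraint.
    """
    out = []
    for name, nucleoside, base in _NUCLEOSIDES:
        out.append(
            NucleosideIon(
                name=name,
                precursor_mz=protonated_mz(nucleoside),
                fragment_mz=protonated_mz(base),
            )
        )
    return out
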