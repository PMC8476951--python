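"""Exact masses and physical constants shared across the pipeline.

All m/z values in this package are negative-mode [M-H]- values in Thomson;
retention times are in seconds.
"""

from __future__ import annotations

# 13C minus 12C mass difference (Da)
MASS_13C_SHIFT = 1.0033548

# mass shift of one fully ring-labeled phenyl ring (six 13C atoms)
RING_SHIFT = 6.0 * MASS_13C_SHIFT

PROTON_MASS = 1.00727646688

# monoisotopic atomic masses (Da)
MASS_H = 1.00782503207
MASS_C = 12.0
MASS_N = 14.0030740048
MASS_O = 15.9949146196


def monoisotopic_mass(c: int = 0, h: int = 0, n: int = 0, o: int = 0,
                      c13: int = 0) -> float:
    """Monoisotopic neutral mass of a CHNO formula, with ``c13`` of the
    carbons replaced by 13C."""
    return ((c - c13) * MASS_C + c13 * (MASS_C + MASS_13C_SHIFT)
            + h * MASS_H + n * MASS_N + o * MASS_O)


def mh_minus(neutral_mass: float) -> float:
    """[M-H]- m/z for a neutral monoisotopic mass."""
    return neutral_mass - PROTON_MASS


# fed amino-acid precursors: phenylalanine C9H11NO2, tyrosine C9H11NO3
PHE_NEUTRAL = monoisotopic_mass(c=9, h=11, n=1, o=2)
TYR_NEUTRAL = monoisotopic_mass(c=9, h=11, n=1, o=3)
PHE_RING13C6_NEUTRAL = monoisotopic_mass(c=9, h=11, n=1, o=2, c13=6)
TYR_RING13C6_NEUTRAL = monoisotopic_mass(c=9, h=11, n=1, o=3, c13=6)


def default_exclusion_masses() -> list[tuple[str, float]]:
    """[M-H]- m/z of the fed amino acids and their ring-13C6 isotopologues.

    These are removed from feature tables before pairing so that the fed
    precursors themselves do not appear as labeled metabolite features.
    """
    return [
        ("Phe", mh_minus(PHE_NEUTRAL)),
        ("Tyr", mh_minus(TYR_NEUTRAL)),
        ("Phe+6", mh_minus(PHE_RING13C6_NEUTRAL)),
        ("Tyr+6", mh_minus(TYR_RING13C6_NEUTRAL)),
    ]
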