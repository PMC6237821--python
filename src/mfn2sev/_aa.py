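"""Amino-acid code tables shared across modules."""

from Bio.Data.IUPACData import protein_letters_1to3

#: 1-letter -> title-case 3-letter code for the 20 canonical amino acids.
ONE_TO_THREE: dict[str, str] = dict(protein_letters_1to3)

#: title-case 3-letter -> 1-letter code.
THREE_TO_ONE: dict[str, str] = {v: k for k, v in ONE_TO_THREE.items()}

#: Canonical 3-letter codes (title case, e.g. "Arg").
CANONICAL_3 = frozenset(THREE_TO_ONE)


def canonical_aa(code: str) -> str:
    """Normalise a 1- or 3-letter amino-acid code to title-case 3-letter form.

    Raises ``ValueError`` for anything outside the canonical 20.
    """
    code = code.strip()
    if len(code) == 1:
        try:
            return ONE_TO_THREE[code.upper()]
        except KeyError:
            raise ValueError(f"unknown amino-acid code: {code!r}") from None
    if len(code) == 3:
        titled = code.capitalize()
        if titled in CANONICAL_3:
            return titled
    raise ValueError(f"unknown amino-acid code: {code!r}")
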