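"""Amino-acid alphabet shared across the package.

The orthogonal (one-hot) encoding uses 21 slots per position: the 20
standard amino acids in alphabetical one-letter order, followed by the
gap symbol ``-``.  Nonstandard residue codes (selenocysteine ``U``,
pyrrolysine ``O``, the ambiguity codes ``B``/``Z``/``J``/``X``) are
normalized to the gap symbol so that every sequence maps into the
21-letter alphabet.
"""

from __future__ import annotations

import logging

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # 21 symbols; gap is slot 20 (the 21st)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
SYMBOL_INDEX = {sym: i for i, sym in enumerate(ALPHABET)}

# Codes normalized to the gap slot rather than rejected.
NONSTANDARD = set("UOBZJX")

PHOSPHOACCEPTORS = "STY"

logger = logging.getLogger("akid")


def normalize_symbol(symbol: str) -> str:
    """Map a raw sequence character onto the 21-letter alphabet.

    Standard residues and the gap pass through unchanged ('.' is read as
    a gap); nonstandard codes collapse to the gap symbol.  Anything else
    raises ``ValueError``.
    """
    s = symbol.upper()
    if s in SYMBOL_INDEX:
        return s
    if s == ".":
        return GAP
    if s in NONSTANDARD:
        return GAP
    raise ValueError(f"illegal sequence character {symbol!r}")


def normalize_sequence(seq: str, *, context: str = "") -> str:
    """Normalize a whole sequence; logs how many nonstandard residues collapsed."""
    out = []
    n_nonstandard = 0
    for pos, ch in enumerate(seq):
        c = ch.upper()
        if c in NONSTANDARD:
            n_nonstandard += 1
        try:
            out.append(normalize_symbol(c))
        except ValueError as exc:
            where = f" in {context}" if context else ""
            raise ValueError(f"illegal character {ch!r} at position {pos}{where}") from exc
    if n_nonstandard:
        logger.info(
            "normalized %d nonstandard residue(s) to gap%s",
            n_nonstandard,
            f" in {context}" if context else "",
        )
    return "".join(out)
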