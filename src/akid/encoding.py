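"""Orthogonal (one-hot) encoding of kinase DoS and target peptides.

A kinase is represented by the residues at its 63 determinant-of-specificity
(DoS) columns; a candidate site by the 15-residue window centered on the
phosphoacceptor (S/T/Y).  Every position is one-hot encoded over 21 slots
(20 amino acids in alphabetical order, gap last), so one kinase-peptide
pair becomes a binary vector of 78 x 21 = 1638 bits with exactly 78 set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import ALPHABET, GAP, PHOSPHOACCEPTORS, SYMBOL_INDEX, normalize_symbol

N_SLOTS = len(ALPHABET)  # 21
WINDOW_FLANK = 7
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1  # 15
N_DOS = 63
N_POSITIONS = N_DOS + WINDOW_LENGTH  # 78
N_BITS = N_POSITIONS * N_SLOTS  # 1638


@dataclass(frozen=True)
class PhosphoPeptide:
    """A candidate phosphosite: the acceptor residue and its +/-7 context.

    ``site_pos`` is the 0-based index of the acceptor in the parent protein;
    ``window`` always has the acceptor at its center and gap symbols where
    the window runs past a protein terminus.
    """

    protein_id: str
    site_pos: int
    acceptor: str
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LENGTH:
            raise ValueError(
                f"window must have length {WINDOW_LENGTH}, got {len(self.window)}"
            )
        if self.window[WINDOW_FLANK] != self.acceptor:
            raise ValueError("window center must equal the acceptor residue")


@dataclass(frozen=True)
class EncodedPair:
    """The 1638-bit network input for one kinase-peptide pair."""

    bits: np.ndarray
    kinase_id: str
    substrate_id: str
    site_pos: int

    def __post_init__(self) -> None:
        if self.bits.shape != (N_BITS,):
            raise ValueError(f"bits must have shape ({N_BITS},)")


def extract_peptide(
    protein_seq: str,
    site_pos: int,
    *,
    protein_id: str = "",
    flank: int = WINDOW_FLANK,
) -> PhosphoPeptide:
    """Cut the +/-``flank`` window around a phosphoacceptor.

    Positions beyond either terminus are filled with the gap symbol, so the
    window length is always ``2*flank + 1`` and the acceptor sits at index
    ``flank``.
    """
    if not 0 <= site_pos < len(protein_seq):
        raise ValueError(
            f"site_pos {site_pos} out of range for protein of length {len(protein_seq)}"
        )
    acceptor = normalize_symbol(protein_seq[site_pos])
    if acceptor not in PHOSPHOACCEPTORS:
        raise ValueError(
            f"residue at site_pos {site_pos} is {protein_seq[site_pos]!r}, "
            "not a phosphoacceptor (S/T/Y)"
        )
    chars = []
    for p in range(site_pos - flank, site_pos + flank + 1):
        if 0 <= p < len(protein_seq):
            chars.append(normalize_symbol(protein_seq[p]))
        else:
            chars.append(GAP)
    return PhosphoPeptide(
        protein_id=protein_id, site_pos=site_pos, acceptor=acceptor, window="".join(chars)
    )


def encode_residue(symbol: str) -> np.ndarray:
    """One-hot encode a single residue or gap over the 21 slots."""
    sym = normalize_symbol(symbol)
    vec = np.zeros(N_SLOTS, dtype=np.uint8)
    vec[SYMBOL_INDEX[sym]] = 1
    return vec


def encode_sequence(symbols: str) -> np.ndarray:
    """One-hot encode a string of residues/gaps; shape (len, 21) flattened."""
    idx = np.array([SYMBOL_INDEX[normalize_symbol(s)] for s in symbols])
    out = np.zeros((len(symbols), N_SLOTS), dtype=np.uint8)
    out[np.arange(len(symbols)), idx] = 1
    return out.ravel()


def encode_pair(dos_symbols: str, peptide: PhosphoPeptide, *, kinase_id: str = "") -> EncodedPair:
    """Concatenate the DoS block (63 x 21 bits) and the peptide block (15 x 21).

    The DoS block comes first; slot order within each block is alphabetical
    with the gap in slot 21.  Exactly 78 bits are set.
    """
    if len(dos_symbols) != N_DOS:
        raise ValueError(f"DoS string must have length {N_DOS}, got {len(dos_symbols)}")
    bits = np.concatenate([encode_sequence(dos_symbols), encode_sequence(peptide.window)])
    return EncodedPair(
        bits=bits,
        kinase_id=kinase_id,
        substrate_id=peptide.protein_id,
        site_pos=peptide.site_pos,
    )


def decode_pair(bits: np.ndarray) -> tuple[str, str]:
    """Invert :func:`encode_pair`: recover (dos_symbols, window)."""
    if bits.shape != (N_BITS,):
        raise ValueError(f"expected {N_BITS} bits")
    blocks = bits.reshape(N_POSITIONS, N_SLOTS)
    if not np.all(blocks.sum(axis=1) == 1):
        raise ValueError("not a valid one-hot encoding: some block is not one-hot")
    idx = blocks.argmax(axis=1)
    symbols = "".join(ALPHABET[i] for i in idx)
    return symbols[:N_DOS], symbols[N_DOS:]
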