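"""Seeded generators for synthetic inputs: kinase-family MSAs, proteomes
with implanted domains, and KsP datasets with planted DoS/peptide
specificity rules.

All generators are deterministic functions of (parameters, seed).  The
planted-rule datasets embody the premise that a handful of kinase-side
determinant residues couple to target-peptide positions: a positive pair
satisfies every coupling of its kinase's rule, a negative violates at
least one, so recovery experiments have an exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, GAP, PHOSPHOACCEPTORS
from .encoding import (
    N_DOS,
    WINDOW_FLANK,
    WINDOW_LENGTH,
    PhosphoPeptide,
    encode_pair,
)

N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class PlantedRule:
    """Couplings between DoS slots and peptide offsets for one kinase.

    Each coupling ``(dos_slot, peptide_offset, residue)`` requires the
    kinase's DoS slot and the peptide position (offset relative to the
    acceptor, in -7..+7) to carry the given residue in a true pair.
    """

    kinase_id: str
    couplings: tuple  # of (dos_slot, peptide_offset, residue)
    acceptor: str

    def __post_init__(self):
        if not self.couplings:
            raise ValueError("a planted rule needs at least one coupling")
        for slot, offset, res in self.couplings:
            if not 0 <= slot < N_DOS:
                raise ValueError(f"dos_slot {slot} out of range")
            if not -WINDOW_FLANK <= offset <= WINDOW_FLANK:
                raise ValueError(f"peptide offset {offset} out of range")
            if offset == 0:
                raise ValueError("the acceptor position cannot carry a coupling")
            if res not in AMINO_ACIDS:
                raise ValueError(f"invalid residue {res!r}")
        if self.acceptor not in PHOSPHOACCEPTORS:
            raise ValueError("acceptor must be S, T or Y")

    def window_satisfies(self, window: str) -> bool:
        return all(
            window[WINDOW_FLANK + off] == res for _, off, res in self.couplings
        )


@dataclass
class SyntheticDataset:
    """A planted-rule KsP dataset plus everything needed to audit it."""

    rules: list
    dos_profiles: dict  # kinase_id -> 63-symbol DoS string
    peptides: list  # PhosphoPeptide per interaction
    kinase_ids: list  # kinase per interaction
    labels: np.ndarray  # observed labels (after noise)
    true_labels: np.ndarray  # noise-free labels
    seed: int

    def encoded(self) -> np.ndarray:
        """Dense (n, 1638) one-hot input matrix."""
        return np.stack(
            [
                encode_pair(self.dos_profiles[k], p, kinase_id=k).bits
                for k, p in zip(self.kinase_ids, self.peptides)
            ]
        ).astype(np.float64)

    @property
    def acceptors(self) -> list:
        return [p.acceptor for p in self.peptides]


def _random_protein(rng, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(N_AA, size=length))


def gen_family_msa(
    n_seqs: int,
    n_columns: int,
    mutation_rate: float = 0.1,
    indel_rate: float = 0.02,
    seed: int = 0,
) -> list:
    """Aligned family: a common ancestor independently mutated per row.

    Each cell mutates to a random other residue with ``mutation_rate`` and
    is gapped with ``indel_rate``.  Returns a list of row strings.
    """
    if not (0 <= mutation_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if n_seqs < 1 or n_columns < 1:
        raise ValueError("n_seqs and n_columns must be >= 1")
    rng = np.random.default_rng(seed)
    ancestor = _random_protein(rng, n_columns)
    rows = []
    for _ in range(n_seqs):
        chars = list(ancestor)
        for c in range(n_columns):
            if rng.random() < mutation_rate:
                chars[c] = AMINO_ACIDS[rng.integers(N_AA)]
            if rng.random() < indel_rate:
                chars[c] = GAP
        rows.append("".join(chars))
    return rows


def sample_domain(hmm, rng) -> str:
    """Sample a domain sequence from a profile's match emissions."""
    out = []
    for j in range(hmm.n_match):
        out.append(AMINO_ACIDS[rng.choice(N_AA, p=hmm.match_emissions[j])])
    return "".join(out)


def gen_proteome(
    n_proteins: int,
    length_range=(100, 300),
    implant_profile=None,
    n_implants: int = 0,
    seed: int = 0,
    composition=None,
):
    """Random proteome with optional implanted domains.

    Background residues are i.i.d. (uniform unless ``composition`` gives
    per-residue probabilities); implants are sampled from the profile's
    match emissions and written over a random stretch of distinct
    proteins.  Returns ``(proteome dict, truth list of (protein_id,
    start, end))`` with 0-based half-open coordinates.
    """
    rng = np.random.default_rng(seed)
    if n_implants > 0 and implant_profile is None:
        raise ValueError("implants requested without an implant profile")
    if n_implants > n_proteins:
        raise ValueError("more implants than proteins")
    lo, hi = length_range
    if implant_profile is not None and implant_profile.n_match > lo:
        raise ValueError("implant does not fit within the shortest protein")
    proteome, truth = {}, []
    implant_into = set(rng.choice(n_proteins, size=n_implants, replace=False).tolist())
    for p in range(n_proteins):
        pid = f"prot{p:04d}"
        length = int(rng.integers(lo, hi + 1))
        if composition is None:
            seq = _random_protein(rng, length)
        else:
            seq = "".join(AMINO_ACIDS[i] for i in rng.choice(N_AA, size=length, p=composition))
        if p in implant_into:
            domain = sample_domain(implant_profile, rng)
            start = int(rng.integers(0, length - len(domain) + 1))
            seq = seq[:start] + domain + seq[start + len(domain) :]
            truth.append((pid, start, start + len(domain)))
        proteome[pid] = seq
    return proteome, truth


def make_rules(
    n_kinases: int,
    n_couplings: int = 3,
    seed: int = 0,
    acceptors: str = PHOSPHOACCEPTORS,
) -> list:
    """Random planted rules, one per kinase, with distinct coupled slots."""
    rng = np.random.default_rng(seed)
    offsets = [o for o in range(-WINDOW_FLANK, WINDOW_FLANK + 1) if o != 0]
    rules = []
    for k in range(n_kinases):
        slots = rng.choice(N_DOS, size=n_couplings, replace=False)
        offs = rng.choice(len(offsets), size=n_couplings, replace=False)
        couplings = tuple(
            (int(s), offsets[o], AMINO_ACIDS[rng.integers(N_AA)])
            for s, o in zip(slots, offs)
        )
        rules.append(
            PlantedRule(
                kinase_id=f"kin{k:03d}",
                couplings=couplings,
                acceptor=acceptors[k % len(acceptors)],
            )
        )
    return rules


def _random_window(rng, acceptor: str) -> list:
    chars = [AMINO_ACIDS[i] for i in rng.integers(N_AA, size=WINDOW_LENGTH)]
    chars[WINDOW_FLANK] = acceptor
    return chars


def gen_ksp(
    rules,
    n_pos_per_kinase: int = 200,
    n_neg_per_kinase: int = 200,
    label_noise: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Planted-rule KsP dataset: positives satisfy every coupling of their
    kinase's rule, negatives violate at least one; ``label_noise`` flips
    that fraction of labels (chosen without replacement, seeded)."""
    rules = list(rules)
    if not rules:
        raise ValueError("no rules given")
    if not 0.0 <= label_noise <= 0.5:
        raise ValueError("label_noise must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)

    dos_profiles = {}
    for rule in rules:
        symbols = [AMINO_ACIDS[i] for i in rng.integers(N_AA, size=N_DOS)]
        for slot, _, res in rule.couplings:
            symbols[slot] = res
        dos_profiles[rule.kinase_id] = "".join(symbols)

    peptides, kinase_ids, labels = [], [], []
    counter = 0
    for rule in rules:
        for _ in range(n_pos_per_kinase):
            chars = _random_window(rng, rule.acceptor)
            for _, off, res in rule.couplings:
                chars[WINDOW_FLANK + off] = res
            peptides.append(
                PhosphoPeptide(
                    protein_id=f"sub{counter:05d}",
                    site_pos=WINDOW_FLANK,
                    acceptor=rule.acceptor,
                    window="".join(chars),
                )
            )
            kinase_ids.append(rule.kinase_id)
            labels.append(1)
            counter += 1
        for _ in range(n_neg_per_kinase):
            while True:
                chars = _random_window(rng, rule.acceptor)
                if not rule.window_satisfies("".join(chars)):
                    break
            peptides.append(
                PhosphoPeptide(
                    protein_id=f"sub{counter:05d}",
                    site_pos=WINDOW_FLANK,
                    acceptor=rule.acceptor,
                    window="".join(chars),
                )
            )
            kinase_ids.append(rule.kinase_id)
            labels.append(0)
            counter += 1

    true_labels = np.asarray(labels, dtype=int)
    observed = true_labels.copy()
    n_flip = round(label_noise * len(observed))
    if n_flip:
        flip_idx = rng.choice(len(observed), size=n_flip, replace=False)
        observed[flip_idx] = 1 - observed[flip_idx]
    return SyntheticDataset(
        rules=rules,
        dos_profiles=dos_profiles,
        peptides=peptides,
        kinase_ids=kinase_ids,
        labels=observed,
        true_labels=true_labels,
        seed=seed,
    )


def recompute_true_labels(dataset: SyntheticDataset) -> np.ndarray:
    """Independent checker: re-derive noise-free labels from the rules."""
    rule_by_kinase = {r.kinase_id: r for r in dataset.rules}
    return np.array(
        [
            int(rule_by_kinase[k].window_satisfies(p.window))
            for k, p in zip(dataset.kinase_ids, dataset.peptides)
        ],
        dtype=int,
    )
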