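"""Evolutionary conservation of kinase-specific phosphorylations.

Human kinase-substrate phosphorylation events are traced into other
organisms through 1:1 orthologs: the human substrate is globally aligned
(Needleman-Wunsch, affine gaps, BLOSUM62 by default) to its ortholog, the
phosphosite is mapped through the alignment, and the site counts as
conserved when the orthologous position carries a compatible
phosphoacceptor.  Aggregating over organisms ordered by divergence time
yields conservation-fraction profiles, overall and per kinase group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import GAP

logger = logging.getLogger("akid")

_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass(frozen=True)
class OrthologPair:
    human_id: str
    ortholog_id: str
    organism: str
    relation: str = "1:1"


@dataclass
class GlobalAlignment:
    """Result of a global pairwise alignment.

    ``pairs``: ordered ``(i, j)`` tuples over 0-based residue indices;
    ``i is None`` marks a gap in the first sequence, ``j is None`` in the
    second.
    """

    score: float
    pairs: list

    @property
    def aligned_strings(self):
        return self.pairs


@dataclass
class ConservationRecord:
    organism: str
    divergence_mya: float
    n_mappable: int
    n_conserved: int
    group: str = "ALL"

    @property
    def fraction(self):
        if self.n_mappable == 0:
            return None
        return self.n_conserved / self.n_mappable


class SimpleScorer:
    """Match/mismatch substitution scores (for tests and identity scans)."""

    def __init__(self, match: float = 1.0, mismatch: float = -1.0):
        self.match = match
        self.mismatch = mismatch

    def __call__(self, a: str, b: str) -> float:
        return self.match if a == b else self.mismatch


class MatrixScorer:
    """Substitution scores from a named Biopython matrix (default BLOSUM62)."""

    def __init__(self, name: str = "BLOSUM62"):
        self._m = substitution_matrices.load(name)

    def __call__(self, a: str, b: str) -> float:
        try:
            return float(self._m[a, b])
        except (KeyError, IndexError):
            return float(self._m["X", "X"]) if "X" in self._m.alphabet else 0.0


def needleman_wunsch(
    a: str,
    b: str,
    substitution=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> GlobalAlignment:
    """Optimal global alignment under affine gap penalties (Gotoh).

    A gap of length k costs ``gap_open + k * gap_extend`` (both
    non-positive; pass ``gap_open=0`` for linear gaps).  ``substitution``
    is a callable ``(a, b) -> score``; BLOSUM62 when omitted.  Equal-scoring
    tracebacks resolve deterministically diagonal > up (gap in ``b``) >
    left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sub = substitution or MatrixScorer()
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), -np.inf)  # a[i-1] aligned to b[j-1]
    X = np.full((n + 1, m + 1), -np.inf)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), -np.inf)  # gap in a (consume b)
    M[0, 0] = 0.0
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    for i in range(1, n + 1):
        X[i, 0] = gap_open + i * gap_extend
        pX[i, 0] = _DIAG if i == 1 else _UP
    for j in range(1, m + 1):
        Y[0, j] = gap_open + j * gap_extend
        pY[0, j] = _DIAG if j == 1 else _LEFT

    def _best3(dm, du, dl):
        # tie-break: diagonal-source > up-source > left-source
        best, ptr = dm, _DIAG
        if du > best:
            best, ptr = du, _UP
        if dl > best:
            best, ptr = dl, _LEFT
        return best, ptr

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(a[i - 1], b[j - 1])
            best, ptr = _best3(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j], pM[i, j] = best + s, ptr
            X[i, j], pX[i, j] = _best3(
                M[i - 1, j] + gap_open + gap_extend,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open + gap_extend,
            )
            Y[i, j], pY[i, j] = _best3(
                M[i, j - 1] + gap_open + gap_extend,
                X[i, j - 1] + gap_open + gap_extend,
                Y[i, j - 1] + gap_extend,
            )

    score, state = _best3(M[n, m], X[n, m], Y[n, m])
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _DIAG:
            pairs.append((i - 1, j - 1))
            state = pM[i, j]
            i, j = i - 1, j - 1
        elif state == _UP:
            pairs.append((i - 1, None))
            state = pX[i, j]
            i -= 1
        else:
            pairs.append((None, j - 1))
            state = pY[i, j]
            j -= 1
    pairs.reverse()
    return GlobalAlignment(score=float(score), pairs=pairs)


def map_site(alignment: GlobalAlignment, human_site_pos: int):
    """Index in the second sequence aligned to a position of the first.

    Returns ``None`` when the human position sits opposite a gap in the
    ortholog.
    """
    for i, j in alignment.pairs:
        if i == human_site_pos:
            return j
    raise ValueError(f"position {human_site_pos} not covered by the alignment")


def alignment_identity(a: str, b: str, substitution=None, **kw) -> float:
    """Fraction of identical aligned positions over the shorter sequence."""
    aln = needleman_wunsch(a, b, substitution or SimpleScorer(), **kw)
    matches = sum(
        1 for i, j in aln.pairs if i is not None and j is not None and a[i] == b[j]
    )
    return matches / min(len(a), len(b))


def conservation_profile(
    ksp_set,
    ortholog_pairs,
    human_proteome: dict,
    ortholog_proteomes: dict,
    divergence_times: dict,
    group_map: dict | None = None,
    *,
    st_equivalent: bool = False,
    substitution=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> list:
    """Count mappable and conserved KsP per organism (and kinase group).

    A KsP is *mappable* in an organism when both its kinase and its
    substrate have a 1:1 ortholog there; it is *conserved* when the
    substrate alignment maps the phosphosite onto a residue equal to the
    human acceptor (S and T interchangeable under ``st_equivalent``).
    Records are sorted by divergence time; organisms missing a divergence
    time are kept with ``nan`` and logged.
    """
    group_map = group_map or {}
    by_org: dict = {}
    for pair in ortholog_pairs:
        if pair.relation != "1:1":
            logger.warning(
                "dropping non-1:1 ortholog record %s/%s (%s)",
                pair.human_id,
                pair.ortholog_id,
                pair.relation,
            )
            continue
        by_org.setdefault(pair.organism, {})[pair.human_id] = pair.ortholog_id

    aln_cache: dict = {}
    records = []
    for organism in sorted(by_org):
        orth = by_org[organism]
        prot = ortholog_proteomes.get(organism, {})
        mya = divergence_times.get(organism)
        if mya is None:
            logger.warning("no divergence time for %s", organism)
            mya = float("nan")
        counts: dict = {}
        for ksp in ksp_set:
            kin, subst = ksp.kinase_id, ksp.substrate_id
            if kin not in orth or subst not in orth:
                continue
            orth_id = orth[subst]
            if orth_id not in prot or subst not in human_proteome:
                continue
            key = (organism, subst)
            if key not in aln_cache:
                aln_cache[key] = needleman_wunsch(
                    human_proteome[subst],
                    prot[orth_id],
                    substitution,
                    gap_open=gap_open,
                    gap_extend=gap_extend,
                )
            mapped = map_site(aln_cache[key], ksp.site_pos)
            conserved = False
            if mapped is not None:
                res = prot[orth_id][mapped]
                if res == ksp.acceptor:
                    conserved = True
                elif st_equivalent and {res, ksp.acceptor} <= {"S", "T"}:
                    conserved = True
            for group in ("ALL", group_map.get(kin)):
                if group is None:
                    continue
                n_map, n_cons = counts.get(group, (0, 0))
                counts[group] = (n_map + 1, n_cons + int(conserved))
        for group, (n_map, n_cons) in sorted(counts.items()):
            records.append(
                ConservationRecord(
                    organism=organism,
                    divergence_mya=mya,
                    n_mappable=n_map,
                    n_conserved=n_cons,
                    group=group,
                )
            )
    records.sort(key=lambda r: (r.divergence_mya, r.organism, r.group))
    return records
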