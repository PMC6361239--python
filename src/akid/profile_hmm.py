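"""Profile hidden Markov model for kinase-domain detection.

A Plan7-style profile (match/insert/delete states, one match state per
sufficiently occupied alignment column) is estimated from a curated
kinase-domain MSA and used in two modes:

* glocal scanning — the full profile aligned against any subsequence of a
  protein (Viterbi, log-odds against a background residue model), to find
  kinase domains in a proteome; significance is assessed against an
  empirical null of scores on shuffled copies of the same protein;
* global alignment — a detected domain sequence aligned end-to-end to the
  profile, which is how determinant-of-specificity (DoS) columns are read
  off each domain.

Scores are log-odds in bits (log2 of the Viterbi path probability over the
background probability of the emitted residues).  Insert states emit at
the background distribution, so they contribute only transition costs.
State topology is the classic profile-HMM one (Durbin et al.): M->M/I/D,
I->M/I, D->M/D; no I<->D transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, GAP, AA_INDEX, normalize_sequence

logger = logging.getLogger("akid")

N_AA = 20
NEG_INF = -np.inf

# traceback codes
_FROM_M, _FROM_I, _FROM_D, _FROM_START = 0, 1, 2, 3


@dataclass
class ProfileHMM:
    """Profile HMM over the 20 amino acids.

    ``match_emissions``: (n_match, 20) probabilities; ``insert_emissions``:
    (20,) background probabilities (shared by all insert states and used as
    the null model); ``transitions``: dict of (n_match + 1,) probability
    arrays keyed 'mm','mi','md','im','ii','dm','dd', where index j holds the
    transitions leaving column j (j=0 is the begin state, j=n_match feeds
    the end state).
    """

    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict
    n_match: int
    alphabet: str = AMINO_ACIDS + GAP

    def __post_init__(self) -> None:
        if self.n_match < 1:
            raise ValueError("profile must have at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.insert_emissions.sum(), 1.0, atol=1e-9):
            raise ValueError("insert emissions must sum to 1")
        # precomputed log2 scores
        self._lods = np.log2(self.match_emissions / self.insert_emissions)
        self._lt = {k: np.log2(v) for k, v in self.transitions.items()}

    @property
    def consensus(self) -> str:
        """Most probable residue of each match state."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))


@dataclass
class DomainAlignment:
    """Profile <-> residue correspondence for one aligned domain.

    ``pairs`` is an ordered list of ``(column, residue)`` tuples, 0-based;
    ``column is None`` marks an insertion, ``residue is None`` a deletion.
    """

    pairs: list

    def residue_for_column(self, column: int):
        for col, res in self.pairs:
            if col == column:
                return res
        return None

    @property
    def matched_columns(self) -> list:
        return [col for col, res in self.pairs if col is not None]

    @property
    def aligned_residues(self) -> list:
        return [res for _, res in self.pairs if res is not None]


@dataclass
class KinaseDomainHit:
    """One detected kinase domain: protein coordinates, score, significance."""

    protein_id: str
    start: int  # 0-based, half-open
    end: int
    bit_score: float
    p_value: float
    alignment: DomainAlignment


@dataclass(frozen=True)
class DoSProfile:
    """Residues (or gaps) at the configured DoS columns of one kinase domain."""

    kinase_id: str
    domain_index: int
    symbols: str


def build_profile(msa, occupancy_threshold: float = 0.5) -> ProfileHMM:
    """Estimate a profile HMM from an aligned set of sequences.

    Columns whose residue occupancy (fraction of non-gap rows) is at least
    ``occupancy_threshold`` become match states.  Match emissions use
    Laplace (+1) pseudocounts on the column residue counts; transition
    probabilities are estimated from the observed per-row state paths,
    again with +1 pseudocounts.  Insert/background emissions come from the
    overall residue counts of the MSA (+1).
    """
    rows = list(msa)
    if not rows:
        raise ValueError("empty MSA")
    width = len(rows[0])
    norm_rows = []
    for r, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"ragged MSA: row {r} has length {len(row)}, expected {width}"
            )
        norm_rows.append(normalize_sequence(row, context=f"MSA row {r}"))
    rows = norm_rows

    occupancy = np.array(
        [sum(1 for row in rows if row[c] != GAP) / len(rows) for c in range(width)]
    )
    match_cols = [c for c in range(width) if occupancy[c] >= occupancy_threshold]
    if not match_cols:
        raise ValueError("no column reaches the occupancy threshold")
    L = len(match_cols)
    match_set = set(match_cols)

    # emissions
    counts = np.zeros((L, N_AA))
    for row in rows:
        for j, c in enumerate(match_cols):
            if row[c] != GAP:
                counts[j, AA_INDEX[row[c]]] += 1
    match_em = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + N_AA)

    bg_counts = np.zeros(N_AA)
    for row in rows:
        for ch in row:
            if ch != GAP:
                bg_counts[AA_INDEX[ch]] += 1
    insert_em = (bg_counts + 1.0) / (bg_counts.sum() + N_AA)

    # transitions from observed state paths, +1 pseudocounts
    tc = {k: np.ones(L + 1) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    for row in rows:
        state, j = "m", 0  # begin acts as M_0
        for c in range(width):
            if c in match_set:
                new = "m" if row[c] != GAP else "d"
                if state + new in tc:  # topology has no I->D; skip those
                    tc[state + new][j] += 1
                state, j = new, j + 1
            elif row[c] != GAP:
                # residue in an insert column; the topology has no D->I, so
                # insertions inside a delete run are ignored for counting
                if state != "d":
                    tc[state + "i"][j] += 1
                    state = "i"
            # gap in an insert column emits nothing
        tc[state + "m"][j] += 1  # exit to end

    trans = {}
    # normalize per source state; at j the valid targets are
    #   M_j -> {M_{j+1}, I_j, D_{j+1}} (no D beyond column L)
    #   I_j -> {M_{j+1}, I_j}
    #   D_j -> {M_{j+1}, D_{j+1}}
    m_tot = tc["mm"] + tc["mi"] + tc["md"]
    i_tot = tc["im"] + tc["ii"]
    d_tot = tc["dm"] + tc["dd"]
    # no D_{L+1}: renormalize last column without the md/dd branches
    m_tot[L] = tc["mm"][L] + tc["mi"][L]
    d_tot[L] = tc["dm"][L]
    trans["mm"] = tc["mm"] / m_tot
    trans["mi"] = tc["mi"] / m_tot
    trans["md"] = tc["md"] / m_tot
    trans["md"][L] = 1e-300  # effectively impossible
    trans["im"] = tc["im"] / i_tot
    trans["ii"] = tc["ii"] / i_tot
    trans["dm"] = tc["dm"] / d_tot
    trans["dd"] = tc["dd"] / d_tot
    trans["dd"][L] = 1e-300

    return ProfileHMM(
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        n_match=L,
    )


def _encode(seq: str) -> np.ndarray:
    """Residue string -> background-index array; gaps are not allowed here."""
    if GAP in seq:
        raise ValueError("unaligned sequence may not contain gap characters")
    return np.array([AA_INDEX[ch] for ch in seq], dtype=np.intp)


def _viterbi(hmm: ProfileHMM, seq_idx: np.ndarray, mode: str):
    """Viterbi DP with traceback.

    mode 'glocal': full profile vs any subsequence (flanks free);
    mode 'global': full profile vs full sequence (flanking insert states).
    Tie-break when scores are equal: Match > Delete > Insert, and for ends
    earlier positions win.  Returns (score, pairs, start, end) with pairs
    as in :class:`DomainAlignment` (residue indices into ``seq_idx``).
    """
    n, L = len(seq_idx), hmm.n_match
    lods, lt = hmm._lods, hmm._lt
    vM = np.full((n + 1, L + 1), NEG_INF)
    vI = np.full((n + 1, L + 1), NEG_INF)
    vD = np.full((n + 1, L + 1), NEG_INF)
    pM = np.zeros((n + 1, L + 1), dtype=np.uint8)
    pI = np.zeros((n + 1, L + 1), dtype=np.uint8)
    pD = np.zeros((n + 1, L + 1), dtype=np.uint8)
    glocal = mode == "glocal"

    if not glocal:
        vM[0, 0] = 0.0  # begin state

    def _fill_deletes(i: int) -> None:
        """D_j for row i (D consumes no residue; depends on vM of the same row)."""
        for j in range(1, L + 1):
            sm = vM[i, j - 1] + lt["md"][j - 1]
            sd = vD[i, j - 1] + lt["dd"][j - 1]
            best, ptr = (sm, _FROM_M) if sm >= sd else (sd, _FROM_D)
            if glocal and j == 1:
                entry = lt["md"][0]  # begin -> D_1, flank free
                if entry > best:
                    best, ptr = entry, _FROM_START
            vD[i, j] = best
            pD[i, j] = ptr

    _fill_deletes(0)

    for i in range(1, n + 1):
        x = seq_idx[i - 1]
        if not glocal:
            # I_0 hosts N-terminal insertions in global mode
            sm = vM[i - 1, 0] + lt["mi"][0]
            si = vI[i - 1, 0] + lt["ii"][0]
            vI[i, 0], pI[i, 0] = (sm, _FROM_M) if sm >= si else (si, _FROM_I)
        for j in range(1, L + 1):
            # match: prefer M > D > I among equal-scoring predecessors
            sm = vM[i - 1, j - 1] + lt["mm"][j - 1]
            sd = vD[i - 1, j - 1] + lt["dm"][j - 1]
            si = vI[i - 1, j - 1] + lt["im"][j - 1]
            best, ptr = sm, _FROM_M
            if sd > best:
                best, ptr = sd, _FROM_D
            if si > best:
                best, ptr = si, _FROM_I
            if glocal and j == 1:
                entry = lt["mm"][0]  # begin -> M_1, flank free
                if entry > best:
                    best, ptr = entry, _FROM_START
            vM[i, j] = best + lods[j - 1, x]
            pM[i, j] = ptr
            # insert I_j; I_L is reachable only in global mode
            if j < L or not glocal:
                sm = vM[i - 1, j] + lt["mi"][j]
                si = vI[i - 1, j] + lt["ii"][j]
                if sm >= si:
                    vI[i, j], pI[i, j] = sm, _FROM_M
                else:
                    vI[i, j], pI[i, j] = si, _FROM_I
        _fill_deletes(i)

    # termination (prefer M > D > I on ties; earlier end positions win)
    if glocal:
        end_m = vM[:, L] + lt["mm"][L]
        end_d = vD[:, L] + lt["dm"][L]
        flat = np.maximum(end_m, end_d)
        end_i = int(np.argmax(flat))
        state = "M" if end_m[end_i] >= end_d[end_i] else "D"
        score = float(flat[end_i])
    else:
        cands = [
            (vM[n, L] + lt["mm"][L], "M"),
            (vD[n, L] + lt["dm"][L], "D"),
            (vI[n, L] + lt["im"][L], "I"),
        ]
        score, state = cands[0]
        for s, st in cands[1:]:
            if s > score:
                score, state = s, st
        end_i = n

    # traceback
    pairs = []
    i, j, st = end_i, L, state
    while True:
        if st == "M":
            ptr = pM[i, j]
            pairs.append((j - 1, i - 1))
            ni, nj = i - 1, j - 1
        elif st == "D":
            ptr = pD[i, j]
            pairs.append((j - 1, None))
            ni, nj = i, j - 1
        else:  # insert (I_j, including I_0 in global mode)
            ptr = pI[i, j]
            pairs.append((None, i - 1))
            ni, nj = i - 1, j
        if ptr == _FROM_START:
            break
        nst = {_FROM_M: "M", _FROM_I: "I", _FROM_D: "D"}[ptr]
        if nj == 0 and nst == "M":
            break  # reached the begin state (global mode)
        i, j, st = ni, nj, nst
    pairs.reverse()
    residues = [r for _, r in pairs if r is not None]
    start = residues[0] if residues else 0
    end = residues[-1] + 1 if residues else 0
    return float(score), pairs, start, end


def _batch_glocal_scores(hmm: ProfileHMM, seqs_idx: np.ndarray) -> np.ndarray:
    """Score-only glocal Viterbi, vectorized over a batch of equal-length
    sequences (rows of ``seqs_idx``).  Used for the empirical null."""
    B, n = seqs_idx.shape
    L = hmm.n_match
    lods, lt = hmm._lods, hmm._lt
    tmm, tmi, tmd = lt["mm"], lt["mi"], lt["md"]
    tim, tii = lt["im"], lt["ii"]
    tdm, tdd = lt["dm"], lt["dd"]

    M = np.full((B, L), NEG_INF)
    I = np.full((B, L), NEG_INF)
    # D row for "no residues consumed yet": pure-delete prefix from begin
    D = np.empty((B, L))
    D[:, 0] = tmd[0]
    for c in range(1, L):
        D[:, c] = D[:, c - 1] + tdd[c]
    # cumulative delete-chain costs: C[c] = sum_{j=1..c} log tdd[j]
    C = np.concatenate([[0.0], np.cumsum(tdd[1:L])])  # length L
    best = np.maximum(M[:, L - 1] + tmm[L], D[:, L - 1] + tdm[L])

    for i in range(n):
        x = seqs_idx[:, i]
        em = hmm._lods[:, x].T  # (B, L)
        prevM, prevI, prevD = M, I, D
        M = np.empty((B, L))
        M[:, 0] = tmm[0]  # fresh glocal entry
        if L > 1:
            M[:, 1:] = np.maximum.reduce(
                [
                    prevM[:, :-1] + tmm[1:L],
                    prevI[:, :-1] + tim[1:L],
                    prevD[:, :-1] + tdm[1:L],
                ]
            )
        M += em
        I = np.maximum(prevM + tmi[1 : L + 1], prevI + tii[1 : L + 1])
        # delete chain via prefix max: D[c] = C[c] + max_{p<=c} A[p]
        A = np.empty((B, L))
        A[:, 0] = tmd[0]
        if L > 1:
            A[:, 1:] = M[:, :-1] + tmd[1:L] - C[1:]
        D = np.maximum.accumulate(A, axis=1) + C
        best = np.maximum(best, np.maximum(M[:, L - 1] + tmm[L], D[:, L - 1] + tdm[L]))
    return best


def align_to_profile(hmm: ProfileHMM, domain_seq: str) -> DomainAlignment:
    """Globally align a domain sequence to the full profile (Viterbi).

    Ties are broken deterministically: Match over Delete over Insert.
    """
    if not domain_seq:
        raise ValueError("empty sequence")
    seq = normalize_sequence(domain_seq).replace(GAP, "")
    idx = _encode(seq)
    _, pairs, _, _ = _viterbi(hmm, idx, mode="global")
    return DomainAlignment(pairs=pairs)


def score_glocal(hmm: ProfileHMM, seq: str):
    """Best glocal (full profile, any subsequence) Viterbi alignment.

    Returns ``(bit_score, DomainAlignment, start, end)`` in sequence
    coordinates.
    """
    idx = _encode(normalize_sequence(seq).replace(GAP, ""))
    score, pairs, start, end = _viterbi(hmm, idx, mode="glocal")
    return score, DomainAlignment(pairs=pairs), start, end


def empirical_p_value(
    hmm: ProfileHMM,
    seq: str,
    observed_score: float,
    *,
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of residue-shuffled copies of ``seq`` scoring >= observed."""
    rng = rng or np.random.default_rng(0)
    idx = _encode(normalize_sequence(seq).replace(GAP, ""))
    shuffled = np.stack([rng.permutation(idx) for _ in range(n_shuffles)])
    null = _batch_glocal_scores(hmm, shuffled)
    return float(np.mean(null >= observed_score))


def scan_proteome(
    hmm: ProfileHMM,
    proteome: dict,
    p_threshold: float = 0.05,
    *,
    n_shuffles: int = 200,
    min_length: int = 15,
    seed: int = 0,
) -> list:
    """Find all significant, non-overlapping kinase-domain hits per protein.

    The best glocal hit is extracted, its significance assessed against an
    empirical null of ``n_shuffles`` residue shuffles, and the flanking
    segments are re-scanned recursively so multi-domain proteins yield one
    hit per domain.  Hits are sorted by protein id then start coordinate.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    rng = np.random.default_rng(seed)
    hits = []
    for pid in sorted(proteome):
        seq = normalize_sequence(proteome[pid], context=pid).replace(GAP, "").rstrip("*")
        if len(seq) < min_length:
            logger.warning("skipping %s: length %d < %d", pid, len(seq), min_length)
            continue
        segments = [(0, len(seq))]
        prot_hits = []
        while segments:
            s0, s1 = segments.pop()
            if s1 - s0 < min_length:
                continue
            sub = seq[s0:s1]
            score, aln, start, end = score_glocal(hmm, sub)
            if end <= start:
                continue
            p = empirical_p_value(hmm, sub, score, n_shuffles=n_shuffles, rng=rng)
            if p >= p_threshold:
                continue
            shifted = DomainAlignment(
                pairs=[(c, None if r is None else r + s0) for c, r in aln.pairs]
            )
            prot_hits.append(
                KinaseDomainHit(
                    protein_id=pid,
                    start=start + s0,
                    end=end + s0,
                    bit_score=score,
                    p_value=p,
                    alignment=shifted,
                )
            )
            segments.append((s0, s0 + start))
            segments.append((s0 + end, s1))
        hits.extend(sorted(prot_hits, key=lambda h: h.start))
    hits.sort(key=lambda h: (h.protein_id, h.start))
    return hits


def map_dos(
    alignment: DomainAlignment,
    domain_seq: str,
    dos_columns,
    *,
    kinase_id: str = "",
    domain_index: int = 0,
) -> DoSProfile:
    """Read the residues at the DoS columns off a domain-to-profile alignment.

    Deleted DoS columns yield the gap symbol, so the output length always
    equals ``len(dos_columns)``.
    """
    cols = list(dos_columns)
    if cols != sorted(set(cols)):
        raise ValueError("dos_columns must be sorted and unique")
    max_col = max((c for c, _ in alignment.pairs if c is not None), default=-1)
    lookup = {c: r for c, r in alignment.pairs if c is not None}
    symbols = []
    for c in cols:
        if c not in lookup:
            if c > max_col:
                raise ValueError(f"DoS column {c} outside the profile range")
            symbols.append(GAP)
            continue
        r = lookup[c]
        symbols.append(GAP if r is None else domain_seq[r])
    return DoSProfile(kinase_id=kinase_id, domain_index=domain_index, symbols="".join(symbols))


def jaccard_overlap(hit_residues, annotated_residues) -> float:
    """Jaccard index |A & B| / |A | B| between two residue-index sets."""
    a, b = set(hit_residues), set(annotated_residues)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def load_dos_columns(path) -> list:
    """Read a DoS configuration file: one 0-based profile column per line."""
    cols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                cols.append(int(line))
    return cols
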