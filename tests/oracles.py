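"""Independent brute-force oracles used to validate the dynamic-programming
and rank-statistic implementations.  Everything here enumerates explicitly
and never calls the code under test."""

from __future__ import annotations

import numpy as np

from akid.alphabet import AA_INDEX


def brute_glocal_score(hmm, seq: str) -> float:
    """Best glocal path score by explicit enumeration of all state paths."""
    L = hmm.n_match
    lods, lt = hmm._lods, hmm._lt
    n = len(seq)
    idx = [AA_INDEX[c] for c in seq]
    best = [-np.inf]

    def rec(j, i, score, prev):
        if j == L:
            if prev == "m":
                best[0] = max(best[0], score + lt["mm"][L])
            elif prev == "d":
                best[0] = max(best[0], score + lt["dm"][L])
            return
        tM = {"m": lt["mm"][j], "i": lt["im"][j], "d": lt["dm"][j]}[prev]
        tD = {"m": lt["md"][j], "d": lt["dd"][j]}.get(prev)
        if i < n:
            rec(j + 1, i + 1, score + tM + lods[j, idx[i]], "m")
        if tD is not None:
            rec(j + 1, i, score + tD, "d")
        if 1 <= j < L and prev in ("m", "i") and i < n:
            tI = {"m": lt["mi"][j], "i": lt["ii"][j]}[prev]
            rec(j, i + 1, score + tI, "i")

    for start in range(n + 1):  # residues consumed by the free flank
        rec(0, start, 0.0, "m")
    return best[0]


def brute_global_score(hmm, seq: str) -> float:
    """Best global (full profile, full sequence) path score by enumeration."""
    L = hmm.n_match
    lods, lt = hmm._lods, hmm._lt
    n = len(seq)
    idx = [AA_INDEX[c] for c in seq]
    best = [-np.inf]

    def rec(j, i, score, prev):
        if j == L:
            if i == n:
                t = {"m": lt["mm"][L], "i": lt["im"][L], "d": lt["dm"][L]}[prev]
                best[0] = max(best[0], score + t)
            if i < n and prev in ("m", "i"):
                tI = {"m": lt["mi"][L], "i": lt["ii"][L]}[prev]
                rec(L, i + 1, score + tI, "i")
            return
        tM = {"m": lt["mm"][j], "i": lt["im"][j], "d": lt["dm"][j]}[prev]
        tD = {"m": lt["md"][j], "d": lt["dd"][j]}.get(prev)
        if i < n:
            rec(j + 1, i + 1, score + tM + lods[j, idx[i]], "m")
        if tD is not None:
            rec(j + 1, i, score + tD, "d")
        if prev in ("m", "i") and i < n:
            tI = {"m": lt["mi"][j], "i": lt["ii"][j]}[prev]
            rec(j, i + 1, score + tI, "i")

    rec(0, 0, 0.0, "m")
    return best[0]


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment as a list of ('M'|'X'|'Y') moves.
    X consumes a residue of ``a`` (gap in ``b``), Y the reverse."""
    def rec(i, j, moves):
        if i == len(a) and j == len(b):
            yield list(moves)
            return
        if i < len(a) and j < len(b):
            moves.append("M")
            yield from rec(i + 1, j + 1, moves)
            moves.pop()
        if i < len(a):
            moves.append("X")
            yield from rec(i + 1, j, moves)
            moves.pop()
        if j < len(b):
            moves.append("Y")
            yield from rec(i, j + 1, moves)
            moves.pop()

    yield from rec(0, 0, [])


def score_alignment(a, b, moves, sub, gap_open, gap_extend) -> float:
    """Score a move string: substitution per M, gap_open + k*gap_extend per
    maximal gap run."""
    score, i, j = 0.0, 0, 0
    prev = None
    for mv in moves:
        if mv == "M":
            score += sub(a[i], b[j])
            i, j = i + 1, j + 1
        else:
            if mv != prev:
                score += gap_open
            score += gap_extend
            if mv == "X":
                i += 1
            else:
                j += 1
        prev = mv
    return score


def brute_nw_score(a, b, sub, gap_open, gap_extend) -> float:
    return max(
        score_alignment(a, b, mv, sub, gap_open, gap_extend)
        for mv in enumerate_alignments(a, b)
    )


def brute_identity(a: str, b: str) -> float:
    """Max identical aligned positions over any global alignment, divided by
    the shorter length."""
    best = 0
    for mv in enumerate_alignments(a, b):
        i = j = matches = 0
        for m in mv:
            if m == "M":
                matches += a[i] == b[j]
                i, j = i + 1, j + 1
            elif m == "X":
                i += 1
            else:
                j += 1
        best = max(best, matches)
    return best / min(len(a), len(b))


def pairwise_auc(scores, labels) -> float:
    """AUC as the mean over all positive-negative pairs; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_mwu(x, y) -> float:
    """Mann-Whitney U of sample x: #{x_i > y_j} + 0.5 #{x_i == y_j}."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u
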