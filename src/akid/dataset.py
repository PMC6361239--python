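"""Construction of labeled kinase-substrate interaction datasets.

Curated kinase-specific phosphorylation (KsP) tables are ingested, their
sites re-anchored onto the working proteome, interactions of multi-domain
kinases excluded (public databases do not say which domain is active),
kinase domains clustered at 70% identity, and negatives generated under
two regimes: peptides drawn from the annotated phosphoproteome, or
windows centered on arbitrary S/T/Y residues of the proteome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import edlib
import pandas as pd

from .alphabet import GAP, PHOSPHOACCEPTORS, normalize_sequence
from .encoding import WINDOW_FLANK, WINDOW_LENGTH, PhosphoPeptide, extract_peptide
from .evolution import SimpleScorer, needleman_wunsch

logger = logging.getLogger("akid")

REQUIRED_COLUMNS = ("kinase_id", "substrate_id", "position", "acceptor")

SOURCE_CURATED = "curated"
SOURCE_ANNOTATED_BG = "annotated-phospho-background"
SOURCE_RANDOM_BG = "random-STY-background"


@dataclass(frozen=True)
class KsPInteraction:
    """One kinase-domain / substrate / site record with its label."""

    kinase_id: str
    substrate_id: str
    site_pos: int  # 0-based
    acceptor: str
    label: str = "positive"  # positive | negative
    source: str = SOURCE_CURATED
    domain_index: int = 0
    window: str | None = None

    @property
    def key(self):
        return (self.kinase_id, self.substrate_id, self.site_pos)


@dataclass(frozen=True)
class KinaseCluster:
    representative_id: str
    member_ids: tuple


def load_ksp_table(path) -> list:
    """Read a PhosphoSitePlus/PhosphoGRID-style TSV of KsP records.

    Required columns: kinase_id, substrate_id, position (1-based),
    acceptor; an optional ``window`` column carries the 15-mer context.
    Malformed rows are rejected with their line numbers logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"KsP table missing required column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            pos = int(row["position"])
            if pos < 1:
                raise ValueError
        except (TypeError, ValueError):
            logger.warning("line %d: non-integer position %r, row rejected", line_no, row["position"])
            continue
        acceptor = str(row["acceptor"]).strip().upper()
        if acceptor not in PHOSPHOACCEPTORS:
            logger.warning("line %d: acceptor %r not S/T/Y, row rejected", line_no, row["acceptor"])
            continue
        window = None
        if "window" in df.columns and isinstance(row.get("window"), str):
            w = row["window"].strip().upper()
            if len(w) == WINDOW_LENGTH:
                window = w
        records.append(
            KsPInteraction(
                kinase_id=str(row["kinase_id"]).strip(),
                substrate_id=str(row["substrate_id"]).strip(),
                site_pos=pos - 1,
                acceptor=acceptor,
                window=window,
            )
        )
    return records


def _find_window(window: str, seq: str, min_identity: float):
    """Locate a 15-mer in a protein: exact first, then edlib infix alignment."""
    core = window.replace(GAP, "")
    offset = window.index(core[0]) if core else 0
    pos = seq.find(core)
    if pos >= 0 and seq.find(core, pos + 1) < 0:
        return pos + (WINDOW_FLANK - offset)
    max_dist = int(len(core) * (1.0 - min_identity))
    res = edlib.align(core, seq, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start = res["locations"][0][0]
    return start + (WINDOW_FLANK - offset)


def map_sites(interactions, proteome: dict, *, min_identity: float = 0.8) -> list:
    """Re-anchor each KsP site onto the working proteome.

    A record with a context window is located by exact 15-mer match, then
    by edlib infix alignment at >= ``min_identity``; without a window the
    annotated coordinate is validated directly.  Unmappable records are
    dropped and counted.
    """
    mapped, dropped = [], 0
    for rec in interactions:
        seq = proteome.get(rec.substrate_id)
        if seq is None:
            dropped += 1
            continue
        seq = normalize_sequence(seq, context=rec.substrate_id).rstrip("*")
        pos = None
        if rec.window is not None:
            pos = _find_window(rec.window, seq, min_identity)
        elif 0 <= rec.site_pos < len(seq) and seq[rec.site_pos] == rec.acceptor:
            pos = rec.site_pos
        if pos is None or not (0 <= pos < len(seq)) or seq[pos] != rec.acceptor:
            dropped += 1
            continue
        pep = extract_peptide(seq, pos, protein_id=rec.substrate_id)
        mapped.append(replace(rec, site_pos=pos, window=pep.window))
    if dropped:
        logger.info("map_sites: dropped %d unmappable record(s)", dropped)
    return mapped


def exclude_multidomain(interactions, hits) -> list:
    """Drop interactions whose kinase has zero or multiple detected domains.

    Databases do not record which of several kinase domains is active, so
    only single-domain kinases remain; kinases with no detected domain are
    removed too (no DoS profile can be built for them) with a warning.
    """
    n_domains: dict = {}
    for h in hits:
        n_domains[h.protein_id] = n_domains.get(h.protein_id, 0) + 1
    kept = []
    for rec in interactions:
        n = n_domains.get(rec.kinase_id, 0)
        if n == 1:
            kept.append(rec)
        elif n == 0:
            logger.warning("kinase %s has no detected domain; interaction removed", rec.kinase_id)
    return kept


def cluster_70(domain_seqs: dict, identity_threshold: float = 0.70) -> list:
    """Greedy longest-first clustering at a sequence-identity threshold.

    Sequences are visited by decreasing length (ties by id); each joins
    the first existing cluster whose representative shares at least the
    threshold identity (identical aligned positions over the shorter
    sequence, via global alignment), otherwise it founds a new cluster.
    """
    if not domain_seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(domain_seqs, key=lambda k: (-len(domain_seqs[k]), k))
    reps: list = []
    members: dict = {}
    for sid in order:
        seq = domain_seqs[sid]
        placed = False
        for rep in reps:
            if _identity(seq, domain_seqs[rep]) >= identity_threshold:
                members[rep].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            members[sid] = [sid]
    return [KinaseCluster(representative_id=r, member_ids=tuple(members[r])) for r in reps]


def _identity(a: str, b: str) -> float:
    aln = needleman_wunsch(a, b, SimpleScorer(1.0, -1.0), gap_open=0.0, gap_extend=-1.0)
    matches = sum(
        1 for i, j in aln.pairs if i is not None and j is not None and a[i] == b[j]
    )
    return matches / min(len(a), len(b))


def make_negatives(
    positives,
    background_pool,
    regime: str,
    n_per_positive: int = 1,
    seed: int = 0,
    *,
    match_acceptor: bool = False,
) -> list:
    """Pair each positive's kinase with random background peptides.

    ``regime`` names the pool semantics: ``annotated-phospho`` (peptides
    from the annotated phosphoproteome) or ``random-STY`` (windows around
    arbitrary S/T/Y residues).  A draw is rejected when that
    (kinase, substrate, site) is a known positive or already sampled; with
    ``match_acceptor`` the peptide must share the positive's acceptor type.
    """
    import numpy as np

    if regime not in ("annotated-phospho", "random-STY"):
        raise ValueError(f"unknown regime {regime!r}")
    if not background_pool:
        raise ValueError("empty background pool")
    source = SOURCE_ANNOTATED_BG if regime == "annotated-phospho" else SOURCE_RANDOM_BG
    rng = np.random.default_rng(seed)
    positive_keys = {p.key for p in positives}
    taken: set = set()
    negatives = []
    for pos in positives:
        pool = background_pool
        if match_acceptor:
            pool = [p for p in background_pool if p.acceptor == pos.acceptor]
        for _ in range(n_per_positive):
            candidates = [
                p
                for p in pool
                if (pos.kinase_id, p.protein_id, p.site_pos) not in positive_keys
                and (pos.kinase_id, p.protein_id, p.site_pos) not in taken
            ]
            if not candidates:
                raise ValueError(
                    f"background pool exhausted for kinase {pos.kinase_id}"
                )
            pep = candidates[rng.integers(len(candidates))]
            taken.add((pos.kinase_id, pep.protein_id, pep.site_pos))
            negatives.append(
                KsPInteraction(
                    kinase_id=pos.kinase_id,
                    substrate_id=pep.protein_id,
                    site_pos=pep.site_pos,
                    acceptor=pep.acceptor,
                    label="negative",
                    source=source,
                    window=pep.window,
                )
            )
    return negatives


def window_identity(w1: str, w2: str) -> float:
    """Positional identity between two 15-mer windows (gaps never match)."""
    return sum(1 for a, b in zip(w1, w2) if a == b and a != GAP) / WINDOW_LENGTH


def deduplicate_vs_training(test_interactions, training_windows, identity_cut: float = 0.5) -> list:
    """Remove test records whose window exceeds the identity cut against
    any training window (redundancy guard between test and training sets)."""
    kept = []
    for rec in test_interactions:
        if rec.window is None:
            kept.append(rec)
            continue
        if any(window_identity(rec.window, tw) > identity_cut for tw in training_windows):
            continue
        kept.append(rec)
    return kept


def dataset_manifest(interactions) -> dict:
    """Counts per label / acceptor / source, for the dataset manifest file."""
    manifest: dict = {"n_total": len(interactions)}
    for rec in interactions:
        for key in (
            f"n_label_{rec.label}",
            f"n_acceptor_{rec.acceptor}",
            f"n_source_{rec.source}",
        ):
            manifest[key] = manifest.get(key, 0) + 1
    return manifest
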