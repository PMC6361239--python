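"""Screening of missense mutations that destroy or create phosphosites.

Pathogenic mutations with a modest structural-impact score (Polyphen-style,
supplied as input, < 0.5 by default) are kept when they hit a
phosphoacceptor (site lost) or introduce one (site gained).  The affected
peptide windows are scored against a kinome of DoS profiles; predictions
passing the per-acceptor thresholds are finally sanity-checked by their
proximity in a physical protein-protein interaction network (kinase-target
pairs should be closer than random protein pairs; one-sided Mann-Whitney U).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu

from .alphabet import PHOSPHOACCEPTORS
from .dnn_model import TrainedModel, predict
from .encoding import encode_pair, extract_peptide

logger = logging.getLogger("akid")


@dataclass(frozen=True)
class MissenseMutation:
    protein_id: str
    position: int  # 0-based
    ref: str
    alt: str
    impact_score: float
    pathogenic: bool

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt residues must differ")
        if not 0.0 <= self.impact_score <= 1.0:
            raise ValueError("impact_score must lie in [0, 1]")


@dataclass(frozen=True)
class PredictedKsP:
    kinase_id: str
    substrate_id: str
    site_pos: int
    score: float
    passed_threshold: bool
    mutation: MissenseMutation
    kind: str  # "gained" | "lost"
    acceptor: str


def filter_mutations(mutations, proteome: dict, impact_cut: float = 0.5) -> list:
    """Keep pathogenic, low-impact mutations that hit or create a
    phosphoacceptor.

    Kept iff pathogenic, ``impact_score < impact_cut`` (strictly below),
    the proteome confirms the reference residue, and ref or alt is S/T/Y.
    Mutations that only touch flanking residues of some site are excluded
    by construction: only the mutated position itself is considered.
    Records whose ref disagrees with the proteome are rejected and logged.
    """
    kept = []
    for mut in mutations:
        seq = proteome.get(mut.protein_id)
        if seq is None or not 0 <= mut.position < len(seq):
            logger.warning("mutation %s:%d outside proteome; rejected", mut.protein_id, mut.position)
            continue
        if seq[mut.position] != mut.ref:
            logger.warning(
                "mutation %s:%d ref %s disagrees with proteome residue %s; rejected",
                mut.protein_id,
                mut.position,
                mut.ref,
                seq[mut.position],
            )
            continue
        if not mut.pathogenic:
            continue
        if not mut.impact_score < impact_cut:
            continue
        if mut.ref in PHOSPHOACCEPTORS or mut.alt in PHOSPHOACCEPTORS:
            kept.append(mut)
    return kept


def scan_mutants(
    model: TrainedModel,
    mutations,
    proteome: dict,
    kinome_dos,
) -> list:
    """Score mutation-affected windows against every kinase DoS profile.

    Site-gained mutations (alt in S/T/Y) are scored on the mutant window;
    site-lost mutations (ref in S/T/Y) on the reference window, naming the
    kinases whose phosphorylation the mutation would destroy.  Output is
    deduplicated to unique (kinase, substrate, site, kind) predictions.
    """
    kinome_dos = list(kinome_dos)
    if not kinome_dos:
        return []
    tasks = []  # (window-peptide, acceptor, mutation, kind)
    seen_sites = set()
    for mut in mutations:
        seq = proteome[mut.protein_id]
        if mut.alt in PHOSPHOACCEPTORS:
            mutant = seq[: mut.position] + mut.alt + seq[mut.position + 1 :]
            key = (mut.protein_id, mut.position, "gained")
            if key not in seen_sites:
                seen_sites.add(key)
                pep = extract_peptide(mutant, mut.position, protein_id=mut.protein_id)
                tasks.append((pep, mut.alt, mut, "gained"))
        if mut.ref in PHOSPHOACCEPTORS:
            key = (mut.protein_id, mut.position, "lost")
            if key not in seen_sites:
                seen_sites.add(key)
                pep = extract_peptide(seq, mut.position, protein_id=mut.protein_id)
                tasks.append((pep, mut.ref, mut, "lost"))

    predictions = []
    for pep, acceptor, mut, kind in tasks:
        pairs = [
            encode_pair(dos.symbols, pep, kinase_id=dos.kinase_id) for dos in kinome_dos
        ]
        scores = predict(model, pairs)
        thr = model.thresholds.for_acceptor(acceptor)
        for dos, score in zip(kinome_dos, scores):
            predictions.append(
                PredictedKsP(
                    kinase_id=dos.kinase_id,
                    substrate_id=pep.protein_id,
                    site_pos=pep.site_pos,
                    score=float(score),
                    passed_threshold=bool(score >= thr),
                    mutation=mut,
                    kind=kind,
                    acceptor=acceptor,
                )
            )
    return predictions


@dataclass
class ProximityResult:
    observed_lengths: list
    null_lengths: list
    n_disconnected: int
    u_statistic: float
    p_value: float


def network_proximity(
    pairs,
    edges,
    score_floor: float = 900.0,
    n_random: int = 1000,
    seed: int = 0,
) -> ProximityResult:
    """Shortest-path proximity of predicted kinase-target pairs vs random.

    Edges below ``score_floor`` (STRING 'experimental' channel convention)
    are discarded before pathfinding; path lengths are unweighted BFS
    distances, disconnected pairs are excluded and counted.  The null is
    ``n_random`` random node pairs from the same network; significance is
    a one-sided Mann-Whitney U (observed shorter than null), exact for
    small samples and normal-approximated with tie correction otherwise.
    """
    G = nx.Graph()
    for a, b, score in edges:
        if score >= score_floor:
            G.add_edge(a, b)
    if G.number_of_nodes() == 0:
        raise ValueError("no network edges pass the score floor")
    rng = np.random.default_rng(seed)
    nodes = sorted(G.nodes)

    observed, n_disconnected = [], 0
    for a, b in pairs:
        if a not in G or b not in G:
            n_disconnected += 1
            continue
        try:
            observed.append(nx.shortest_path_length(G, a, b))
        except nx.NetworkXNoPath:
            n_disconnected += 1
    if n_disconnected:
        logger.info("network_proximity: %d disconnected pair(s) excluded", n_disconnected)

    null = []
    while len(null) < n_random:
        a, b = rng.choice(len(nodes), size=2, replace=False)
        try:
            null.append(nx.shortest_path_length(G, nodes[a], nodes[b]))
        except nx.NetworkXNoPath:
            continue

    if not observed:
        raise ValueError("no connected predicted pairs to test")
    method = "exact" if max(len(observed), len(null)) <= 20 else "asymptotic"
    res = mannwhitneyu(observed, null, alternative="less", method=method)
    return ProximityResult(
        observed_lengths=observed,
        null_lengths=null,
        n_disconnected=n_disconnected,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
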