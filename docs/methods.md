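# Methods

## The model

A kinase-specific phosphorylation (KsP) is a triple (kinase, substrate,
site). The package scores such triples from sequence alone, in three
stages.

**Kinase-domain detection.** A profile HMM is estimated from an aligned
set of kinase-domain sequences. Alignment columns whose residue occupancy
is at least the `occupancy_threshold` (default 0.5, the usual
heuristic) become match states; match emissions are column residue counts
with Laplace (+1) pseudocounts, insert states emit at the background
distribution (overall MSA residue frequencies, +1), and transition
probabilities are estimated from the observed per-row state paths, again
with +1 pseudocounts. The topology is the classic profile one (M→M/I/D,
I→M/I, D→M/D, no I↔D); observed MSA adjacencies that would need an I↔D
transition are skipped during counting, which the pseudocounts absorb.
Proteome scanning uses glocal Viterbi — the full profile against any
subsequence, flanks free — with log-odds scores in bits against the
background model. Because the score distribution of such a bespoke
profile has no usable closed form, significance is empirical: the P-value
of a hit is the fraction of `n_shuffles` (default 200) residue-shuffled
copies of the same protein whose best glocal score reaches the observed
one; hits with P below the cutoff (default 0.05) are kept, the flanking
segments re-scanned recursively so multi-domain proteins yield one hit
per domain. Detected domains are then aligned *globally* to the profile
and the residues at the configured DoS columns read off, with a gap
symbol wherever a DoS column is deleted. Viterbi ties resolve
deterministically Match > Delete > Insert, so outputs are reproducible.
Coordinates are 0-based half-open internally and 1-based inclusive only
in TSV output.

**Encoding.** The kinase side is its 63 DoS residues; the peptide side is
the ±7 window around the phosphoacceptor, gap-padded at protein termini.
Every position is one-hot over 21 slots (amino acids in alphabetical
one-letter order, gap last), blocks concatenated DoS-first: 78 positions,
1638 bits, exactly 78 set. Nonstandard residue codes (U, O, B, Z, J, X)
normalize to the gap slot with a logged count, keeping the 21-slot
contract intact. Block order and slot order are fixed conventions
recorded in the model archive, and prediction refuses a model whose
block-order tag disagrees.

**Scoring network.** 1638 inputs → two softplus hidden layers → 2-unit
softmax; the pair score is the positive-class probability. Training
minimizes mean squared error against one-hot targets. The optimizer is
resilient backpropagation in the iRprop− variant: per-parameter step
sizes grow by 1.2 on a stable gradient sign, shrink by 0.5 on a flip
(with the flipped gradient zeroed), clamped to [1e-6, 50], initial step
0.01; it is applied per mini-batch. Rprop adapts steps from gradient
signs only, so the recorded learning rate of 0.5 is provenance metadata
rather than an active parameter. Weight init is Normal(0, 1/√fan-in);
after every update each neuron's incoming weight vector is capped at L2
norm 15 ("weight normalization"). Training is deterministic given the
config seed (initialization and batch order both derive from it) and the
model manifest records a checksum of the training data.

The reference architecture for real kinome-scale data is 210 and 53
hidden units with batch size 400, the optimum of the prescribed grid
(batch ∈ {100, 200, 400, 600, 800}; first layer 10–1010 step 200; second
layer ⌈¼, ½, ¾⌉ of the first — 90 combinations). `grid_search` scores
each combination by 3-fold CV AUC (a cheaper inner loop than the final
10-fold evaluation) and breaks ties toward the smaller first layer, then
the smaller batch. Cross-validation folds are stratified jointly by label
and acceptor residue so that tyrosine sites, the rarest class, appear in
every fold.

**Thresholds.** Scores are converted to calls per acceptor type at the
crossing point of the Gaussian kernel density estimates (Silverman
bandwidth) of positive and negative scores; among multiple crossings the
one between the two density modes is chosen, refined by bisection. The
shipped defaults t_S = 0.545, t_T = 0.517, t_Y = 0.34 are the values
published for the original human training data; they depend on that
(licensed) training corpus and should be re-derived for any new one.

## Dataset construction

KsP tables in the style of PhosphoSitePlus/PhosphoGRID exports are
re-anchored onto the working proteome by exact 15-mer window lookup with
an edlib infix-alignment fallback accepted at ≥ 80% window identity —
an alignment-based remap without an external BLAST dependency.
Interactions of kinases with zero or ≥ 2 detected kinase domains are
excluded (the databases do not say which domain is active). Kinase
domains are clustered at 70% identity by greedy longest-first clustering:
identity is identical aligned positions over the shorter sequence from a
global alignment, the CD-HIT denominator convention, without CD-HIT's
short-word screening heuristics. Negatives are sampled one per positive
(the published convention of equal-sized negative sets) from either the
annotated phosphopeptide pool or from random S/T/Y-centered proteome
windows; draws colliding with known positives are rejected and resampled,
all under an explicit seed. By default the negative's acceptor type is
not constrained to match the positive's; `match_acceptor=True` enables
the stricter regime, which per-acceptor thresholds suggest for
type-aware evaluation. Test-vs-training redundancy is removed at > 50%
positional window identity (8/15 positions removes, 7/15 keeps).

## Conservation analysis

Human KsP are traced into other organisms through 1:1 orthologs only
(records with any other relation are rejected at load). The human
substrate is aligned globally to its ortholog (Needleman–Wunsch, affine
gaps, BLOSUM62 with gap open −10 / extend −1 by default; tie-break
diagonal > up > left), the site mapped through the alignment, and counted
conserved when the orthologous residue equals the human acceptor —
strictly by default; `st_equivalent=True` treats S↔T as conserved. A KsP
is mappable only when *both* kinase and substrate have 1:1 orthologs.
Organisms with zero mappable KsP report an undefined fraction rather
than 0, since sparse mapping usually reflects annotation gaps rather than
genuine loss. Whether the flanking window should also be conserved is a
genuinely open question; only acceptor-level conservation is scored, and
window identity can be computed separately from the same alignments.

## Mutation screening

Missense mutations arrive with an externally computed structural-impact
score in [0, 1] (Polyphen-style; the package never computes it). Kept are
pathogenic records with impact strictly below 0.5 whose reference or
alternate residue is a phosphoacceptor — i.e. the mutation itself sits at
the (lost or gained) site; mutations that only touch flanking residues
are out of scope because the model of a mutated *context* is a different
problem. For gained sites the mutant window is scored against every
kinase of the supplied kinome, for lost sites the reference window is
scored to name the kinases whose site the mutation destroys; both tables
are emitted, flagged by the per-acceptor threshold. Predicted pairs are
validated by proximity in a physical interaction network (edges kept at
experimental-channel score ≥ 900): BFS path lengths of predicted pairs
against random node pairs, one-sided Mann–Whitney U, exact enumeration up
to 20 observations per side and the tie-corrected normal approximation
beyond.

## Synthetic data

The fixture generators define the conditions under which the package is
tested. `gen_family_msa` mutates a random ancestor per row (default
20 rows; mutation and gap rates per cell); `gen_proteome` draws i.i.d.
background residues (uniform by default, or a supplied composition) and
implants domains sampled from the profile's match emissions at recorded
coordinates; `gen_ksp` plants per-kinase coupling rules — by default 3
couplings joining distinct DoS slots to distinct peptide offsets —
and emits positives satisfying every coupling and negatives violating at
least one, with an optional label-flip noise fraction and a recomputable
truth table. Everything is bit-reproducible from (parameters, seed).

What these fixtures do *not* emulate: real amino-acid composition and
phylogenetic correlation among kinases, the heavy S≫T≫Y site imbalance,
overlapping specificities of related kinases, and annotation noise that
is structured rather than uniform. Passing the recovery experiments
therefore demonstrates that the machinery is correct and can learn
planted specificity rules, not that real-kinome AUC (published: 0.78
average, 0.93 for tyrosine kinases, 0.58 for TKL) is reproduced — those
numbers require licensed database snapshots and are shipped as reference
documentation only.

## Evaluation choices and problem sizes

The standing recovery experiment uses 10 kinases × (200 positive + 200
negative) pairs with 3-coupling rules, scored by 10-fold CV. The network
for this experiment is 64/16 hidden units (batch 400, 10 epochs): the
planted task is far simpler than a real phosphoproteome, and a small
network has ample capacity for it while keeping the experiment quick.
At zero label noise the mean CV AUC is ≥ 0.97; at 0.5 label noise the
labels carry no information and AUC sits at 0.5 within seed noise, with
monotone degradation in between. Domain recovery uses 50 proteins of
length 100–300 with 10 implanted 40-column domains, scanned at P < 0.05
with 200 shuffles per null.

## Numerical notes and limitations

- Viterbi and Needleman–Wunsch tracebacks use explicit pointer arrays, so
  tie-breaking never depends on floating-point equality of recomputed
  sums.
- The batch (score-only) glocal scorer used for the shuffle null
  vectorizes the delete chain with a prefix-max over cumulative
  transition costs and agrees exactly with the single-sequence DP.
- The empirical P-value is a plain fraction over shuffles; with 200
  shuffles its resolution is 0.005, adequate for a 0.05 cutoff but not
  for E-value-style ranking, and it is not calibrated against hmmer.
- Two empty residue sets make the Jaccard index undefined and raise.
- KDE threshold selection needs ≥ 20 scores per class per acceptor and
  falls back to the mode midpoint when the densities never cross in
  [0, 1].
- Forward/posterior decoding, deep-belief pretraining, GO semantic
  similarity and ortholog inference are out of scope; ortholog pairs,
  divergence times, kinase-group maps and impact scores are inputs.
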