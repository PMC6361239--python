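# akid

Kinase-specific phosphorylation (KsP) prediction from the sequence of the
kinase *and* of its candidate target peptide.

Most phosphosite predictors model the target peptide only, per kinase or
per kinase family, which limits them to kinases with annotated substrates.
`akid` implements the AKID approach instead: it detects kinase domains in
any proteome with a profile hidden Markov model (no prior kinase
annotation needed), reads off each domain the 63 **determinants of
specificity** (DoS) — the profile columns whose residues best explain
target-peptide preference — and scores a kinase–peptide pair with a
feed-forward neural network over a one-hot encoding of the 63 DoS residues
plus the 15-residue peptide window centered on the phosphoacceptor
(S/T/Y). Each of the 78 positions is encoded over 21 slots (20 amino acids
plus gap), so one pair is a 1638-bit vector with exactly 78 bits set. The
network (1638 → h₁ → h₂ → 2-softmax, softplus hidden units, MSE loss,
resilient backpropagation) outputs the probability that the kinase
phosphorylates the site; per-acceptor decision thresholds are taken at the
crossing of the score densities of true and false KsP.

Around this core the package provides:

- **`profile_hmm`** — build a Plan7-style profile from a kinase-domain
  MSA, scan proteomes (glocal Viterbi, empirical shuffle-null P-values),
  align domains to the profile and map DoS columns;
- **`encoding`** — peptide windows and the orthogonal encoding;
- **`dataset`** — KsP table ingestion, site remapping onto a proteome,
  multi-domain-kinase exclusion, greedy 70%-identity clustering of kinase
  domains, and two negative-interaction regimes (annotated phosphopeptides
  vs random S/T/Y windows);
- **`dnn_model`** — training, grid search over batch size and layer
  widths, stratified 10-fold cross-validation, ROC/AUC, per-acceptor
  threshold selection;
- **`evolution`** — Needleman–Wunsch ortholog alignment, phosphosite
  mapping, conservation-fraction profiles vs divergence time per kinase
  group;
- **`mutation_scan`** — screening of missense mutations that create or
  destroy phosphoacceptors, kinome-wide scoring of the affected windows,
  and network-proximity validation (BFS shortest paths, Mann–Whitney U);
- **`fixtures`** — seeded generators for synthetic MSAs, proteomes with
  implanted domains, and KsP datasets with *planted* DoS↔peptide coupling
  rules, so every recovery experiment has exact ground truth.

## Worked example

Detect domains in a synthetic proteome with ten implanted kinase domains,
then train the scorer on a planted-rule dataset:

```bash
akid simulate proteome --seed 7 --out sim/           # proteome.fa + truth.tsv
akid scan --msa sim/kinases.afa --proteome sim/proteome.fa \
          --pvalue 0.05 --dos sim/dos.txt --out hits.tsv --seed 7
# -> 15 hit(s) written to hits.tsv
head -3 hits.tsv
# protein_id  domain_index  start  end  bit_score  p_value  dos_symbols
# prot0000    0             1      20   30.75      0        ----------THRYLNMTRH
# prot0002    0             27     66   64.87      0        LQNTCGLLNDTGEKQISTRQ

akid simulate ksp --seed 3 --out ksp/                # encoded pairs + labels
akid train --pairs ksp/pairs.tsv --labels ksp/labels.tsv \
           --layer1 32 --layer2 8 --epochs 3 --seed 1 --out model.npz
akid predict --model model.npz --pairs ksp/pairs.tsv --out scores.tsv
akid evaluate --scores scores.tsv --labels ksp/labels.tsv
# -> AUC: 0.9846 (4000 interactions)
```

`hits.tsv` reports 1-based start / inclusive end coordinates, the Viterbi
bit score, the empirical P-value (fraction of residue-shuffled copies of
the protein scoring at least as high), and the DoS residues read off the
domain-to-profile alignment (gap where a DoS column is deleted). The AUC
of 0.98 on the planted-rule dataset reflects that the synthetic coupling
rules are recoverable almost perfectly from 400 examples per kinase; real
phosphoproteome data is far harder (see `docs/methods.md`).

The same classes and functions are importable directly
(`akid.build_profile`, `akid.scan_proteome`, `akid.train`,
`akid.cross_validate`, `akid.conservation_profile`, …); the CLI is a thin
wrapper.

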