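# Methods

## Scope

`fire-pri` implements similarity-transfer selection of reliable negative
protein–RNA pairs, the paired conjoint-triad × k-nucleotide feature
encoding with FScore filtering, a classifier-evaluation harness, and a
synthetic-interactome generator that makes the whole pipeline testable
without database downloads. It does not construct datasets from PRIDB,
NPInter, STRING, UniProt, Pfam or GO dumps; only generic readers (FASTA,
two-column pair/annotation tables) are provided.

## Protein–protein similarity

Aggregated similarity is the unweighted mean AS = (SS + FS + DS)/3 of three
channels, each in [0, 1]:

- **SS** (sequence): Smith–Waterman local alignment normalized by the
  geometric mean of the two self-scores,
  nsw(a, b) = sw(a, b)/(√sw(a, a)·√sw(b, b)), then symmetrized over
  argument order (a formality — the normalization is already symmetric).
  Scoring scheme: BLOSUM62, gap open 10, gap extension 0.5 (a gap of
  length L costs 10 + 0.5·(L−1)); these are canonical local-alignment
  defaults, exposed via `AlignmentParams`. Because each BLOSUM62 diagonal
  entry is the maximum of its row, sw(a, b) ≤ min(sw(a,a), sw(b,b)) and
  the normalized score cannot exceed 1. Alignment is delegated to
  Biopython's `PairwiseAligner`; the test suite checks it against an
  independent Gotoh dynamic-programming oracle.
- **FS** (function): Jaccard overlap of the two proteins' directly
  assigned GO terms, all three ontologies pooled, no ancestor closure
  (the closest literal reading of set-overlap semantic similarity).
- **DS** (domains): Jaccard overlap of Pfam domain fingerprints.

Design points in the open:

- *Jaccard of two empty sets is 0*: absence of annotation evidence is not
  evidence of similarity.
- *Missing channels are not renormalized*: a protein without GO terms
  contributes FS = 0 to a fixed three-way mean rather than upgrading the
  other channels' weight. This biases AS downward for poorly annotated
  proteins, which is conservative for negative selection (it lowers their
  SPR scores).
- The diagonal applies the same composition, so a protein with no
  annotations has self-similarity (1+0+0)/3 — the matrix diagonal equals 1
  only for fully annotated proteins.

## Candidate scoring and negative selection

The candidate universe is P × R minus the positive set, where P and R are
the proteins and RNAs appearing in the positive set (the similarity matrix
is only defined for those proteins). Each candidate (p_i, r_j) receives

SPR_ij = Σ_k δ(k, j) · SP_ik,   δ(k, j) = 1 iff (p_k, r_j) ∈ PS, k ≠ i,

the summed similarity of p_i to the known partners of r_j. Selection
strategies:

- **random** — uniform without replacement (the traditional baseline);
- **ranked (FIRE)** — ascending SPR, lowest m;
- **threshold** — the m candidates minimizing |SPR − st|, which sweeps
  negative-set quality as st rises from 0 to the score maximum;
- **positive prediction** — per RNA, the top-scoring candidates above a
  floor (`rank_candidate_positives`), descending SPR. The score used here
  is SPR; an aggregated per-pair sum is the only score in the pipeline
  that can exceed 1, which is what a useful floor requires.

All orderings break score ties lexicographically by (protein id, RNA id),
making every selection reproducible across platforms. Adding one positive
pair (p_k, r_j) raises SPR_ij by exactly SP_ik, a property the tests
verify.

## Feature encoding

Residues are collapsed to 4 physicochemical classes
({DE}, {HRK}, {CGNQSTY}, {AFILMPVW}); a conjoint triad is a width-3 window
identified up to this alphabet (64 classes). A k-NA is a width-k RNA
window, k = 1, 2, 3. Pairing them gives 256 + 1024 + 4096 = 5376
dimensions, ordered 6-mers, 5-mers, 4-mers; within a block,
lexicographically by (k-NA, class triple) — names like `CCU-444`.

The occurrence count of a paired unit is defined as the *product* of its
triad-class count and its k-NA count: a paired unit occurs once per
co-occurrence of its two components, and the product is the definition
consistent with independent sliding-window counts (the tests confirm it
against explicit materialization of every co-occurrence). Raw values are
weighted by the type concentration C_i = N_i/5376 and min–max normalized
across the vector's 5376 entries; a constant raw vector maps to all zeros
(no information, and 0/0 is avoided). Triad windows overlapping
non-standard residue letters are skipped rather than rejecting the
sequence.

**FScore filtering.** Per feature, frequencies are summed over the
positive and over the negative class; each 5376-long profile is min–max
normalized, floored at ε = 1/(2·5376), and the ratio FF_p/FF_n is the
FScore. The floor keeps never-observed features finite and neutral
(score 1). Selection keeps the k/2 largest and k/2 smallest scores
(default k = 1000), ties broken by ascending index; if ties make the two
halves overlap the selection is ambiguous and an error is raised rather
than silently returning fewer features.

## Classifiers and metrics

SVM (RBF, C = 1, gamma = 1/n_features), random forest (500 trees) and
Gaussian naive Bayes, via scikit-learn; hyperparameters are ecosystem
defaults and overridable. Cross-validation is stratified so every fold
preserves the positive:negative ratio (essential for the 2:1 and 1:2
dataset presets), and metrics are pooled over out-of-fold predictions
(micro-averaged) rather than averaged per fold — stable when a dataset has
only a few dozen positives. AUC uses the classifier's continuous score
(decision value or positive-class probability). GM = √(SE·SP) is the
headline metric for imbalanced data; IR = (reliable − random)/random ×
100% compares the two negative-construction arms.

## The synthetic generator

`generate_world` plants the assumption the selection method exploits —
similar proteins share RNA partners — as measurable ground truth:

- groups of proteins descend from a common random ancestor (length
  50–300) by per-site substitution at `mutation_rate`; group members share
  6 core GO terms and 3 core domains, plus 2 + 1 private noise terms each;
- each RNA (length 20–200) truly binds all proteins of 1–2 random groups;
- the observed positive set is a uniform subsample of the truth at
  `observation_fraction`; the unobserved remainder is exactly the
  contamination hazard for random negative sampling.

Defaults (5 groups × 8 proteins, 40 RNAs, mutation 0.1, observation 0.6)
give ~480 true interactions, ~290 observed, and a candidate universe of
~1100 pairs of which ~15% are hidden positives — large enough for stable
statistics, small enough that a 20-seed study runs in about two minutes on
one CPU. Uniform sequence composition and block-structured annotations are
deliberate simplifications: the generator does not mimic real degree
distributions, GO DAG structure, or compositional bias, so passing the
benchmark shows the machinery works and the selection principle holds
under its own assumption — not that the same margins will appear on real
interactomes.

## Benchmark protocols

**Contamination.** With m = |observed|, the fraction of selected negatives
that are hidden true interactions, compared between ranked and random
selection per seed (one-sided sign test over ≥ 20 seeds).

**Classifier benefit.** For each arm, the constructed dataset (observed
positives + that arm's negatives) is 10-fold cross-validated with the
labels the experimenter would actually have, and the pooled out-of-fold
predictions are scored against the *true* labels. A contaminated negative
that the model learned to call negative therefore counts as a false
negative. This isolates label quality — the thing negative selection is
supposed to improve. The study uses a 100-tree random forest and the
k = 1000 feature filter; one seed takes a few seconds.

An alternative protocol — training on the constructed dataset and testing
on an independent sample of held-out truth — measures something different
(generalization under the selection bias of the training distribution) and
there the ranked method can *underperform* random sampling: ascending-SPR
selection concentrates negatives on RNAs with few observed partners, since
SPR scales with the number of partners summed over, and a classifier can
exploit that as an RNA-identity shortcut. This is a real limitation of
score-ranked negative selection, inherited by this implementation.

**Threshold sweep.** Negative sets targeted at st ∈ {0, 0.2, 0.4, 0.7, 1}
× s_max; 10-fold CV AUC (Gaussian NB) per set. AUC declines as st rises,
because high-score candidates are increasingly likely to be unobserved
true interactions; the tests assert the trend direction only.

## Numerical and degenerate-input conventions

- Local-alignment score 0 (no positive-scoring alignment) gives nsw = 0;
  a non-positive self-score (impossible under BLOSUM62) is an error.
- Proteins shorter than 3 residues produce all-zero feature vectors.
- `random_negatives`/`fire_negatives` raise a capacity error naming the
  maximum when m exceeds the candidate universe.
- Metrics are undefined (error, not NaN) when a class is empty; IR is
  undefined for a zero baseline.
- All randomness flows through `numpy.random.default_rng` seeds;
  stratified fold assignment is seeded; repeated runs are bit-identical
  on one platform.

## Known limitations

- Jaccard-based GO similarity ignores term depth and ancestry; an
  information-content measure is out of scope by design.
- The per-vector min–max normalization ties a feature's scale to the
  vector's largest entry (usually a 6-mer), so 4-mer values are
  systematically small before FScore normalization.
- The product definition of paired-unit counts is one of several
  defensible readings of "occurrence frequency" for a composite unit;
  alternatives (minimum, normalized frequency) would change raw scales
  but not the zero pattern.
- The RNA-degree sensitivity of SPR described above means ranked
  negatives are not a representative sample of the candidate space;
  consumers training models for *screening* new pairs should weigh the
  CV-based evidence accordingly.
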