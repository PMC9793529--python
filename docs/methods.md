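# Methods

## Problem setting

Given two drug populations — small-molecule drugs (SMDs) with SMILES
structures and biotech drugs (BioDs) with primary amino-acid sequences —
and four prior-knowledge networks (SMD–SMD, BioD–BioD, SMD–protein,
BioD–protein), the task is multi-label classification of every ordered
candidate pair (SMD, BioD): class 0 means "no interaction", classes 1..K
are interaction event types derived from (mechanism, action) combinations.
A pair may carry several events at once, so the output layer is sigmoid
per class, not softmax, and the loss is mean per-class binary
cross-entropy.

## Event catalog

Events are ranked by descending frequency (ties broken lexicographically
on (mechanism, action)); every event with at most `min_count` interactions
(default 10) is pooled into one rare bucket placed last. The catalog is a
pure function of the quaternary multiset — shuffling the input rows cannot
change it. The reference corpus configuration has 48 event classes plus
class 0 (49 outputs); synthetic universes have `n_events` plus class 0.
Whether the rare bucket counts as one of the event classes is explicit in
the catalog (`rare_bucket_id`), not implicit in the output width.

## Feature modalities

* **Token sequences (CNN modality).** Character-level integer encoding,
  index 0 reserved for padding, one reserved index past the vocabulary for
  unseen characters (so novel drugs can be scored rather than rejected).
  Default lengths: 1000 characters for SMILES, 100 residues for sequences;
  longer inputs are truncated, shorter ones right-padded. The vocabulary is
  corpus-derived and persisted, rather than fixed a priori.
* **Fingerprint / embedding (FP_EMB modality).** The SMD fingerprint is a
  1024-bit hashed linear-path fingerprint: every simple atom-bond path of
  up to 7 bonds is rendered as an alternating atom/bond label string
  (direction-normalized, so SMILES aliases of one molecule agree), and each
  path sets 2 bits chosen by a cryptographic hash. It is a topological
  fingerprint in the Daylight tradition, equivalent in kind but not
  bit-identical to other toolkits' implementations; the featurizer
  name+version travels with every vector. The BioD embedding is pluggable:
  the built-in deterministic backend truncates the sequence to its first
  1024 residues, hashes overlapping 3-mers into 2048 buckets, L2-normalizes
  the counts and applies a fixed Gaussian random projection to 1280
  dimensions; any pretrained protein language model producing 1280
  dimensions can be dropped in through the adapter contract.
* **Network topology (SPI_BPI and SSI_BBI modalities).** Each drug's
  position in a network is a binary interaction profile over that network's
  observed partner universe (sorted and persisted so inference-time
  profiles align). Profiles are compared with the Jaccard index over
  supports; two empty supports get similarity 0 (isolated drugs share no
  evidence — the 0/0 case is otherwise undefined). The per-network
  similarity matrix over same-type drugs provides the drugs' topology rows;
  SMD rows are PCA-reduced (default 512 components, capped at the feasible
  rank) while the much shorter BioD rows stay raw. PCA uses a deterministic
  sign convention (largest-magnitude loading positive) and the fitted
  transform is persisted for projecting unseen drugs. PCA is fitted on all
  drugs' similarity rows: the rows derive only from the four input
  networks, which contain no SMD–BioD edges, so no interaction label of any
  evaluated pair can leak through the transform.

Vector-modality sub-model inputs are z-scored with statistics fitted on
the training fold only; the blocks mix binary bits, small-magnitude
projections and PCA scores, and a shared un-normalized scale measurably
starves the smaller-scale block during training.

## PU-sampling

Three steps, T repetitions (default T = 50 — the mean score's variance
decays as 1/T and 50 stabilizes the ranking at desk scale; the value is
configurable because no canonical choice exists): (1) draw |P| unlabeled
pairs uniformly without replacement as temporary negatives and fit a
depth-limited decision tree (default depth 8, min leaf 5) of positives
versus the draw on the concatenated fingerprint/embedding + topology pair
features; (2) score all unlabeled pairs with the tree's leaf positive-class
fraction — probabilities, not hard votes, so averaging across repetitions
is meaningful; (3) eliminate pairs whose mean score reaches θ (default 1.0
— only unanimously positive-looking pairs; exposed because a strict 1.0 is
fragile under probability averaging) and keep the n lowest-scoring
survivors, ties broken lexicographically on the pair id so the selection is
a deterministic function of the score table. Every tree scores all of the
unlabeled pool, including its own temporary negatives; with |U| ≫ |P| the
self-scoring bias on any pair's mean is at most a few repetitions out of T
and is ignored.

## Sub-models, ensemble, training

Each sub-model is a 512 → 256 → (K+1) fully connected head with ReLU
activations and dropout 0.3 on hidden units (hidden-layer activation is a
field-default choice). The CNN sub-model first encodes each channel with
three 1D convolutions of kernel length 8 and filter counts (f, 2f, 3f),
followed by global max pooling; the two pooled outputs (3f each) are
concatenated into the head. Tokens pass through a learned embedding table
(default width 128) before the first convolution. The ensemble prediction
is the unweighted arithmetic mean of the fitted sub-models' sigmoid
outputs; ablation experiments evaluate modality subsets with the same
cached per-modality predictions.

Training uses Adam, up to 100 epochs, early stopping with patience 10 on
the loss of a stratified 10% validation split of the training fold, best
weights restored. The default learning rate is 1e-3; 0.3 remains
selectable in the configuration but is far outside the stable range for
Adam on these models and is not used by any harness. Batch size defaults
to 256 (128 in the desk-scale harnesses). All layers are implemented in a
compact numpy engine with explicit backward passes (`sbipred.nn`);
training is exactly reproducible given the seed, the data and the
architecture.

## Evaluation

Stratified 5-fold cross-validation over drug pairs (rare strata pooled so
folds remain constructible); an SMD-disjoint cold-start split is available
as an extra mode but is not the reference protocol. Six metrics are
computed micro-averaged over all class indicators: ACC, precision, recall
and F1 from pooled TP/FP/TN/FN at threshold 0.5, AUC as the trapezoidal
area over the pooled ROC, AUPR as the step-interpolated area (average
precision) over the pooled PR curve. Macro (per-class averaged) mode is
available behind a flag, as is top-1 subset accuracy. Single-class truth
leaves the ranking areas undefined; they are reported as NaN with a
warning rather than silently coerced.

## Synthetic universes

The generator emulates the *shape* of a curated interaction corpus, not
its chemistry. Each drug carries an 8-dimensional standard-normal latent
factor split into two halves: the network half drives its protein
neighborhoods (top-k picks by affinity plus Gumbel noise, per-drug degrees
binomial at the configured density) and its intra-type edges; the
structure half drives the composition of its structure string — SMILES are
chains of 6–14 fragments drawn from a curated grammar whose every fragment
is chain-extensible (so any concatenation parses), sequences are i.i.d.
residues with group frequencies biased by a temperature-2 softmax of the
structure half. Pair propensity is the full latent inner product plus 0.5×
the standardized shared-protein count; the top `positive_rate` fraction of
candidate pairs (by `signal_strength` × propensity + Gumbel noise) become
true positives, and event labels are drawn from a softmax whose logits
combine both latent halves, the shared-protein count and a decaying prior
(so late event ids are naturally rare). A `hidden_positive_fraction` of
true positives is withheld from the labeled set and returned separately —
hidden and labeled positives follow the same generative law, which is
precisely the exchangeability PU-sampling exploits.

Splitting the latent factor is the design choice that makes multi-modal
fusion demonstrably useful: topology features can recover only the network
half, structure features only the structure half, so the averaged ensemble
reliably outperforms every single modality. With a fully shared latent
factor the strongest single modality matches the ensemble and the ablation
ordering is not identifiable at desk scale. With `signal_strength = 0` the
labels are independent of all features, giving an exact null.

What the generator does **not** emulate: real chemistry (fragment chains
are valid but arbitrary molecules), realistic protein sequences, degree
heterogeneity of curated networks, annotation biases, or the reference
corpus's scale and class count. Passing the synthetic harnesses therefore
shows that the pipeline's mechanisms work — PU-sampling avoids planted
hidden positives, fusion combines complementary signal, metrics are
calibrated — not that real-data accuracy figures are reproduced.

## Null calibration

With `signal_strength = 0` the per-class (macro) AUC of a trained
sub-model is 0.5 within Monte-Carlo error — the chance-level check. The
pooled (micro) AUC is *not* 0.5 under this null and is not a defect: class
prevalences differ across indicator columns, so any classifier that merely
reproduces the class priors orders high-prevalence indicators above
low-prevalence ones (measured ≈ 0.80 at the default configuration). The
calibration harness therefore asserts on the macro statistic and reports
both.

## Desk-scale harness settings

The reference experiment harnesses (`sbipred.experiments`) use the
generator defaults (120 SMDs × 30 BioDs × 80 proteins, 6 events, 12%
positive rate, 10% hidden positives) with SMILES token length 96, PCA to
64 components, CNN base filter count 8 with embedding width 24, Adam for
up to 35 epochs (patience 8, batch 128), and a single stratified 80/20
holdout per seed; the sampling comparison averages 10 seeds, the ablation
5, the null calibration 3. These sizes keep a full multi-seed harness in
the minutes range on a single core while leaving every compared quantity
well away from its noise floor.

## Known limitations

- The bundled BioD embedding is a composition-level hash, blind to residue
  order beyond 3-mers; plug in a pretrained protein language model through
  the adapter for order-sensitive representations.
- The fingerprint enumerates linear paths only (no branched subtrees or
  ring-closure features beyond path traversal).
- PCA over similarity rows is transductive across all drugs of a type; a
  strict train-only fit is available by fitting `reduce_pca` on a row
  subset and projecting the rest.
- The numpy training engine is single-threaded and CPU-bound; it is meant
  for corpus scales up to a few thousand pairs, not for GPU-scale training.
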