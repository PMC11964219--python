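# Methods

`rankcell` implements a scale-configurable pipeline for building and using a
single-cell transcriptome foundation model: corpus quality control,
rank-value-encoding tokenization, masked-token pretraining of a transformer
encoder, `[CLS]`-head fine-tuning for cell-type / disease-state
classification, in silico gene perturbation ranked by a cosine-similarity
shift with a Wilcoxon rank-sum statistic, and deterministic human↔mouse
ortholog conversion. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the underlying
protocol leaves them open.

## Rank value encoding

A cell is represented as an ordered sentence of gene tokens. Each gene `g`
with raw count `x_g > 0` in the cell is scored `x_g / m_g`, where `m_g` is
the gene's corpus-wide median of *strictly positive* counts, computed after
QC and pooled over all datasets. Genes are sorted by descending score; ties
break by ascending token id (gene tokens are assigned lexicographically
after the reserved specials `[PAD]=0`, `[MASK]=1`, `[CLS]=2`). The sentence
is `[CLS]` followed by the ranked gene tokens, truncated to the model's
positional capacity (`max_input`, default 2048). The cap is read as the
encoder's total positional capacity, so at most `max_input − 1` gene tokens
follow `[CLS]`.

Median normalization makes the ordering reflect how unusual a gene's
expression is for that gene rather than library depth; the encoding is
invariant to any positive rescaling of a cell's counts. A raw-rank mode
(no normalization) is available for ablation. Zero-count genes never appear
in a sentence.

## Quality control

Four per-dataset filters remove artifact cells (ambient RNA, doublets,
empty droplets). With per-cell total counts `T`, mitochondrial counts `M`
(sum over flagged genes; a fraction mode is available), and detected genes
`D` (genes with count > 0):

1. `|T − mean(T)| > 3·sd(T)`
2. `|M − mean(M)| > 3·sd(M)`
3. `D < 7`
4. `T > 20000` (strict: a cell at exactly 20,000 is retained)

Statistics use the population SD and are computed per dataset on the
pre-filter cells; all four predicates are evaluated in a single conjunctive
pass (no sequential re-estimation), and the filter report records every
predicate fired per removed cell. The 3-SD filters are two-sided by default
— the literal reading of "more than three standard deviations from the
mean" — with a one-sided option in `QCThresholds`. Exclusion of e.g.
cancer / immortalized-line datasets is metadata curation, not expression
arithmetic, and is left to a metadata predicate at corpus assembly.

## Encoder

A BERT-style post-layer-norm transformer encoder: learned absolute position
embeddings, multi-head self-attention with padding masked additively,
feed-forward inner dimension 4× the embedding width, SiLU activation,
dropout 0.02. Full-scale defaults: 2048 positions, 6 blocks, 4 heads, 256
embedding dimensions. The masked-token head is an untied linear projection
to the vocabulary (tying is a flag); the classification head is a linear
layer on the final-layer `[CLS]` state. `EncoderConfig.tiny()` is the
desk-scale preset used throughout the tests: 2 blocks, 2 heads, 64
dimensions, 256 positions.

Because no deep-learning framework is assumed, the encoder runs on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`rankcell.autograd`), gradient-checked against central finite differences.
Training is single-process CPU; inference disables dropout and graph
construction.

## Training

**Pretraining** masks `floor(0.15·n)` of each sentence's gene tokens
(minimum 1; `[CLS]`/`[PAD]` never selected), corrupts targets with the
80/10/10 mask / random-token / unchanged convention (a pure-mask flag
exists), and minimizes cross-entropy at masked positions only. Optimizer:
AdamW (decoupled weight decay 1e-3), batch 12, linear warmup to the max
learning rate followed by cosine decay to zero over the total step budget.
Full-scale schedule: 10 epochs, max LR 1e-3, 10,000 warmup steps
(fine-tuning: 5e-5, 500). The desk-scale presets keep the pretraining max
LR and shrink warmup with the corpus (`pretrain_tiny`: 3 epochs, 50 warmup
steps); `finetune_tiny` raises the fine-tune max LR to 5e-4 because the
step budget is roughly two orders of magnitude smaller than the full-scale
protocol's, keeping the total update budget comparable.

**Fine-tuning** adds the classification head, optionally freezes the first
`k` encoder blocks (with `k = n_blocks` the whole encoder including the
embedding tables is fixed and only the head trains), splits the labeled
corpus into stratified 80% train / 20% test (stratification avoids empty
classes at desk scale; the split seed can be fixed independently of the
training seed), records held-out accuracy per epoch, and restores the
weights of the best epoch — so the reported metrics always describe the
returned model. Metrics: accuracy and macro-F1 (scikit-learn), plus
per-class precision/recall.

**Zero-shot classification** assigns each query cell the label of the
nearest class centroid (mean reference embedding) by cosine similarity,
ties broken by class-name order. This is the simplest protocol consistent
with "classification without fine-tuning"; kNN variants can be layered on
the same embeddings.

Cell embeddings default to the mean over gene-token positions (excluding
`[CLS]`/`[PAD]`) at the final encoder layer; both the layer and the pooling
(`mean` | `cls`) are parameters, since "average feature vector" does not
pin down either.

## In silico perturbation

Perturbations are pure transforms of a cell sentence:

* **delete**: the gene token is removed and all later tokens move one rank
  forward — the gene leaves the dataset entirely rather than being set to
  zero expression;
* **activate**: the gene token moves to rank 1 (immediately after `[CLS]`);
  tokens formerly ahead of it shift back one rank. Activating a gene absent
  from the sentence inserts it at rank 1 (dropping the last token at
  capacity) and is flagged.

These two rules are taken as the definition of the operations; prose about
every other gene's rank shifting by one follows from them and carries no
extra semantics. `delete ∘ activate(g) = delete(g)` for present genes, and
deleting a present gene from an untruncated sentence equals re-encoding the
cell with that gene's count zeroed.

For a gene under test: the reference is the mean embedding of the goal
cells; the *specific* distribution is the cosine similarity of each
perturbed start cell's embedding to that reference (for deletion, only
start cells containing the gene participate); the *control* distribution
perturbs, per cell and per repetition, one uniformly drawn gene from that
cell's own sentence (excluding the gene under test), pooled over
`n_random` repetitions. A two-sided Wilcoxon rank-sum (Mann–Whitney U) test
compares the two distributions; p < 0.05 flags the gene as acting unlike a
random perturbation. The report carries the raw mean similarities
(specific, control, unperturbed) and the shift (specific − unperturbed), so
either a raw-similarity or a shift reading is recoverable. Screening over
candidates sorts by shift (ties: p, then gene id) and adds
Benjamini–Hochberg q values; a configurable pre-flight gate requires the
fine-tuned classifier to reach 90% held-out accuracy before screening, with
an explicit override.

The U test enumerates the exact rank-sum distribution (dynamic programming)
when `n + m ≤ 16` with no ties, and otherwise uses the normal approximation
with tie and continuity corrections.

## Ortholog conversion

Two tables are composed: human Ensembl → (symbol, mouse MGI) and mouse MGI
→ mouse Ensembl. One-to-many records collapse deterministically: per human
id, candidate symbols are sorted alphabetically (case-insensitive, then
case-sensitive, then file order) and the *last* symbol's MGI is chosen; per
MGI id, the *final* mouse Ensembl id in the stage-2 table's output order is
chosen — record order in that table is semantically load-bearing, so the
readers preserve it. Residual collisions (two human ids composing to one
mouse id) keep the lexicographically smallest human id; the rest are
reported unmapped. Ensembl version suffixes are stripped before matching.
Matrix conversion renames mapped genes, drops unmapped ones (counted in the
report), and never touches count values.

## Synthetic data

The generator emulates the *structure* the pipeline depends on, not any
particular tissue: negative-binomial counts (mean `m`, dispersion `φ`,
variance `m + φm²`; Poisson at `φ = 0`), disjoint per-cell-type gene
programs whose genes are boosted `program_fold`-fold in their cells,
explicit mitochondrial flags, optional two-condition structure where causal
genes are shifted `causal_fold`-fold in condition B, and cells engineered
to violate individual QC filters (annotated with exactly the filters they
trip in the final dataset, since a cell planted for one filter may
necessarily trip another).

Defaults: `baseline_mean = 2.0`, `dispersion = 0.1`, programs of 25 genes
at fold 8, 5% mitochondrial genes. The baseline mean is set so that
integer-count noise cannot reach the fold-8 program separation after median
normalization — at mean 1 the near-Poisson upper tail of background genes
intrudes into the top ranks and the planted programs would not dominate
cell sentences, which is the property downstream stages assume. This makes
the corpus denser than droplet scRNA-seq (~40% zeros rather than ~90%);
together with the absence of batch effects, ambient contamination and
doublet mixtures, it means passing tests demonstrate the *procedures* are
correct on data with known truth, not that the model reaches any particular
accuracy on real tissue.

`qc_calibration_corpus` additionally provides a clean population with
*constant* per-cell totals (multinomial allocation) for QC testing:
unbounded count models always place a few honest cells beyond 3 SD, so
exact planted-truth recovery is only a well-posed requirement against a
bounded-spread clean population.

## Desk-scale protocols and problem sizes

The package's own evaluation runs everything end-to-end at sizes a single
CPU handles comfortably:

* **Condition-pair gate**: 3,000 cells × 500 genes, 4 programs of 25 genes
  at fold 8, 20 causal genes at fold 4, dispersion 0.1, data seed 7; tiny
  encoder (2/2/64, 256 positions), 3 pretraining epochs, 3 fine-tuning
  epochs, stratified 80/20 split with split seed 7. The held-out accuracy
  is checked against the 90% pre-perturbation quality gate.
* **Causal-gene screen**: 1,000 cells × 150 genes with a single causal gene
  at fold 8. One informative gene is a deliberately weak classification
  signal (the classifier must read the rank of one token), so this protocol
  uses the smaller gene universe and 10 fine-tuning epochs at max LR 5e-4 to
  clear the 90% gate before screening. One encoder is pretrained and
  fine-tuned once, and the screen (10 candidates, deletion, 25 subsampled
  start cells, 3 random-control repetitions) is repeated over 20 screening
  seeds that vary the start-cell subsample and control draws. Training one
  encoder per seed would add no information about the screening statistic
  while multiplying the runtime twentyfold.
* Tokenizer, QC, perturbation-algebra, Wilcoxon-calibration and ortholog
  checks run against independent brute-force oracles at small sizes.

## Numerical choices and limitations

* float32 throughout; layer-norm ε = 1e-5; attention padding mask −1e9.
* MLM target count: `floor(rate·n)`, minimum 1 (rounding unspecified in
  the protocol).
* Sentence tie-break (equal scores) and zero-shot tie-break (equal
  centroid similarity) are deterministic by token id / class name.
* The Wilcoxon control distribution pools repetitions across cells, so its
  values are not independent across repetitions of the same cell; the test
  is used as a ranking heuristic exactly as in the protocol it follows.
* Loom support is a minimal HDF5 reader/writer for the public loom layout
  (`/matrix` + `row_attrs`/`col_attrs`); the Arrow corpus is a single IPC
  file plus a JSON manifest carrying the vocabulary hash, which loaders
  check so corpora and checkpoints can never be silently mixed across
  vocabularies.
* Single-process CPU training only; no distributed or mixed-precision
  paths, no attention-map interpretability tooling, no UMAP plotting.
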