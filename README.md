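# rankcell

A scale-configurable pipeline for building and using a single-cell
transcriptome foundation model: corpus quality control, rank-value-encoding
tokenization, masked-token pretraining of a BERT-style transformer encoder,
`[CLS]`-head fine-tuning for cell-type / disease-state classification, in
silico gene perturbation, and deterministic human↔mouse ortholog conversion.

It is aimed at computational biologists who want the *procedures* of the
gene-token foundation-model workflow — tokenizer, training loop, perturbation
statistic, homology mapping — as an inspectable, testable library that runs
end-to-end on a single CPU using synthetic corpora with planted ground truth,
rather than as a GPU-scale production trainer.

## The method in brief

**Rank value encoding.** A cell with raw counts `x` becomes an ordered
sentence of gene tokens: each expressed gene `g` is scored `x_g / m_g`, where
`m_g` is the gene's corpus-wide median of nonzero counts, and genes are
sorted by descending score (ties by token id). `[CLS]` leads the sentence;
length is capped by the encoder's positional capacity (2048 full scale). The
encoding is invariant to library-size rescaling: position 1 holds the gene
most unusually high *for that gene*.

**Pretraining.** 15% of each sentence's gene tokens are masked
(80/10/10 corruption) and predicted from context — cross-entropy on masked
positions only — with AdamW (weight decay 1e-3), batch 12, linear warmup then
cosine decay. Full-scale architecture: 6 encoder blocks, 4 heads, 256
embedding dimensions, SiLU, dropout 0.02.

**Fine-tuning and zero-shot.** A classification layer on the final-layer
`[CLS]` state is trained on a stratified 80/20 split (optionally freezing the
first k encoder blocks); metrics are accuracy and macro-F1. Zero-shot
classification assigns the nearest class-centroid by cosine similarity on
frozen embeddings.

**In silico perturbation.** Deleting a gene removes its token (later tokens
move up one rank); activating a gene moves its token to rank 1. For a
candidate gene, the cosine similarities of perturbed start-cell embeddings to
the mean goal-state embedding are compared with a random-gene control
distribution by a two-sided Wilcoxon rank-sum (Mann–Whitney U) test; p < 0.05
marks the gene as acting unlike a random perturbation, and candidates are
ranked by the similarity shift. A pre-flight gate requires ≥ 90% held-out
accuracy of the fine-tuned classifier before screening.

**Ortholog conversion.** Human Ensembl → symbol → mouse MGI → mouse Ensembl,
collapsed to a one-to-one table with deterministic tie-breaks
(alphabetically last symbol; final stage-2 record in file order), version
suffixes stripped, unmapped genes dropped and reported.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import rankcell as rc

# 1. simulate a corpus with four planted cell-type programs
cfg = rc.SyntheticConfig(n_cells=240, n_genes=100, n_cell_types=4,
                         program_size=10, program_fold=8.0, seed=1)
dataset, truth = rc.generate_corpus(cfg)

# 2. quality control + corpus gene medians
stats = rc.dataset_stats(dataset)
filtered, report = rc.apply_filters(dataset, stats)
medians = rc.compute_gene_medians(filtered)

# 3. rank-value tokenization
vocab = rc.build_vocabulary(filtered.gene_ids, medians)
corpus = rc.encode_dataset(filtered, medians, vocab, max_input=64,
                           label_column="cell_type")

# 4. masked-token pretraining of a tiny encoder (2 blocks, 64 dims)
model = rc.build_model(rc.EncoderConfig.tiny(vocab.size, max_input=64), seed=0)
schedule = rc.TrainingSchedule(epochs=8, max_lr=1e-3, warmup_steps=16, seed=0)
model, loss_trace = rc.pretrain(model, corpus, schedule)

# 5. fine-tune the [CLS] head on the planted cell types
model, metrics = rc.finetune(model, corpus,
                             rc.TrainingSchedule.finetune_tiny(seed=0, epochs=6))

# 6. in silico deletion screen: which gene moves type0 cells toward type1?
labels = corpus.labels()
start = [s for s, l in zip(corpus.sentences, labels) if l == "type0"][:20]
goal = [s for s, l in zip(corpus.sentences, labels) if l == "type1"][:20]
candidates = [str(g) for g in filtered.gene_ids[:3]]  # type0 program genes
table = rc.screen_genes(model, start, goal, candidates, op="delete",
                        n_random=3, seed=0, vocab=vocab,
                        classifier_accuracy=metrics.accuracy)
print(table[["gene", "shift", "p_value", "significant"]].to_string(index=False))
```

Output:

```
QC kept 239/240 cells; filters fired: {'total_sd': 0, 'mito_sd': 1, 'min_genes': 0, 'max_total': 0}
vocabulary size 103; first sentence starts [2, 32, 25, 26, 30]
pretraining loss: 4.639 -> 4.379
held-out accuracy 1.000, macro-F1 1.000
              gene    shift  p_value  significant
ENSMUSG00000000000 0.002017 0.036219         True
ENSMUSG00000000001 0.001778 0.076358        False
ENSMUSG00000000002 0.001092 0.191701        False
```

Reading the result: one QC filter fired (a mitochondrial 3-SD outlier); the
pretraining loss falls below the uniform baseline (`log(103) ≈ 4.63`); the
fine-tuned classifier separates the four planted types perfectly; and in the
deletion screen each candidate's `shift` is the change in cosine similarity
toward the goal state, with the top-ranked gene's effect distinguishable from
random-gene deletions at p < 0.05.

The same workflow is available as a CLI:
`rankcell simulate | qc | tokenize | pretrain | finetune | classify |
zero-shot | perturb | convert-genes` (exit codes: 2 configuration error,
3 data error; every subcommand writes a run manifest).

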