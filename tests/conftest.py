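"""Shared fixtures: one small synthetic corpus and one tiny trained encoder,
built once per session and cloned by tests that mutate parameters."""
from __future__ import annotations

import numpy as np
import pytest

import rankcell as rc
from rankcell.model import EncoderModel


def clone_model(model: EncoderModel) -> EncoderModel:
    out = EncoderModel(model.config, seed=0)
    for k, p in model.params.items():
        out.params[k].data = p.data.copy()
    out.provenance = dict(model.provenance)
    return out


@pytest.fixture(scope="session")
def tiny_bundle():
    """240-cell / 100-gene corpus with 4 planted cell-type programs."""
    cfg = rc.SyntheticConfig(n_cells=240, n_genes=100, n_cell_types=4,
                             program_size=10, program_fold=8.0,
                             baseline_mean=1.0, dispersion=0.1,
                             mito_fraction=0.05, seed=1)
    ds, truth = rc.generate_corpus(cfg)
    medians = rc.compute_gene_medians(ds)
    vocab = rc.build_vocabulary(ds.gene_ids, medians)
    corpus = rc.encode_dataset(ds, medians, vocab, max_input=64,
                               label_column="cell_type")
    return {"config": cfg, "dataset": ds, "truth": truth, "medians": medians,
            "vocab": vocab, "corpus": corpus}


@pytest.fixture(scope="session")
def pretrained_tiny(tiny_bundle):
    """Tiny encoder pretrained for 3 epochs on the shared corpus."""
    vocab = tiny_bundle["vocab"]
    model = rc.build_model(rc.EncoderConfig.tiny(vocab.size, max_input=64),
                           seed=0)
    # warmup sized to the 20 steps/epoch of this corpus
    schedule = rc.TrainingSchedule(epochs=8, max_lr=1e-3, warmup_steps=16,
                                   seed=0)
    model, trace = rc.pretrain(model, tiny_bundle["corpus"], schedule)
    return {"model": model, "trace": trace}


@pytest.fixture(scope="session")
def finetuned_tiny(tiny_bundle, pretrained_tiny):
    """The pretrained tiny encoder fine-tuned on the planted cell types."""
    model = clone_model(pretrained_tiny["model"])
    schedule = rc.TrainingSchedule.finetune_tiny(seed=0, epochs=6)
    model, metrics = rc.finetune(model, tiny_bundle["corpus"], schedule)
    return {"model": model, "metrics": metrics}
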