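"""Rank value encoding: a cell's expression vector becomes an ordered
gene-token "cell sentence".

Each expressed gene is scored by its raw count divided by the gene's
corpus-wide nonzero median, so genes that are high *relative to their usual
level* rank first, which is what makes the ordering characterize the cell
rather than overall library depth. Sentences start with the [CLS] token and
are truncated to the model's positional capacity.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
import warnings

import numpy as np
import pandas as pd

from .data import RawDataset
from .errors import ConfigurationError, DataError

PAD, MASK, CLS = 0, 1, 2
SPECIAL_TOKENS = {"[PAD]": PAD, "[MASK]": MASK, "[CLS]": CLS}
N_SPECIALS = 3


@dataclass(frozen=True)
class GeneVocabulary:
    """Injective gene id -> token id mapping with reserved special tokens.

    Gene tokens start at 3 in lexicographic gene-id order, so the mapping is
    deterministic and stable across save/load.
    """

    gene_to_token: dict[str, int]
    token_to_gene: dict[int, str] = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "token_to_gene", {t: g for g, t in self.gene_to_token.items()}
        )
        if len(self.token_to_gene) != len(self.gene_to_token):
            raise ConfigurationError("vocabulary mapping is not injective")
        if any(t < N_SPECIALS for t in self.gene_to_token.values()):
            raise ConfigurationError("gene tokens collide with special tokens")

    def __len__(self) -> int:
        return N_SPECIALS + len(self.gene_to_token)

    @property
    def size(self) -> int:
        return len(self)

    def token(self, gene_id: str) -> int:
        return self.gene_to_token[gene_id]

    def gene(self, token: int) -> str:
        return self.token_to_gene[token]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_to_token

    def content_hash(self) -> str:
        blob = json.dumps(sorted(self.gene_to_token.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.gene_to_token, indent=0))

    @classmethod
    def load(cls, path) -> "GeneVocabulary":
        return cls(gene_to_token=json.loads(Path(path).read_text()))


@dataclass
class CellSentence:
    """Ordered token sequence for one cell, [CLS] first, ranks descending."""

    tokens: np.ndarray
    source_cell: str = ""
    label: object = None

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def gene_tokens(self) -> np.ndarray:
        """Tokens excluding the leading [CLS] (and any specials)."""
        return self.tokens[self.tokens >= N_SPECIALS]

    def validate(self, max_input: int | None = None) -> None:
        if len(self.tokens) == 0 or self.tokens[0] != CLS:
            raise DataError("sentence must start with [CLS]")
        genes = self.gene_tokens
        if len(np.unique(genes)) != len(genes):
            raise DataError("duplicate gene tokens in sentence")
        if max_input is not None and len(self.tokens) > max_input:
            raise DataError(f"sentence length {len(self.tokens)} > max_input {max_input}")


@dataclass
class TokenizedCorpus:
    """A collection of cell sentences plus carried labels; the unit consumed
    by pretraining/fine-tuning and serialized to the Arrow corpus layout."""

    sentences: list[CellSentence]
    vocab: GeneVocabulary
    max_input: int
    meta: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.sentences)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sentences], dtype=object)


def build_vocabulary(gene_ids: Iterable[str],
                     medians: dict[str, float] | None = None) -> GeneVocabulary:
    """Vocabulary over genes present in ``medians`` (all ``gene_ids`` when no
    median table is given), lexicographic after the reserved specials."""
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise ConfigurationError("duplicate gene ids")
    if medians is not None:
        gene_ids = [g for g in gene_ids if g in medians]
    ordered = sorted(gene_ids)
    return GeneVocabulary(
        gene_to_token={g: N_SPECIALS + i for i, g in enumerate(ordered)}
    )


def encode_cell(expression: np.ndarray, gene_ids: np.ndarray,
                medians: dict[str, float], vocab: GeneVocabulary,
                max_input: int = 2048, source_cell: str = "",
                label=None, on_missing: str = "skip",
                normalize: bool = True) -> CellSentence:
    """Rank-value encode one cell.

    Zero-count genes are excluded; remaining genes are scored
    ``count / median`` (or raw count when ``normalize=False``), sorted by
    descending score with ties broken by ascending token id, prefixed with
    [CLS] and truncated to ``max_input`` total tokens.
    """
    if max_input < 2:
        raise ConfigurationError("max_input must be >= 2")
    expression = np.asarray(expression)
    if expression.min(initial=0) < 0:
        raise DataError("expression must be non-negative")
    nz = np.flatnonzero(expression)
    scores, toks = [], []
    for g in nz:
        gid = str(gene_ids[g])
        if gid not in vocab or (normalize and gid not in medians):
            if on_missing == "error":
                raise DataError(f"gene {gid!r} missing from vocabulary/medians")
            warnings.warn(f"skipping gene {gid!r}: not in vocabulary/medians",
                          stacklevel=2)
            continue
        s = expression[g] / medians[gid] if normalize else float(expression[g])
        scores.append(s)
        toks.append(vocab.token(gid))
    scores = np.asarray(scores, dtype=np.float64)
    toks = np.asarray(toks, dtype=np.int64)
    order = np.lexsort((toks, -scores))  # descending score, ascending token id
    ranked = toks[order][: max_input - 1]
    tokens = np.concatenate([[CLS], ranked])
    return CellSentence(tokens=tokens, source_cell=source_cell, label=label)


def encode_dataset(dataset: RawDataset, medians: dict[str, float],
                   vocab: GeneVocabulary, max_input: int = 2048,
                   label_column: str | None = None,
                   normalize: bool = True) -> TokenizedCorpus:
    """One sentence per cell; labels carried from ``label_column`` if given."""
    labels = (dataset.cell_meta[label_column].to_numpy()
              if label_column else [None] * dataset.n_cells)
    csc = dataset.counts.tocsc()
    sentences = []
    for j, cell_id in enumerate(dataset.cell_ids):
        col = np.asarray(csc[:, j].todense()).ravel()
        sentences.append(encode_cell(
            col, dataset.gene_ids, medians, vocab, max_input,
            source_cell=str(cell_id), label=labels[j], normalize=normalize,
        ))
    return TokenizedCorpus(
        sentences=sentences, vocab=vocab, max_input=max_input,
        meta=dataset.cell_meta.copy(),
    )
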