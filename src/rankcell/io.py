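"""Readers/writers for single-cell formats, the Arrow corpus layout, and the
pipeline configuration.

The internal orientation is genes x cells. Loom files natively store genes
as rows; h5ad (AnnData) stores cells x genes and is transposed on load;
MatrixMarket triples are read in the genes x cells convention with the
orientation inferred from the sidecar files. Ensembl version suffixes are
stripped on load. Mitochondrial flags come from an explicit boolean gene
attribute when present, otherwise from a case-insensitive "mt-" prefix.
"""
from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import pyarrow as pa
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError
from scipy import io as sio
from scipy import sparse

from .data import RawDataset
from .encoding import CellSentence, GeneVocabulary, TokenizedCorpus
from .errors import ConfigurationError, DataError
from .orthologs import strip_version


def _mito_from_names(gene_ids) -> np.ndarray:
    return np.array([str(g).lower().startswith("mt-") for g in gene_ids])


def _clean_ids(gene_ids) -> np.ndarray:
    return np.array([strip_version(str(g)) for g in gene_ids], dtype=object)


# ---------------------------------------------------------------------------
# RawDataset readers/writers
# ---------------------------------------------------------------------------

def read_dataset(path, format: str | None = None,
                 orientation: str | None = None) -> RawDataset:
    """Read a raw count dataset from h5ad, loom or a MatrixMarket triple.

    ``format`` is inferred from the path when omitted. ``orientation``
    ("genes_x_cells" or "cells_x_genes") disambiguates MatrixMarket input
    whose sidecar files do not determine it.
    """
    path = Path(path)
    if format is None:
        if path.suffix == ".h5ad":
            format = "h5ad"
        elif path.suffix == ".loom":
            format = "loom"
        elif path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        else:
            raise DataError(f"cannot infer format of {path}")
    try:
        if format == "h5ad":
            return _read_h5ad(path)
        if format == "loom":
            return _read_loom(path)
        if format == "mtx":
            return _read_mtx(path, orientation)
    except (OSError, ValueError) as e:
        raise DataError(f"failed to parse {path}: {e}") from e
    raise DataError(f"unknown format {format!r}")


def _read_h5ad(path: Path) -> RawDataset:
    adata = ad.read_h5ad(path)
    counts = sparse.csr_matrix(adata.X.T)  # AnnData is cells x genes
    counts.data = np.round(counts.data).astype(np.int64)
    gene_ids = _clean_ids(adata.var_names)
    if "mito" in adata.var.columns:
        mito = adata.var["mito"].to_numpy(dtype=bool)
    else:
        mito = _mito_from_names(adata.var_names)
    meta = adata.obs.copy()
    return RawDataset(counts=counts, gene_ids=gene_ids, mito_flags=mito,
                      cell_meta=meta)


def write_h5ad(dataset: RawDataset, path) -> None:
    var = pd.DataFrame({"mito": dataset.mito_flags},
                       index=pd.Index(dataset.gene_ids.astype(str), name="gene_id"))
    adata = ad.AnnData(X=dataset.counts.T.tocsr().astype(np.float32),
                       obs=dataset.cell_meta.copy(), var=var)
    adata.write_h5ad(Path(path))


def _read_loom(path: Path) -> RawDataset:
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise DataError(f"{path} is not a loom file (no /matrix)")
        counts = np.asarray(f["matrix"])  # loom rows are genes
        ra = f.get("row_attrs", {})
        ca = f.get("col_attrs", {})

        def _str(a):
            return np.array([x.decode() if isinstance(x, bytes) else str(x)
                             for x in a], dtype=object)

        if "Gene" in ra:
            gene_ids = _clean_ids(_str(ra["Gene"][:]))
        else:
            gene_ids = np.array([f"gene{i}" for i in range(counts.shape[0])],
                                dtype=object)
        mito = (np.asarray(ra["mito"][:], dtype=bool) if "mito" in ra
                else _mito_from_names(gene_ids))
        if "CellID" in ca:
            index = pd.Index(_str(ca["CellID"][:]))
        else:
            index = pd.Index([f"cell{i}" for i in range(counts.shape[1])])
        meta = pd.DataFrame(index=index)
        for key in ca:
            if key != "CellID":
                meta[key] = _str(ca[key][:])
    return RawDataset(counts=sparse.csr_matrix(counts.astype(np.int64)),
                      gene_ids=gene_ids, mito_flags=mito, cell_meta=meta)


def write_loom(dataset: RawDataset, path) -> None:
    """Minimal loom layout: /matrix (genes x cells) + row/col attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix",
                         data=np.asarray(dataset.counts.todense(), dtype=np.int64))
        ra = f.create_group("row_attrs")
        ra.create_dataset("Gene",
                          data=np.array([s.encode() for s in
                                         dataset.gene_ids.astype(str)]))
        ra.create_dataset("mito", data=dataset.mito_flags.astype(np.int8))
        ca = f.create_group("col_attrs")
        ca.create_dataset("CellID",
                          data=np.array([str(s).encode()
                                         for s in dataset.cell_ids]))
        for col in dataset.cell_meta.columns:
            ca.create_dataset(col, data=np.array(
                [str(v).encode() for v in dataset.cell_meta[col]]))


def _read_mtx(path: Path, orientation: str | None) -> RawDataset:
    d = path if path.is_dir() else path.parent
    mtx_path = d / "matrix.mtx" if path.is_dir() else path
    counts = sparse.csr_matrix(sio.mmread(mtx_path)).astype(np.int64)
    genes_file = next((d / n for n in ("genes.tsv", "features.tsv")
                       if (d / n).exists()), None)
    barcodes_file = d / "barcodes.tsv" if (d / "barcodes.tsv").exists() else None
    gene_ids = mito = None
    if genes_file is not None:
        gdf = pd.read_csv(genes_file, sep="\t", header=None, dtype=str)
        gene_ids = _clean_ids(gdf[0])
        if gdf.shape[1] >= 2 and set(gdf[1].unique()) <= {"0", "1", "True", "False"}:
            mito = gdf[1].isin(["1", "True"]).to_numpy()
    n_rows, n_cols = counts.shape
    if orientation is None:
        if gene_ids is not None and len(gene_ids) == n_rows != n_cols:
            orientation = "genes_x_cells"
        elif gene_ids is not None and len(gene_ids) == n_cols != n_rows:
            orientation = "cells_x_genes"
        else:
            raise DataError(
                f"ambiguous matrix orientation in {mtx_path}; pass "
                "orientation='genes_x_cells' or 'cells_x_genes'")
    if orientation == "cells_x_genes":
        counts = counts.T.tocsr()
    if gene_ids is None:
        gene_ids = np.array([f"gene{i}" for i in range(counts.shape[0])],
                            dtype=object)
    if mito is None:
        mito = _mito_from_names(gene_ids)
    if barcodes_file is not None:
        index = pd.Index(pd.read_csv(barcodes_file, sep="\t", header=None,
                                     dtype=str)[0])
    else:
        index = pd.Index([f"cell{i}" for i in range(counts.shape[1])])
    meta_file = d / "meta.tsv"
    meta = (pd.read_csv(meta_file, sep="\t", index_col=0, dtype=str)
            if meta_file.exists() else pd.DataFrame(index=index))
    return RawDataset(counts=counts, gene_ids=gene_ids, mito_flags=mito,
                      cell_meta=meta)


def write_mtx(dataset: RawDataset, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(d / "matrix.mtx", dataset.counts.tocoo())
    pd.DataFrame({0: dataset.gene_ids.astype(str),
                  1: dataset.mito_flags.astype(int)}).to_csv(
        d / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(dataset.cell_ids.astype(str)).to_csv(
        d / "barcodes.tsv", sep="\t", header=False, index=False)
    if len(dataset.cell_meta.columns):
        dataset.cell_meta.to_csv(d / "meta.tsv", sep="\t")


def write_dataset(dataset: RawDataset, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {"h5ad": "h5ad", ".h5ad": "h5ad", ".loom": "loom"}.get(
            path.suffix, "mtx" if path.suffix == "" else None)
    if format == "h5ad":
        write_h5ad(dataset, path)
    elif format == "loom":
        write_loom(dataset, path)
    elif format == "mtx":
        write_mtx(dataset, path)
    else:
        raise DataError(f"unknown output format for {path}")


# ---------------------------------------------------------------------------
# Arrow corpus
# ---------------------------------------------------------------------------

def write_corpus_arrow(corpus: TokenizedCorpus, path, append: bool = False) -> dict:
    """Serialize a tokenized corpus as a columnar Arrow dataset directory.

    Layout: ``data.arrow`` (input_ids, length, cell_id, label),
    ``vocab.json`` and ``manifest.json`` (vocabulary hash + tokenizer
    settings). Appending to a corpus built with a different vocabulary is an
    error. Returns the manifest.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest_path = path / "manifest.json"
    vocab_hash = corpus.vocab.content_hash()
    old_sentences: list[CellSentence] = []
    if append:
        if not manifest_path.exists():
            raise DataError(f"cannot append: no corpus at {path}")
        old = json.loads(manifest_path.read_text())
        if old["vocab_hash"] != vocab_hash:
            raise DataError(
                f"vocabulary hash mismatch on append: corpus {old['vocab_hash']} "
                f"vs new {vocab_hash}")
        old_corpus = read_corpus_arrow(path)
        old_sentences = old_corpus.sentences
    sentences = old_sentences + corpus.sentences
    table = pa.table({
        "input_ids": pa.array([s.tokens.tolist() for s in sentences],
                              type=pa.list_(pa.int32())),
        "length": pa.array([len(s) for s in sentences], type=pa.int32()),
        "cell_id": pa.array([s.source_cell for s in sentences]),
        "label": pa.array([None if s.label is None else str(s.label)
                           for s in sentences]),
    })
    with pa.OSFile(str(path / "data.arrow"), "wb") as sink:
        with pa.ipc.new_file(sink, table.schema) as writer:
            writer.write_table(table)
    corpus.vocab.save(path / "vocab.json")
    manifest = {
        "vocab_hash": vocab_hash,
        "vocab_size": corpus.vocab.size,
        "max_input": corpus.max_input,
        "n_cells": len(sentences),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def read_corpus_arrow(path, expected_vocab: GeneVocabulary | None = None
                      ) -> TokenizedCorpus:
    """Load a tokenized corpus; an ``expected_vocab`` with a different hash
    is a hard error (no silent remapping)."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    vocab = GeneVocabulary.load(path / "vocab.json")
    if expected_vocab is not None and \
            expected_vocab.content_hash() != manifest["vocab_hash"]:
        raise DataError(
            f"corpus at {path} was tokenized with a different vocabulary "
            f"({manifest['vocab_hash']} != {expected_vocab.content_hash()})")
    with pa.OSFile(str(path / "data.arrow"), "rb") as f:
        table = pa.ipc.open_file(f).read_all()
    ids = table["input_ids"].to_pylist()
    cells = table["cell_id"].to_pylist()
    labels = table["label"].to_pylist()
    sentences = [CellSentence(tokens=np.asarray(t, dtype=np.int64),
                              source_cell=c, label=l)
                 for t, c, l in zip(ids, cells, labels)]
    return TokenizedCorpus(sentences=sentences, vocab=vocab,
                           max_input=manifest["max_input"])


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QCSection(_Section):
    sd_multiplier: float = 3.0
    min_genes_per_cell: int = 7
    max_total_counts: int = 20_000
    two_sided: bool = True
    mito_mode: str = "sum"


class TokenizerSection(_Section):
    max_input: int = 2048
    normalize: bool = True


class EncoderSection(_Section):
    max_input: int = 2048
    n_blocks: int = 6
    n_heads: int = 4
    embed_dim: int = 256
    dropout: float = 0.02


class ScheduleSection(_Section):
    epochs: int = 10
    max_lr: float = 1e-3
    warmup_steps: int = 10_000
    batch_size: int = 12
    weight_decay: float = 1e-3
    freeze_blocks: int = 0
    mask_rate: float = 0.15


class PerturbSection(_Section):
    op: str = "delete"
    n_random: int = 10
    accuracy_gate: float = 0.90
    override_gate: bool = False


class PipelineConfig(_Section):
    """Nested configuration for the whole pipeline; unknown keys rejected."""

    seed: int = 0
    qc: QCSection = QCSection()
    tokenizer: TokenizerSection = TokenizerSection()
    encoder: EncoderSection = EncoderSection()
    pretrain: ScheduleSection = ScheduleSection()
    finetune: ScheduleSection = ScheduleSection(max_lr=5e-5, warmup_steps=500)
    perturbation: PerturbSection = PerturbSection()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**raw)
        except ValidationError as e:
            raise ConfigurationError(f"invalid config {path}: {e}") from e

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump()))
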