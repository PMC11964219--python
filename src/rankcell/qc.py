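"""Per-dataset cell quality filtering and corpus-level gene statistics.

Four per-dataset filters remove artifact cells (ambient RNA, doublets,
empty droplets): total counts more than ``sd_multiplier`` standard
deviations from the dataset mean, mitochondrial counts likewise, fewer
than ``min_genes_per_cell`` detected genes, and total counts strictly
exceeding ``max_total_counts``. All four predicates are evaluated against
statistics computed on the pre-filter dataset in a single conjunctive
pass. The nonzero gene medians computed here normalize expression in the
rank-value tokenizer.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import RawDataset
from .errors import ConfigurationError, DataError

FILTER_NAMES = ("total_sd", "mito_sd", "min_genes", "max_total")


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow the corpus-construction protocol."""

    sd_multiplier: float = 3.0
    min_genes_per_cell: int = 7
    max_total_counts: int = 20_000
    #: two-sided reads "more than k SD from the mean" as |x - mu| > k*sd;
    #: set False for the one-sided (upper tail only) variant.
    two_sided: bool = True
    #: "sum": mitochondrial expression level = summed mito counts;
    #: "fraction": mito counts / total counts.
    mito_mode: str = "sum"

    def __post_init__(self):
        if self.sd_multiplier <= 0 or self.min_genes_per_cell <= 0 \
                or self.max_total_counts <= 0:
            raise ConfigurationError("QC thresholds must be strictly positive")
        if self.mito_mode not in ("sum", "fraction"):
            raise ConfigurationError("mito_mode must be 'sum' or 'fraction'")


@dataclass(frozen=True)
class QCStats:
    """Population moments of one dataset, computed before any removal."""

    mean_total: float
    sd_total: float
    mean_mito: float
    sd_mito: float
    n_cells: int
    mito_mode: str = "sum"


@dataclass
class FilterReport:
    """Outcome of one filtering pass."""

    kept_index: np.ndarray
    removed: dict[str, list[str]]  # cell id -> filters that fired
    counts_per_filter: dict[str, int] = field(default_factory=dict)
    n_passes: int = 1


def _cell_vectors(dataset: RawDataset, mito_mode: str):
    csc = dataset.counts.tocsc()
    totals = np.asarray(csc.sum(axis=0)).ravel().astype(np.float64)
    if dataset.mito_flags.any():
        mito = np.asarray(csc[dataset.mito_flags].sum(axis=0)).ravel().astype(np.float64)
    else:
        mito = np.zeros_like(totals)
    if mito_mode == "fraction":
        with np.errstate(invalid="ignore", divide="ignore"):
            mito = np.where(totals > 0, mito / totals, 0.0)
    detected = np.diff(csc.indptr)
    return totals, mito, detected


def dataset_stats(dataset: RawDataset, mito_mode: str = "sum") -> QCStats:
    """Mean/SD of per-cell total and mitochondrial expression (population SD,
    computed on all cells before any removal)."""
    if dataset.n_cells == 0:
        raise DataError("cannot compute QC statistics on an empty dataset")
    totals, mito, _ = _cell_vectors(dataset, mito_mode)
    return QCStats(
        mean_total=float(totals.mean()), sd_total=float(totals.std()),
        mean_mito=float(mito.mean()), sd_mito=float(mito.std()),
        n_cells=dataset.n_cells, mito_mode=mito_mode,
    )


def apply_filters(dataset: RawDataset, stats: QCStats,
                  thresholds: QCThresholds = QCThresholds()
                  ) -> tuple[RawDataset, FilterReport]:
    """Remove cells failing any filter; report every predicate fired per cell.

    All four predicates use the supplied pre-filter ``stats`` (one conjunctive
    pass, no sequential re-estimation). The 20,000-count cap is strict
    ("exceeded"): a cell at exactly the cap is retained.
    """
    if stats.n_cells != dataset.n_cells:
        raise DataError(
            f"stats computed on {stats.n_cells} cells, dataset has {dataset.n_cells}"
        )
    if stats.mito_mode != thresholds.mito_mode:
        raise DataError("stats mito_mode does not match thresholds mito_mode")
    totals, mito, detected = _cell_vectors(dataset, thresholds.mito_mode)
    k = thresholds.sd_multiplier
    if thresholds.two_sided:
        f_total = np.abs(totals - stats.mean_total) > k * stats.sd_total
        f_mito = np.abs(mito - stats.mean_mito) > k * stats.sd_mito
    else:
        f_total = totals - stats.mean_total > k * stats.sd_total
        f_mito = mito - stats.mean_mito > k * stats.sd_mito
    f_detected = detected < thresholds.min_genes_per_cell
    f_max = totals > thresholds.max_total_counts

    fired = {
        "total_sd": f_total, "mito_sd": f_mito,
        "min_genes": f_detected, "max_total": f_max,
    }
    any_fired = f_total | f_mito | f_detected | f_max
    cell_ids = dataset.cell_ids
    removed = {}
    for j in np.flatnonzero(any_fired):
        removed[str(cell_ids[j])] = [n for n in FILTER_NAMES if fired[n][j]]
    report = FilterReport(
        kept_index=cell_ids[~any_fired],
        removed=removed,
        counts_per_filter={n: int(fired[n].sum()) for n in FILTER_NAMES},
    )
    return dataset.subset_cells(~any_fired), report


def compute_gene_medians(corpus) -> dict[str, float]:
    """Median of each gene's strictly positive counts pooled over all cells
    of all datasets. Genes never expressed are absent from the table.

    Parameters
    ----------
    corpus
        A :class:`RawDataset` or an iterable of them sharing one gene universe.
    """
    if isinstance(corpus, RawDataset):
        corpus = [corpus]
    corpus = list(corpus)
    if not corpus:
        raise DataError("empty corpus")
    ref_ids = corpus[0].gene_ids
    per_gene: list[list[np.ndarray]] = [[] for _ in ref_ids]
    for ds in corpus:
        if not np.array_equal(ds.gene_ids, ref_ids):
            diff = sorted(set(ds.gene_ids) ^ set(ref_ids))
            raise DataError(f"gene universe mismatch across datasets: {diff[:10]}")
        csr = ds.counts.tocsr()
        for g in range(len(ref_ids)):
            row = csr.data[csr.indptr[g]:csr.indptr[g + 1]]
            row = row[row > 0]
            if row.size:
                per_gene[g].append(row)
    table: dict[str, float] = {}
    for g, chunks in enumerate(per_gene):
        if chunks:
            table[str(ref_ids[g])] = float(np.median(np.concatenate(chunks)))
    return table
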