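"""Synthetic single-cell count data with known (planted) structure.

Every downstream stage — QC, tokenization, pretraining, fine-tuning,
perturbation — is exercised on data from this module, so the generator
commits to exactly the properties those stages assume: sparse non-negative
integer counts with a heavy tail (negative binomial), disjoint cell-type
gene programs whose genes dominate the top ranks of their cells, flagged
mitochondrial genes, optional condition-specific causal genes, and cells
engineered to violate individual QC filters.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .data import RawDataset
from .errors import ConfigurationError, GenerationError

#: QC thresholds mirrored here so planted-truth annotations are computed
#: independently of the qc module under test.
_SD_MULTIPLIER = 3.0
_MIN_GENES = 7
_MAX_TOTAL = 20_000

QC_FILTERS = ("total_sd", "mito_sd", "min_genes", "max_total")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``program_size`` genes per cell type are boosted ``program_fold``-fold in
    cells of that type; counts are negative binomial with per-gene mean
    ``baseline_mean`` (times any boost) and dispersion ``dispersion``
    (variance = m + dispersion * m^2).
    """

    n_cells: int = 1000
    n_genes: int = 500
    n_cell_types: int = 4
    program_size: int = 25
    program_fold: float = 8.0
    baseline_mean: float = 2.0
    dispersion: float = 0.1
    mito_fraction: float = 0.05
    n_conditions: int = 1
    causal_genes: tuple[str, ...] = ()
    causal_fold: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0 or self.n_genes <= 0:
            raise ConfigurationError("n_cells must be >= 0 and n_genes > 0")
        if self.n_cell_types < 1 or self.program_size < 0:
            raise ConfigurationError("need >= 1 cell type and program_size >= 0")
        n_mito = int(np.floor(self.mito_fraction * self.n_genes))
        if self.program_size * self.n_cell_types + n_mito > self.n_genes:
            raise ConfigurationError(
                "programs overlap: program_size * n_cell_types + mito genes "
                f"({self.program_size * self.n_cell_types + n_mito}) exceeds "
                f"n_genes ({self.n_genes})"
            )
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ConfigurationError("baseline_mean must be > 0, dispersion >= 0")
        if not (0 <= self.mito_fraction < 1):
            raise ConfigurationError("mito_fraction must be in [0, 1)")
        if self.n_conditions not in (1, 2):
            raise ConfigurationError("n_conditions must be 1 or 2")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator.

    ``qc_violation_index`` maps each engineered bad cell's identifier to the
    exact list of QC filters it violates in the final dataset.
    """

    cell_type_labels: np.ndarray
    condition_labels: np.ndarray | None = None
    qc_violation_index: dict[str, list[str]] = field(default_factory=dict)
    causal_genes: tuple[str, ...] = ()


def gene_ids_for(n_genes: int) -> np.ndarray:
    """Ensembl-style mouse gene identifiers."""
    return np.array([f"ENSMUSG{i:011d}" for i in range(n_genes)], dtype=object)


def program_genes(config: SyntheticConfig) -> list[np.ndarray]:
    """Disjoint index sets, one gene program per cell type (from the front)."""
    return [
        np.arange(t * config.program_size, (t + 1) * config.program_size)
        for t in range(config.n_cell_types)
    ]


def _mito_indices(config: SyntheticConfig) -> np.ndarray:
    n_mito = int(np.floor(config.mito_fraction * config.n_genes))
    return np.arange(config.n_genes - n_mito, config.n_genes)


def _sample_nb(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draw; Poisson limit at dispersion == 0."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _build(config: SyntheticConfig, conditions: bool) -> tuple[RawDataset, PlantedTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = gene_ids_for(config.n_genes)
    mito = np.zeros(config.n_genes, dtype=bool)
    mito[_mito_indices(config)] = True

    n = config.n_cells
    if n == 0:
        truth = PlantedTruth(
            cell_type_labels=np.array([], dtype=object),
            condition_labels=np.array([], dtype=object) if conditions else None,
            causal_genes=config.causal_genes if conditions else (),
        )
        ds = RawDataset(
            counts=sparse.csr_matrix((config.n_genes, 0), dtype=np.int64),
            gene_ids=gene_ids, mito_flags=mito,
            cell_meta=pd.DataFrame(index=pd.Index([], dtype=object)),
        )
        return ds, truth

    # balanced cell-type assignment, shuffled
    types = np.tile(np.arange(config.n_cell_types), n // config.n_cell_types + 1)[:n]
    types = rng.permutation(types)

    causal_idx = np.array([], dtype=int)
    cond = None
    if conditions:
        if config.n_conditions != 2:
            raise ConfigurationError("generate_condition_pair needs n_conditions=2")
        if not config.causal_genes:
            raise ConfigurationError("generate_condition_pair needs causal_genes")
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in config.causal_genes if g not in gene_pos]
        if missing:
            raise ConfigurationError(f"causal genes not in gene universe: {missing}")
        causal_idx = np.array([gene_pos[g] for g in config.causal_genes])
        cond = np.where(np.arange(n) % 2 == 0, "A", "B").astype(object)
        cond = rng.permutation(cond)

    mean = np.full((config.n_genes, n), config.baseline_mean, dtype=np.float64)
    programs = program_genes(config)
    for t, prog in enumerate(programs):
        cols = np.flatnonzero(types == t)
        if prog.size and cols.size:
            mean[np.ix_(prog, cols)] *= config.program_fold
    if conditions and config.causal_fold != 1.0:
        b_cols = np.flatnonzero(cond == "B")
        mean[np.ix_(causal_idx, b_cols)] *= config.causal_fold

    counts = _sample_nb(mean, config.dispersion, rng).astype(np.int64)
    meta = pd.DataFrame(
        {
            "dataset_id": "synthetic",
            "cell_type": np.array([f"type{t}" for t in types], dtype=object),
        },
        index=pd.Index([f"cell{i}" for i in range(n)], dtype=object),
    )
    if conditions:
        meta["condition"] = cond
    ds = RawDataset(
        counts=sparse.csr_matrix(counts), gene_ids=gene_ids,
        mito_flags=mito, cell_meta=meta,
    )
    truth = PlantedTruth(
        cell_type_labels=meta["cell_type"].to_numpy(),
        condition_labels=cond,
        causal_genes=config.causal_genes if conditions else (),
    )
    return ds, truth


def generate_corpus(config: SyntheticConfig) -> tuple[RawDataset, PlantedTruth]:
    """Generate a single-condition corpus with planted cell-type programs."""
    return _build(replace(config, n_conditions=1), conditions=False)


def generate_condition_pair(config: SyntheticConfig) -> tuple[RawDataset, PlantedTruth]:
    """Generate a two-condition dataset: condition B cells have the causal
    genes' means multiplied by ``causal_fold``; all other structure shared."""
    return _build(config, conditions=True)


def qc_calibration_corpus(n_cells: int = 500, n_genes: int = 100,
                          total_per_cell: int = 600, mito_per_cell: int = 30,
                          mito_genes: int = 5, seed: int = 0) -> RawDataset:
    """A clean population that is *well separated* by construction for QC
    planting: every cell has exactly ``total_per_cell`` total counts and
    ``mito_per_cell`` mitochondrial counts (multinomial allocation), so no
    clean cell can sit in the tail of the 3-SD filters once violating cells
    are planted. Negative-binomial corpora have unbounded tails and always
    place a few honest cells beyond 3 SD; this corpus exists so planted
    violations are the only removable cells.
    """
    rng = np.random.default_rng(seed)
    gene_ids = gene_ids_for(n_genes)
    mito = np.zeros(n_genes, dtype=bool)
    if mito_genes:
        mito[n_genes - mito_genes:] = True
        body = rng.multinomial(total_per_cell - mito_per_cell,
                               np.full(n_genes - mito_genes,
                                       1.0 / (n_genes - mito_genes)),
                               size=n_cells).T
        mbody = rng.multinomial(mito_per_cell,
                                np.full(mito_genes, 1.0 / mito_genes),
                                size=n_cells).T
        counts = np.vstack([body, mbody]).astype(np.int64)
    else:
        counts = rng.multinomial(total_per_cell,
                                 np.full(n_genes, 1.0 / n_genes),
                                 size=n_cells).T.astype(np.int64)
    meta = pd.DataFrame(
        {"dataset_id": "qc_calibration"},
        index=pd.Index([f"cell{i}" for i in range(n_cells)], dtype=object))
    return RawDataset(counts=sparse.csr_matrix(counts), gene_ids=gene_ids,
                      mito_flags=mito, cell_meta=meta)


# ---------------------------------------------------------------------------
# QC violation planting
# ---------------------------------------------------------------------------

def _violations_fired(counts: sparse.csr_matrix, mito_flags: np.ndarray
                      ) -> list[list[str]]:
    """Which QC filters fire per cell, computed with local arithmetic only
    (independent of the qc module, which these annotations later validate)."""
    csc = counts.tocsc()
    totals = np.asarray(csc.sum(axis=0)).ravel().astype(np.float64)
    mito_totals = np.asarray(csc[mito_flags].sum(axis=0)).ravel().astype(np.float64)
    detected = np.diff(csc.indptr)  # nonzeros per column
    mu_t, sd_t = totals.mean(), totals.std()
    mu_m, sd_m = mito_totals.mean(), mito_totals.std()
    out: list[list[str]] = []
    for j in range(counts.shape[1]):
        fired = []
        if np.abs(totals[j] - mu_t) > _SD_MULTIPLIER * sd_t:
            fired.append("total_sd")
        if np.abs(mito_totals[j] - mu_m) > _SD_MULTIPLIER * sd_m:
            fired.append("mito_sd")
        if detected[j] < _MIN_GENES:
            fired.append("min_genes")
        if totals[j] > _MAX_TOTAL:
            fired.append("max_total")
        out.append(fired)
    return out


def plant_qc_violations(dataset: RawDataset, spec: dict[str, int], seed: int = 0
                        ) -> tuple[RawDataset, PlantedTruth]:
    """Append cells engineered to violate named QC filters.

    ``spec`` maps filter names (subset of :data:`QC_FILTERS`) to the number
    of violating cells to append. Each appended cell is annotated with the
    exact set of filters it violates in the *final* dataset (a cell planted
    for one filter may necessarily trip another, e.g. a >20,000-total cell
    is usually also a 3-SD outlier). Raises :class:`GenerationError` if a
    requested violation cannot be realized or if any clean cell would be
    caught by a filter after planting.
    """
    unknown = set(spec) - set(QC_FILTERS)
    if unknown:
        raise ConfigurationError(f"unknown QC filters in spec: {sorted(unknown)}")
    n_new = sum(int(v) for v in spec.values())
    if n_new == 0:
        truth = PlantedTruth(
            cell_type_labels=dataset.cell_meta.get(
                "cell_type", pd.Series(index=dataset.cell_meta.index, dtype=object)
            ).to_numpy(),
        )
        return dataset, truth
    if any(v < 0 for v in spec.values()):
        raise ConfigurationError("violation counts must be >= 0")
    if n_new > dataset.n_cells:
        raise ConfigurationError("spec counts exceed n_cells")

    rng = np.random.default_rng(seed)
    n_genes = dataset.n_genes
    mito = dataset.mito_flags
    if spec.get("mito_sd", 0) and not mito.any():
        raise GenerationError("mito_sd violations need mitochondrial genes")

    totals = np.asarray(dataset.counts.sum(axis=0)).ravel().astype(np.float64)
    mito_totals = np.asarray(
        dataset.counts[mito].sum(axis=0)
    ).ravel().astype(np.float64) if mito.any() else np.zeros(dataset.n_cells)
    mu_t, sd_t = totals.mean(), totals.std()
    mu_m, sd_m = mito_totals.mean(), mito_totals.std()

    new_cols: list[np.ndarray] = []
    intents: list[str] = []

    for _ in range(int(spec.get("min_genes", 0))):
        v = np.zeros(n_genes, dtype=np.int64)
        picks = rng.choice(np.flatnonzero(~mito), size=min(3, n_genes), replace=False)
        v[picks] = 1
        new_cols.append(v)
        intents.append("min_genes")

    for _ in range(int(spec.get("max_total", 0))):
        v = rng.multinomial(_MAX_TOTAL + 5000, np.full(n_genes, 1.0 / n_genes))
        new_cols.append(v.astype(np.int64))
        intents.append("max_total")

    # Extreme-total cells sit 6 clean-population SDs above the mean. Cells
    # planted for other filters (notably max_total) inflate the final SD;
    # account for that before choosing the target.
    planted_totals = [float(c.sum()) for c in new_cols]
    n_final = dataset.n_cells + n_new
    all_totals = np.concatenate([totals, planted_totals])

    def projected_sd(extra: list[float]) -> tuple[float, float]:
        t = np.concatenate([all_totals, extra])
        pad = n_final - t.size
        t = np.concatenate([t, np.full(pad, t.mean())]) if pad > 0 else t
        return float(t.mean()), float(t.std())

    n_total_sd = int(spec.get("total_sd", 0))
    if n_total_sd:
        target = None
        for _ in range(8):  # fixed-point: target depends on its own inclusion
            mu_p, sd_p = projected_sd([target] * n_total_sd if target else [])
            target = mu_p + 6.0 * max(sd_p, sd_t, 1.0)
        if target > _MAX_TOTAL:
            raise GenerationError(
                "total_sd violation would exceed the 20,000-count cap; "
                "shrink the clean population spread"
            )
        for _ in range(n_total_sd):
            v = rng.multinomial(int(round(target)), np.full(n_genes, 1.0 / n_genes))
            new_cols.append(v.astype(np.int64))
            intents.append("total_sd")

    n_mito_sd = int(spec.get("mito_sd", 0))
    if n_mito_sd:
        # Other planted cells (e.g. >20,000-total ones) can carry extreme
        # mitochondrial totals that inflate the final mito SD; the bump is a
        # fixed point of its own inclusion in the statistics.
        mito_idx = np.flatnonzero(mito)
        planted_mito = [float(c[mito_idx].sum()) for c in new_cols]
        all_mito = np.concatenate([mito_totals, planted_mito])
        n_final_m = dataset.n_cells + n_new
        bump = mu_m + 6.0 * max(sd_m, 1.0)
        for _ in range(12):
            t = np.concatenate([all_mito, [bump] * n_mito_sd])
            pad = n_final_m - t.size
            if pad > 0:
                t = np.concatenate([t, np.full(pad, mu_m)])
            bump = float(t.mean()) + 6.0 * max(float(t.std()), sd_m, 1.0)
        for _ in range(n_mito_sd):
            # typical cell body + concentrated mitochondrial bump
            body = _sample_nb(np.full(n_genes, max(mu_t / n_genes, 0.1)), 0.1, rng)
            v = body.astype(np.int64)
            v[mito_idx] = 0
            v[mito_idx[0]] = int(round(bump)) + 1
            new_cols.append(v)
            intents.append("mito_sd")

    new_mat = sparse.csr_matrix(np.stack(new_cols, axis=1))
    combined = sparse.hstack([dataset.counts, new_mat], format="csr")
    new_ids = [f"planted{k}_{intents[k]}" for k in range(n_new)]
    new_meta = pd.DataFrame(index=pd.Index(new_ids, dtype=object))
    meta = pd.concat([dataset.cell_meta, new_meta])
    out = RawDataset(
        counts=combined, gene_ids=dataset.gene_ids.copy(),
        mito_flags=dataset.mito_flags.copy(), cell_meta=meta,
    )

    fired = _violations_fired(out.counts, out.mito_flags)
    n_clean = dataset.n_cells
    for j in range(n_clean):
        if fired[j]:
            raise GenerationError(
                f"clean cell {out.cell_ids[j]} trips {fired[j]} after planting; "
                "clean population is not well separated"
            )
    index: dict[str, list[str]] = {}
    for k in range(n_new):
        f = fired[n_clean + k]
        if intents[k] not in f:
            raise GenerationError(
                f"planted cell {new_ids[k]} fails to violate {intents[k]!r} "
                f"(fired: {f})"
            )
        index[new_ids[k]] = f

    truth = PlantedTruth(
        cell_type_labels=meta.get(
            "cell_type", pd.Series(index=meta.index, dtype=object)
        ).to_numpy(),
        qc_violation_index=index,
    )
    return out, truth
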