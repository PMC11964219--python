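"""In silico gene perturbation and its ranking statistic.

Deleting a gene removes its token from the cell sentence (later tokens move
one rank forward); activating a gene moves its token to rank 1, immediately
after [CLS]. The effect of perturbing a specific gene is measured as the
cosine similarity of each perturbed start cell's embedding to the mean
embedding of a goal cell state, compared against a random-gene control
distribution with the Wilcoxon rank-sum (Mann-Whitney U) test; p < 0.05
rejects the null that the specific gene acts like a random one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .encoding import N_SPECIALS, CellSentence, GeneVocabulary
from .errors import ConfigurationError, DataError
from .model import EncoderModel, embed_cells


# ---------------------------------------------------------------------------
# sentence transforms
# ---------------------------------------------------------------------------

def delete_gene(sentence: CellSentence, gene_token: int
                ) -> tuple[CellSentence, bool]:
    """Remove ``gene_token`` from the sentence; all later tokens move one
    position forward. Absent gene is a flagged no-op.

    Returns (new sentence, gene_was_present).
    """
    toks = sentence.tokens
    pos = np.flatnonzero(toks == gene_token)
    if pos.size == 0:
        return sentence, False
    out = np.delete(toks, pos[0])
    return CellSentence(tokens=out, source_cell=sentence.source_cell,
                        label=sentence.label), True


def activate_gene(sentence: CellSentence, gene_token: int,
                  vocab_size: int, max_input: int
                  ) -> tuple[CellSentence, bool]:
    """Reposition ``gene_token`` to rank 1 (immediately after [CLS]); tokens
    formerly ahead of it move one rank back. A gene absent from the sentence
    is inserted at rank 1 (dropping the last token if at ``max_input``).

    Returns (new sentence, gene_was_present).
    """
    if not (N_SPECIALS <= gene_token < vocab_size):
        raise ConfigurationError(f"token {gene_token} is not a gene token")
    toks = sentence.tokens
    pos = np.flatnonzero(toks == gene_token)
    if pos.size:
        rest = np.delete(toks[1:], pos[0] - 1)
        out = np.concatenate([[toks[0], gene_token], rest])
        present = True
    else:
        out = np.concatenate([[toks[0], gene_token], toks[1:]])[:max_input]
        present = False
    return CellSentence(tokens=out, source_cell=sentence.source_cell,
                        label=sentence.label), present


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """cos(u, v) in [-1, 1]; zero vectors are an error."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise DataError("embedding dimensions differ")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DataError("cosine similarity undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum / Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_ranksum_p(w: float, n: int, m: int) -> float:
    """Exact two-sided p for rank-sum ``w`` of the size-``n`` sample among
    ``n + m`` tie-free values, by dynamic-programming enumeration of the
    rank-sum distribution."""
    N = n + m
    max_w = n * N  # loose bound for table width
    counts = np.zeros((n + 1, max_w + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        # add rank r to subsets; iterate sizes downward
        counts[1: n + 1, r:] += counts[0: n, : max_w + 1 - r]
    dist = counts[n]
    total = dist.sum()
    w = int(round(w))
    p_le = dist[: w + 1].sum() / total
    p_ge = dist[w:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n + m <= 16 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.

    Returns (U statistic of the first sample, two-sided p value).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise DataError("wilcoxon_rank_sum needs non-empty samples")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)  # midranks
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= 16 and not has_ties:
        return u, _exact_ranksum_p(w, n, m)
    N = n + m
    mean_u = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (N * (N - 1.0))
                if N > 1 else 0.0)
    var_u = n * m / 12.0 * ((N + 1.0) - tie_term)
    if var_u <= 0:
        return u, 1.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)  # continuity correction
    z = max(z, 0.0)
    return u, float(min(1.0, 2.0 * sstats.norm.sf(z)))


# ---------------------------------------------------------------------------
# perturbation experiments
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSpec:
    """One gene perturbation experiment: move ``start_cells`` toward the
    state defined by ``goal_cells``."""

    gene: str
    op: str  # "delete" | "activate"
    start_cells: list[CellSentence]
    goal_cells: list[CellSentence]
    n_random: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.op not in ("delete", "activate"):
            raise ConfigurationError("op must be 'delete' or 'activate'")
        if self.n_random < 1:
            raise ConfigurationError("n_random must be >= 1")
        if not self.start_cells or not self.goal_cells:
            raise ConfigurationError("start and goal cell sets must be non-empty")


@dataclass
class PerturbationReport:
    """Similarity summary and Wilcoxon statistic for one gene."""

    gene: str
    op: str
    mean_specific: float
    mean_random: float
    mean_unperturbed: float
    shift: float  # mean_specific - mean_unperturbed
    u_stat: float
    p_value: float
    significant: bool = field(init=False)
    n_cells: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.significant = bool(self.p_value < 0.05)


def _apply(op: str, sentence: CellSentence, token: int,
           vocab_size: int, max_input: int) -> CellSentence:
    if op == "delete":
        return delete_gene(sentence, token)[0]
    return activate_gene(sentence, token, vocab_size, max_input)[0]


def perturbation_test(model: EncoderModel, spec: PerturbationSpec,
                      vocab: GeneVocabulary, layer: int | None = None,
                      pooling: str = "mean",
                      reference: np.ndarray | None = None) -> PerturbationReport:
    """Compare the cosine-similarity distribution under the specific
    perturbation with the pooled random-gene control distribution.

    The reference is the mean embedding of ``goal_cells``. For deletion,
    only start cells whose sentences contain the gene participate (deleting
    an absent gene is a no-op); an error is raised if no start cell contains
    it. The control perturbs, per cell and per repetition, one uniformly
    drawn gene from that cell's own sentence (excluding the gene under test),
    with the same operation, pooled over ``n_random`` repetitions.
    """
    if spec.gene not in vocab:
        raise ConfigurationError(f"gene {spec.gene!r} not in vocabulary")
    token = vocab.token(spec.gene)
    rng = np.random.default_rng(spec.seed)
    max_input = model.config.max_input
    vsize = model.config.vocab_size

    if spec.op == "delete":
        cells = [s for s in spec.start_cells if (s.tokens == token).any()]
        if not cells:
            raise DataError(
                f"nothing to perturb: {spec.gene!r} absent from every start cell")
    else:
        cells = list(spec.start_cells)
    flags = []
    if spec.op == "activate":
        absent = sum(1 for s in cells if not (s.tokens == token).any())
        if absent:
            flags.append(f"activated_absent_gene_in_{absent}_cells")

    if reference is None:
        goal_emb, _ = embed_cells(model, spec.goal_cells, layer=layer,
                                  pooling=pooling)
        ref = goal_emb.mean(axis=0)
    else:
        ref = np.asarray(reference)

    specific = [_apply(spec.op, s, token, vsize, max_input) for s in cells]
    controls: list[CellSentence] = []
    for _ in range(spec.n_random):
        for s in cells:
            pool = s.tokens[(s.tokens >= N_SPECIALS) & (s.tokens != token)]
            if pool.size == 0:
                raise DataError(
                    f"cell {s.source_cell!r} has no control genes to draw")
            controls.append(_apply(spec.op, s, int(rng.choice(pool)),
                                   vsize, max_input))

    all_sents = list(cells) + specific + controls
    emb, _ = embed_cells(model, all_sents, layer=layer, pooling=pooling)
    sims = np.array([cosine_similarity(e, ref) for e in emb])
    k = len(cells)
    unpert = sims[:k]
    spec_sims = sims[k: 2 * k]
    ctrl_sims = sims[2 * k:]
    u, p = wilcoxon_rank_sum(spec_sims, ctrl_sims)
    return PerturbationReport(
        gene=spec.gene, op=spec.op,
        mean_specific=float(spec_sims.mean()),
        mean_random=float(ctrl_sims.mean()),
        mean_unperturbed=float(unpert.mean()),
        shift=float(spec_sims.mean() - unpert.mean()),
        u_stat=u, p_value=p, n_cells=k, flags=flags,
    )


def screen_genes(model: EncoderModel, start_cells, goal_cells, candidates,
                 op: str, n_random: int, seed: int, vocab: GeneVocabulary,
                 layer: int | None = None, pooling: str = "mean",
                 classifier_accuracy: float | None = None,
                 accuracy_gate: float = 0.90,
                 override_gate: bool = False) -> pd.DataFrame:
    """One perturbation test per candidate gene, ranked by mean shift.

    A pre-flight check requires the fine-tuned classifier accuracy (when
    supplied) to reach ``accuracy_gate`` unless ``override_gate`` is set.
    Per-gene failures become flagged rows, not exceptions. The table is
    sorted by shift descending, ties by p ascending then gene id, and carries
    Benjamini-Hochberg q values.
    """
    candidates = list(candidates)
    if not candidates:
        raise ConfigurationError("no candidate genes")
    if not goal_cells:
        raise ConfigurationError("empty goal cell set")
    if (classifier_accuracy is not None and classifier_accuracy < accuracy_gate
            and not override_gate):
        raise ConfigurationError(
            f"classifier accuracy {classifier_accuracy:.4f} below the "
            f"{accuracy_gate:.0%} gate; pass override_gate=True to proceed")
    goal_emb, _ = embed_cells(model, list(goal_cells), layer=layer, pooling=pooling)
    reference = goal_emb.mean(axis=0)
    rows = []
    rng = np.random.default_rng(seed)
    for gene in sorted(candidates):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        try:
            rep = perturbation_test(
                model,
                PerturbationSpec(gene=gene, op=op, start_cells=list(start_cells),
                                 goal_cells=list(goal_cells), n_random=n_random,
                                 seed=sub_seed),
                vocab, layer=layer, pooling=pooling, reference=reference)
            rows.append({
                "gene": gene, "op": op, "mean_specific": rep.mean_specific,
                "mean_random": rep.mean_random,
                "mean_unperturbed": rep.mean_unperturbed, "shift": rep.shift,
                "u_stat": rep.u_stat, "p_value": rep.p_value,
                "significant": rep.significant, "n_cells": rep.n_cells,
                "error": "",
            })
        except (DataError, ConfigurationError) as e:
            rows.append({
                "gene": gene, "op": op, "mean_specific": np.nan,
                "mean_random": np.nan, "mean_unperturbed": np.nan,
                "shift": np.nan, "u_stat": np.nan, "p_value": np.nan,
                "significant": False, "n_cells": 0, "error": str(e),
            })
    table = pd.DataFrame(rows)
    ok = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(table.loc[ok, "p_value"],
                                         method="fdr_bh")[1]
    table["q_value"] = q
    table = table.sort_values(
        by=["shift", "p_value", "gene"], ascending=[False, True, True],
        na_position="last").reset_index(drop=True)
    return table
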