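"""Perturbation algebra, the Mann-Whitney U implementation, and the
similarity-shift experiment machinery."""
import itertools

import numpy as np
import pytest
from scipy import stats as sstats

import rankcell as rc
from rankcell.encoding import CLS, CellSentence
from rankcell.errors import ConfigurationError, DataError
from rankcell.perturb import (PerturbationSpec, activate_gene, cosine_similarity,
                              delete_gene, perturbation_test, screen_genes,
                              wilcoxon_rank_sum)


def _s(*genes):
    return CellSentence(tokens=np.array([CLS, *genes]))


class TestDeleteGene:
    def test_removal_shifts_later_tokens_forward(self):
        out, present = delete_gene(_s(10, 11, 12, 13), 11)
        assert present
        assert out.tokens.tolist() == [CLS, 10, 12, 13]

    def test_absent_gene_is_flagged_noop(self):
        s = _s(10, 11)
        out, present = delete_gene(s, 99)
        assert not present
        assert out.tokens.tolist() == s.tokens.tolist()

    def test_delete_matches_reencoding_with_zeroed_count(self):
        """For an untruncated cell, deleting a gene token equals re-encoding
        the cell with that gene's count set to zero."""
        rng = np.random.default_rng(4)
        gene_ids = np.array([f"g{i:02d}" for i in range(30)], dtype=object)
        med = {g: 2.0 for g in gene_ids}
        vocab = rc.build_vocabulary(gene_ids, med)
        counts = rng.poisson(2.0, 30)
        base = rc.encode_cell(counts, gene_ids, med, vocab, max_input=64)
        for gi in np.flatnonzero(counts):
            zeroed = counts.copy()
            zeroed[gi] = 0
            reenc = rc.encode_cell(zeroed, gene_ids, med, vocab, max_input=64)
            deleted, _ = delete_gene(base, vocab.token(str(gene_ids[gi])))
            assert deleted.tokens.tolist() == reenc.tokens.tolist()


class TestActivateGene:
    def test_reposition_to_rank_one(self):
        out, present = activate_gene(_s(10, 11, 12), 12, vocab_size=20,
                                     max_input=8)
        assert present
        assert out.tokens.tolist() == [CLS, 12, 10, 11]

    def test_rank_one_gene_is_idempotent(self):
        s = _s(10, 11, 12)
        out, _ = activate_gene(s, 10, vocab_size=20, max_input=8)
        assert out.tokens.tolist() == s.tokens.tolist()

    def test_absent_gene_inserted_dropping_last_when_full(self):
        s = _s(10, 11, 12)  # length 4 == max_input
        out, present = activate_gene(s, 15, vocab_size=20, max_input=4)
        assert not present
        assert out.tokens.tolist() == [CLS, 15, 10, 11]
        assert len(out) == 4

    def test_non_gene_token_rejected(self):
        with pytest.raises(ConfigurationError):
            activate_gene(_s(10), 1, vocab_size=20, max_input=8)


class TestAlgebraExhaustive:
    def test_invariants_on_all_short_sentences(self):
        """Removal semantics, move-to-front, idempotence and
        delete(activate(g)) == delete(g), exhaustively for every sentence
        with up to 4 gene tokens over a 10-gene vocabulary and every gene
        (the full length-8 sweep runs in the acceptance suite)."""
        genes = list(range(3, 13))
        vocab_size, max_input = 13, 8
        checked = 0
        for k in range(0, 5):
            for perm in itertools.permutations(genes, k):
                s = CellSentence(tokens=np.array([CLS, *perm]))
                base = (CLS, *perm)
                present_set = set(perm)
                for g in genes:
                    d, present = delete_gene(s, g)
                    dt = tuple(d.tokens.tolist())
                    a, _ = activate_gene(s, g, vocab_size, max_input)
                    at = tuple(a.tokens.tolist())
                    if g in present_set:
                        assert present
                        i = base.index(g)
                        assert dt == base[:i] + base[i + 1:]
                        assert len(d) == len(s) - 1
                        assert at == (CLS, g) + base[1:i] + base[i + 1:]
                        assert len(a) == len(s)
                        # delete after activate == plain delete
                        da, _ = delete_gene(a, g)
                        assert tuple(da.tokens.tolist()) == dt
                        if i == 1:  # already rank 1: idempotent
                            assert at == base
                    else:
                        assert not present and dt == base
                        expected = ((CLS, g) + base[1:])[:max_input]
                        assert at == expected
                    assert len(a) <= max_input
                    checked += 1
        assert checked > 0


class TestCosineSimilarity:
    def test_orthogonal_vectors(self):
        assert cosine_similarity([1, 0], [0, 1]) == 0.0

    def test_scale_invariance(self):
        assert cosine_similarity([1, 1], [2, 2]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(
            0.974631846, abs=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(DataError):
            cosine_similarity([0, 0], [1, 1])


class TestWilcoxon:
    def test_exact_small_sample_example(self):
        # a=(1,2), b=(3,4): all 6 orderings, two-sided p = 2/6
        u, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_not_significant(self):
        a = np.arange(20.0)
        _, p = wilcoxon_rank_sum(a, a)
        assert p >= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_for_all_tiefree_cases_up_to_10(self):
        """Exhaustive sweep: every (n, m) with n + m <= 10 and every
        assignment of the ranks 1..n+m; the two-sided p must equal the
        brute-force enumeration of the rank-sum distribution."""
        for N in range(2, 11):
            values = np.arange(1.0, N + 1)
            for n in range(1, N):
                # enumeration oracle: distribution of rank sums over all
                # C(N, n) subsets
                sums = np.array([sum(c) for c in
                                 itertools.combinations(range(1, N + 1), n)])
                for comb in itertools.combinations(range(N), n):
                    a = values[list(comb)]
                    b = np.delete(values, list(comb))
                    u, p = wilcoxon_rank_sum(a, b)
                    w = a.sum()
                    p_le = (sums <= w).mean()
                    p_ge = (sums >= w).mean()
                    expected = min(1.0, 2 * min(p_le, p_ge))
                    assert p == pytest.approx(expected, abs=1e-12), (N, n, a)

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n, m = rng.integers(2, 8, 2)
            pool = rng.permutation(np.arange(1.0, n + m + 1))
            a, b = pool[:n], pool[n:]
            u, p = wilcoxon_rank_sum(a, b)
            ref = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="exact")
            assert u == ref.statistic
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = rng.normal(0.5, size=35)
        u, p = wilcoxon_rank_sum(a, b)
        ref = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_rejection_rate_calibrated(self):
        """Type-I error at the 0.05 level under a simulated null
        (n = m = 30), within Monte-Carlo tolerance."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            _, p = wilcoxon_rank_sum(a, b)
            rejections += p < 0.05
        assert 0.04 <= rejections / n_rep <= 0.06


@pytest.fixture(scope="module")
def perturb_setup(tiny_bundle, finetuned_tiny):
    corpus = tiny_bundle["corpus"]
    labels = corpus.labels()
    start = [s for s, l in zip(corpus.sentences, labels) if l == "type0"][:12]
    goal = [s for s, l in zip(corpus.sentences, labels) if l == "type1"][:12]
    return {"model": finetuned_tiny["model"], "vocab": corpus.vocab,
            "start": start, "goal": goal,
            "gene_ids": tiny_bundle["dataset"].gene_ids}


class TestPerturbationTest:
    def test_deterministic_under_seed(self, perturb_setup):
        p = perturb_setup
        gene = str(p["gene_ids"][0])  # program gene of type0, present in cells
        spec = PerturbationSpec(gene=gene, op="delete", start_cells=p["start"],
                                goal_cells=p["goal"], n_random=1, seed=9)
        r1 = perturbation_test(p["model"], spec, p["vocab"])
        r2 = perturbation_test(p["model"], spec, p["vocab"])
        assert r1.mean_specific == r2.mean_specific
        assert r1.p_value == r2.p_value
        assert r1.significant == (r1.p_value < 0.05)

    def test_delete_of_absent_gene_everywhere_is_an_error(self, perturb_setup):
        p = perturb_setup
        # make a gene absent from every start cell by construction
        gene = str(p["gene_ids"][0])
        token = p["vocab"].token(gene)
        start = [delete_gene(s, token)[0] for s in p["start"]]
        spec = PerturbationSpec(gene=gene, op="delete", start_cells=start,
                                goal_cells=p["goal"], n_random=1, seed=0)
        with pytest.raises(DataError, match="nothing to perturb"):
            perturbation_test(p["model"], spec, p["vocab"])

    def test_similarities_within_bounds(self, perturb_setup):
        p = perturb_setup
        gene = str(p["gene_ids"][1])
        spec = PerturbationSpec(gene=gene, op="activate",
                                start_cells=p["start"], goal_cells=p["goal"],
                                n_random=2, seed=1)
        r = perturbation_test(p["model"], spec, p["vocab"])
        for v in (r.mean_specific, r.mean_random, r.mean_unperturbed):
            assert -1.0 <= v <= 1.0
        assert 0.0 <= r.p_value <= 1.0

    def test_null_configuration_rejection_rate_is_moderate(self, perturb_setup):
        """When the perturbed gene is itself an arbitrary expressed gene (a
        null configuration), significance should be the exception, not the
        rule."""
        p = perturb_setup
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 30
        neutral = [str(g) for g in p["gene_ids"][40:90]]
        for i in range(n_rep):
            gene = neutral[int(rng.integers(len(neutral)))]
            spec = PerturbationSpec(gene=gene, op="delete",
                                    start_cells=p["start"],
                                    goal_cells=p["goal"], n_random=2,
                                    seed=int(rng.integers(2 ** 31)))
            try:
                r = perturbation_test(p["model"], spec, p["vocab"])
            except DataError:
                continue
            rejections += r.significant
        assert rejections / n_rep < 0.3


class TestScreenGenes:
    def test_candidate_order_does_not_change_content(self, perturb_setup):
        p = perturb_setup
        genes = [str(g) for g in p["gene_ids"][:4]]
        t1 = screen_genes(p["model"], p["start"], p["goal"], genes,
                          op="delete", n_random=1, seed=3, vocab=p["vocab"])
        t2 = screen_genes(p["model"], p["start"], p["goal"], genes[::-1],
                          op="delete", n_random=1, seed=3, vocab=p["vocab"])
        assert t1["gene"].tolist() == t2["gene"].tolist()
        assert np.allclose(t1["shift"], t2["shift"])

    def test_empty_goal_set_rejected(self, perturb_setup):
        p = perturb_setup
        with pytest.raises(ConfigurationError):
            screen_genes(p["model"], p["start"], [], ["g"], op="delete",
                         n_random=1, seed=0, vocab=p["vocab"])

    def test_accuracy_gate_blocks_below_90_percent(self, perturb_setup):
        p = perturb_setup
        with pytest.raises(ConfigurationError, match="gate"):
            screen_genes(p["model"], p["start"], p["goal"], ["g"],
                         op="delete", n_random=1, seed=0, vocab=p["vocab"],
                         classifier_accuracy=0.85)
        # override proceeds (and the unknown gene becomes a flagged row)
        t = screen_genes(p["model"], p["start"], p["goal"],
                         [str(p["gene_ids"][0]), "NOT_A_GENE"],
                         op="delete", n_random=1, seed=0, vocab=p["vocab"],
                         classifier_accuracy=0.85, override_gate=True)
        assert (t["error"] != "").sum() == 1

    def test_sorted_by_shift_with_bh_column(self, perturb_setup):
        p = perturb_setup
        genes = [str(g) for g in p["gene_ids"][:5]]
        t = screen_genes(p["model"], p["start"], p["goal"], genes,
                         op="delete", n_random=2, seed=5, vocab=p["vocab"])
        shifts = t["shift"].to_numpy()
        assert all(a >= b for a, b in zip(shifts, shifts[1:]))
        assert "q_value" in t.columns
        ok = t["q_value"].notna()
        assert (t.loc[ok, "q_value"] >= t.loc[ok, "p_value"] - 1e-12).all()
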