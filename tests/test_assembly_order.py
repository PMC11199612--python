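"""Docking extraction, bit-scores, PNN features, pathway scoring, ranking."""

import itertools
import math

import numpy as np
import pytest

from pksmith import assembly_order as ao
from pksmith import fixtures as fx
from pksmith.bgc_model import BGC, Domain, Gene, Module


def _bgc(n: int, protein_len: int = 200) -> BGC:
    rng = np.random.default_rng(123)
    genes = [
        Gene(
            id=f"g{i}",
            protein=fx._random_protein(rng, protein_len),
            genomic_rank=i,
        )
        for i in range(n)
    ]
    return BGC(genes=genes)


class TestExtractDocking:
    def test_head_and_tail_slices(self):
        bgc = _bgc(2, protein_len=200)
        sites = ao.extract_docking(bgc)
        g = bgc.genes[0]
        assert sites["g0"].head_seq == g.protein[:100]
        assert sites["g0"].tail_seq == g.protein[150:200]

    def test_short_protein_truncates_with_warning(self):
        bgc = _bgc(1, protein_len=40)
        with pytest.warns(UserWarning, match="truncated"):
            sites = ao.extract_docking(bgc)
        assert sites["g0"].head_seq == bgc.genes[0].protein
        assert sites["g0"].tail_seq == bgc.genes[0].protein

    def test_single_gene_bgc_trivial_order(self):
        bgc = _bgc(1)
        result = ao.rank_pathways(bgc, pair_score={})
        assert result.n_candidates == 1
        assert result.orders[0].score == 0.0

    def test_terminal_genes_marked_excluded(self):
        rng = np.random.default_rng(5)
        start = Gene(
            id="start", protein=fx._random_protein(rng, 400), genomic_rank=0,
            modules=[Module(domains=[Domain("AT", "C" * 60)])],
        )
        mid = Gene(
            id="mid", protein=fx._random_protein(rng, 400), genomic_rank=1,
            modules=[Module(domains=[Domain("KS", "A" * 60),
                                     Domain("AT", "C" * 60)])],
        )
        end = Gene(
            id="end", protein=fx._random_protein(rng, 400), genomic_rank=2,
            modules=[Module(domains=[Domain("KS", "A" * 60),
                                     Domain("AT", "C" * 60),
                                     Domain("TE", "D" * 60)])],
        )
        sites = ao.extract_docking(BGC(genes=[start, mid, end]))
        assert sites["start"].head_excluded and not sites["start"].tail_excluded
        assert sites["end"].tail_excluded and not sites["end"].head_excluded
        assert not sites["mid"].head_excluded and not sites["mid"].tail_excluded


class TestBitscore:
    def test_hand_computed_local_alignment(self):
        # PAW vs PAWHE: best local alignment is the exact PAW block:
        # BLOSUM62 P->P 7, A->A 4, W->W 11, total raw score 22 (no gap helps)
        raw = 22
        expected = (ao.BITSCORE_LAMBDA * raw - math.log(ao.BITSCORE_K)) / math.log(2)
        assert ao.bitscore("PAWHE", "PAW") == pytest.approx(expected)

    def test_symmetric(self):
        assert ao.bitscore("MKLVHE", "ACDEFG") == ao.bitscore("ACDEFG", "MKLVHE")

    def test_self_similarity_dominates(self):
        rng = np.random.default_rng(1)
        x = fx._random_protein(rng, 30)
        for _ in range(10):
            y = fx._random_protein(rng, 30)
            assert ao.bitscore(x, x) >= ao.bitscore(x, y)

    def test_empty_sequence_scores_zero(self):
        assert ao.bitscore("", "MKL") == 0.0


class TestPairDistance:
    def test_equals_componentwise_sum(self):
        rng = np.random.default_rng(2)
        p = ao.DockingPair(tail_seq=fx._random_protein(rng, 50),
                           head_seq=fx._random_protein(rng, 100), id="p")
        q = ao.DockingPair(tail_seq=fx._random_protein(rng, 50),
                           head_seq=fx._random_protein(rng, 100), id="q")
        expected = ao.bitscore(p.head_seq, q.head_seq) + \
            ao.bitscore(p.tail_seq, q.tail_seq)
        assert ao.pair_distance(p, q) == pytest.approx(expected)
        assert ao.pair_distance(q, p) == pytest.approx(expected)


class TestPnnFeatures:
    @pytest.fixture(scope="class")
    def training(self):
        return fx.make_docking_training(per_family=1, seed=9)

    def test_per_score_mode_gives_4n_features(self, training):
        q = training[0]
        feats = ao.pnn_features(q, training, ao.NeighborConfig(n=3, feature_mode="per_score"))
        assert feats.shape == (12,)

    def test_summed_mode_gives_2n_features(self, training):
        q = training[0]
        feats = ao.pnn_features(q, training, ao.NeighborConfig(n=3, feature_mode="summed"))
        assert feats.shape == (6,)

    def test_identical_positive_is_own_top_neighbor(self, training):
        q = training[0]  # a positive pair
        ranked = sorted(
            (p for p in training if p.label),
            key=lambda p: -ao.pair_distance(q, p),
        )
        assert ranked[0].id == q.id

    def test_insufficient_class_errors(self, training):
        pos_only = [p for p in training if p.label]
        with pytest.raises(ao.AssemblyError, match="non-interacting"):
            ao.pnn_features(pos_only[0], pos_only, ao.NeighborConfig(n=2))


class TestInteractionModel:
    def test_balanced_subsample_equals_positive_count(self):
        pairs = fx.make_docking_training(per_family=2, seed=4)
        extra_neg = fx.make_docking_training(per_family=2, seed=8)
        pairs = pairs + [p for p in extra_neg if not p.label]
        n_pos = sum(1 for p in pairs if p.label)
        model = ao.train_interaction_model(pairs, seed=0)
        assert sum(1 for p in model.training if not p.label) == n_pos

    def test_probability_in_open_interval(self, interaction_model):
        rng = np.random.default_rng(3)
        q = ao.DockingPair(tail_seq=fx._random_protein(rng, 50),
                           head_seq=fx._random_protein(rng, 100), id="q")
        p = interaction_model.predict_proba(q)
        assert 0.0 < p < 1.0

    def test_single_class_rejected(self):
        pairs = [p for p in fx.make_docking_training(seed=4) if p.label]
        with pytest.raises(ao.AssemblyError, match="both"):
            ao.train_interaction_model(pairs)

    def test_held_out_cognate_vs_noncognate_separated(self, interaction_model):
        rng = np.random.default_rng(17)
        cognate, noncognate = [], []
        for fam in range(6):
            t, h = fx._connector(fam)
            _, h_other = fx._connector(fam + 3)
            cognate.append(interaction_model.predict_proba(ao.DockingPair(
                tail_seq=fx._random_protein(rng, 38) + t,
                head_seq=h + fx._random_protein(rng, 88), id="c")))
            noncognate.append(interaction_model.predict_proba(ao.DockingPair(
                tail_seq=fx._random_protein(rng, 38) + t,
                head_seq=h_other + fx._random_protein(rng, 88), id="n")))
        assert min(cognate) > max(noncognate)


class TestScorePathway:
    def _three_gene_bgc(self):
        return _bgc(3)

    def test_unit_weights_collapse_to_plain_sum(self):
        bgc = self._three_gene_bgc()
        scores = {("g0", "g1"): 0.9, ("g1", "g2"): 0.8}
        total = ao.score_pathway(["g0", "g1", "g2"], scores, bgc)
        assert total == pytest.approx(1.7)

    def test_forward_weight_applies_to_adjacent_pairs(self):
        bgc = self._three_gene_bgc()
        scores = {("g0", "g1"): 0.9, ("g1", "g2"): 0.8}
        # g0-g1 and g1-g2 are both forward-adjacent; hand evaluation with
        # w_forward=2 doubles both terms of the first example's sum
        total = ao.score_pathway(
            ["g0", "g1", "g2"], scores, bgc,
            ao.PathwayScoreParams(w_forward=2.0),
        )
        assert total == pytest.approx(2 * 0.9 + 2 * 0.8)

    def test_backward_and_nonadjacent_classes(self):
        bgc = self._three_gene_bgc()
        scores = {("g2", "g0"): 0.5, ("g0", "g1"): 0.9, ("g1", "g0"): 0.4}
        # order g1-g0: backward-adjacent; order g2-g0: non-adjacent
        assert ao.score_pathway(
            ["g1", "g0"], scores, bgc, ao.PathwayScoreParams(w_backward=3.0)
        ) == pytest.approx(1.2)
        assert ao.score_pathway(
            ["g2", "g0"], scores, bgc, ao.PathwayScoreParams(w_backward=3.0)
        ) == pytest.approx(0.5)

    def test_single_gene_scores_zero(self):
        bgc = _bgc(1)
        assert ao.score_pathway(["g0"], {}, bgc) == 0.0

    def test_missing_pair_score_errors(self):
        bgc = self._three_gene_bgc()
        with pytest.raises(ao.AssemblyError, match="missing pair score"):
            ao.score_pathway(["g0", "g2"], {}, bgc)

    def test_unit_weight_identity_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            bgc = _bgc(n)
            ids = bgc.gene_ids
            scores = {
                (a, b): float(rng.random())
                for a in ids for b in ids if a != b
            }
            perm = list(rng.permutation(ids))
            plain = sum(scores[(a, b)] for a, b in zip(perm, perm[1:]))
            assert ao.score_pathway(perm, scores, bgc) == pytest.approx(plain)


class TestRankPathways:
    def _random_scores(self, ids, rng):
        return {
            (a, b): float(rng.random()) for a in ids for b in ids if a != b
        }

    @pytest.mark.parametrize("g, expected", [(4, 24), (6, 720), (7, 5040)])
    def test_candidate_count_is_factorial(self, g, expected):
        rng = np.random.default_rng(g)
        bgc = _bgc(g)
        result = ao.rank_pathways(
            bgc, pair_score=self._random_scores(bgc.gene_ids, rng), cap=5
        )
        assert result.n_candidates == expected == math.factorial(g)

    def test_orders_sorted_descending_with_lexicographic_ties(self):
        bgc = _bgc(3)
        scores = {pair: 0.5 for pair in
                  itertools.permutations(bgc.gene_ids, 2)}
        result = ao.rank_pathways(bgc, pair_score=scores, cap=6)
        perms = [o.permutation for o in result.orders]
        assert perms == sorted(perms)  # all tied: pure lexicographic

    def test_branch_and_bound_matches_exhaustive(self):
        rng = np.random.default_rng(33)
        for g in (3, 4, 5, 6, 7):
            bgc = _bgc(g)
            scores = self._random_scores(bgc.gene_ids, rng)
            cap = 10
            ex = ao.rank_pathways(bgc, pair_score=scores, cap=cap,
                                  exhaustive_limit=9)
            bb = ao.rank_pathways(bgc, pair_score=scores, cap=cap,
                                  exhaustive_limit=0)
            assert [o.permutation for o in ex.orders] == \
                [o.permutation for o in bb.orders]
            for a, b in zip(ex.orders, bb.orders):
                assert a.score == pytest.approx(b.score)

    def test_score_invariant_under_gene_relabeling(self):
        rng = np.random.default_rng(44)
        bgc1 = _bgc(4)
        scores1 = self._random_scores(bgc1.gene_ids, rng)
        rename = {"g0": "zz", "g1": "aa", "g2": "mm", "g3": "kk"}
        genes2 = [
            Gene(id=rename[g.id], protein=g.protein,
                 genomic_rank=g.genomic_rank)
            for g in bgc1.genes
        ]
        bgc2 = BGC(genes=genes2)
        scores2 = {
            (rename[a], rename[b]): s for (a, b), s in scores1.items()
        }
        r1 = ao.rank_pathways(bgc1, pair_score=scores1, cap=1)
        r2 = ao.rank_pathways(bgc2, pair_score=scores2, cap=1)
        assert r1.orders[0].score == pytest.approx(r2.orders[0].score)
        assert [rename[g] for g in r1.orders[0].permutation] == \
            r2.orders[0].permutation

    def test_cap_below_one_rejected(self):
        with pytest.raises(ao.AssemblyError, match="cap"):
            ao.rank_pathways(_bgc(2), pair_score={}, cap=0)

    def test_planted_order_recovered(self, interaction_model):
        spec = fx.FixtureSpec(seed=0, n_genes=4, modules_per_gene=1,
                              planted_order=(2, 0, 3, 1))
        bgc, truth = fx.make_bgc(spec)
        result = ao.rank_pathways(bgc, model=interaction_model)
        assert result.orders[0].permutation == truth["planted_order"]
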