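"""Similarity matrices, profiles, rank curves, thresholds, top-k, sweeps."""

import numpy as np
import pytest

from metmaxstruct import (
    SimilarityMatrix,
    SimilarityProfile,
    TverskyParams,
    bit_counts,
    cumulative_curve,
    fraction_exceeding,
    max_profile,
    named_hits_above,
    random_collection,
    similarity_matrix,
    sweep,
    top_k_hits,
    tversky,
)
from metmaxstruct.compare import _streamed_profile

P = TverskyParams(0.3, 0.7)
TANIMOTO = TverskyParams(1.0, 1.0)


def profile_of(values, params=TANIMOTO):
    n = len(values)
    return SimilarityProfile(
        [f"q{i}" for i in range(n)], np.array(values), [""] * n, params
    )


class TestSimilarityMatrix:
    def test_cells_match_scalar_oracle(self):
        queries = random_collection(5, seed=11, id_prefix="q")
        targets = random_collection(7, seed=22, id_prefix="t")
        m = similarity_matrix(queries, targets, P)
        for i in range(5):
            for j in range(7):
                expect = tversky(
                    bit_counts(queries.fingerprint(i), targets.fingerprint(j)), P
                )
                assert m.values[i, j] == pytest.approx(expect, abs=1e-15)

    def test_self_comparison_unit_diagonal(self):
        coll = random_collection(6, density=0.4, seed=3)
        m = similarity_matrix(coll, coll, TANIMOTO)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)

    def test_transpose_exchange(self):
        queries = random_collection(4, seed=5, id_prefix="q")
        targets = random_collection(6, seed=6, id_prefix="t")
        m = similarity_matrix(queries, targets, P)
        mt = similarity_matrix(targets, queries, P.swapped())
        assert np.allclose(m.values, mt.values.T, atol=1e-15)

    def test_empty_collection_rejected(self):
        coll = random_collection(3, seed=1)
        with pytest.raises(ValueError):
            SimilarityMatrix(["a"], ["b"], np.array([[1.5]]), P)
        with pytest.raises(ValueError):
            similarity_matrix(coll.subset([]), coll, P)


class TestMaxProfile:
    def test_tie_broken_by_earliest_target(self):
        m = SimilarityMatrix(
            ["q"], ["t1", "t2", "t3"], np.array([[0.2, 0.9, 0.9]]), TANIMOTO
        )
        prof = max_profile(m)
        assert prof.max_similarity[0] == 0.9
        assert prof.best_target_id == ["t2"]

    def test_identical_twin_gives_unit_max(self):
        coll = random_collection(5, density=0.4, seed=9)
        m = similarity_matrix(coll.subset([2]), coll, TANIMOTO)
        prof = max_profile(m)
        assert prof.max_similarity[0] == 1.0
        assert prof.best_target_id[0] == coll.ids[2]

    def test_argmax_agrees_with_exhaustive_scan(self, rng):
        vals = rng.random((50, 80))
        m = SimilarityMatrix(
            [f"q{i}" for i in range(50)], [f"t{j}" for j in range(80)], vals, P
        )
        prof = max_profile(m)
        for i in range(50):
            best_j, best_v = 0, -1.0
            for j in range(80):
                if vals[i, j] > best_v:
                    best_j, best_v = j, vals[i, j]
            assert prof.max_similarity[i] == best_v
            assert prof.best_target_id[i] == f"t{best_j}"

    def test_streamed_profile_equals_matrix_profile(self):
        queries = random_collection(300, seed=41, id_prefix="q")
        targets = random_collection(70, seed=42, id_prefix="t")
        streamed = _streamed_profile(queries, targets, P)
        full = max_profile(similarity_matrix(queries, targets, P))
        assert np.array_equal(streamed.max_similarity, full.max_similarity)
        assert streamed.best_target_id == full.best_target_id


class TestCumulativeCurve:
    def test_sorted_descending_with_rank_fractions(self):
        curve = cumulative_curve(profile_of([0.3, 0.9, 0.6]))
        assert list(curve["similarity"]) == [0.9, 0.6, 0.3]
        assert list(curve["rank_fraction"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_constant_profile_is_flat(self):
        curve = cumulative_curve(profile_of([0.4] * 5))
        assert (curve["similarity"] == 0.4).all()

    def test_nested_targets_order_curves_pointwise(self):
        queries = random_collection(30, seed=7, id_prefix="q")
        targets = random_collection(60, seed=8, id_prefix="t")
        small = max_profile(similarity_matrix(queries, targets.subset(range(20)), P))
        big = max_profile(similarity_matrix(queries, targets, P))
        c_small = cumulative_curve(small)["similarity"].to_numpy()
        c_big = cumulative_curve(big)["similarity"].to_numpy()
        assert (c_big >= c_small - 1e-15).all()
        # and per query, adding targets never lowers any max
        assert (big.max_similarity >= small.max_similarity - 1e-15).all()


class TestFractionExceeding:
    def test_strict_inequality_at_threshold(self):
        assert fraction_exceeding(profile_of([0.81, 0.80, 0.79]), 0.8) == pytest.approx(
            1 / 3
        )

    def test_zero_threshold_counts_all_positive_maxima(self):
        assert fraction_exceeding(profile_of([0.5, 0.2, 0.9]), 0.0) == 1.0

    def test_non_increasing_in_threshold(self, rng):
        prof = profile_of(rng.random(200))
        fracs = [fraction_exceeding(prof, t) for t in np.linspace(0, 1, 41)]
        assert all(x >= y for x, y in zip(fracs, fracs[1:]))
        # strict-exceedance = 1 - ECDF(t)
        for t in (0.25, 0.5, 0.75):
            ecdf = np.mean(prof.max_similarity <= t)
            assert fraction_exceeding(prof, t) == pytest.approx(1 - ecdf)

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fraction_exceeding(profile_of([0.5]), 1.2)


class TestTopK:
    def test_full_ranking_when_k_is_collection_size(self):
        targets = random_collection(12, seed=13, id_prefix="t")
        query = random_collection(1, seed=14).fingerprint(0)
        hits = top_k_hits(query, targets, P, k=12)
        assert len(hits) == 12
        sims = [s for _, s in hits]
        assert sims == sorted(sims, reverse=True)
        assert {t for t, _ in hits} == set(targets.ids)

    def test_agrees_with_sort_then_truncate_oracle(self):
        targets = random_collection(25, seed=15, id_prefix="t")
        query = random_collection(1, seed=16).fingerprint(0)
        row = [
            (tid, tversky(bit_counts(query, targets.fingerprint(j)), P))
            for j, tid in enumerate(targets.ids)
        ]
        oracle = sorted(row, key=lambda x: -x[1])[:3]
        got = top_k_hits(query, targets, P, k=3)
        assert [t for t, _ in got] == [t for t, _ in oracle]
        assert [s for _, s in got] == pytest.approx([s for _, s in oracle], abs=1e-15)

    def test_k1_consistent_with_max_profile(self):
        queries = random_collection(8, seed=17, id_prefix="q")
        targets = random_collection(20, seed=18, id_prefix="t")
        prof = max_profile(similarity_matrix(queries, targets, P))
        for i in range(8):
            [(tid, s)] = top_k_hits(queries.fingerprint(i), targets, P, k=1)
            assert tid == prof.best_target_id[i]
            assert s == prof.max_similarity[i]

    def test_k_larger_than_collection_returns_all(self):
        targets = random_collection(4, seed=19)
        query = targets.fingerprint(0)
        assert len(top_k_hits(query, targets, P, k=99)) == 4

    def test_errors(self):
        targets = random_collection(4, seed=19)
        with pytest.raises(ValueError):
            top_k_hits(targets.fingerprint(0), targets, P, k=0)


class TestSweep:
    def test_tanimoto_grid_point_matches_tanimoto_profile(self):
        queries = random_collection(10, seed=21, id_prefix="q")
        targets = random_collection(15, seed=22, id_prefix="t")
        from metmaxstruct import alpha_grid

        result = sweep(queries, targets, alpha_grid("sum2", 11))
        at_tanimoto = result.profile_for(TANIMOTO)
        direct = max_profile(similarity_matrix(queries, targets, TANIMOTO))
        assert np.array_equal(at_tanimoto.max_similarity, direct.max_similarity)
        assert at_tanimoto.best_target_id == direct.best_target_id

    def test_single_point_grid_reduces_to_one_analysis(self):
        queries = random_collection(5, seed=23)
        result = sweep(queries, queries, [TANIMOTO], keep_matrices=True)
        assert len(result.profiles) == 1
        assert np.allclose(np.diag(result.matrices[0].values), 1.0)

    def test_planted_sub_superset_pairs_favor_alpha_extremes(self):
        # half the targets are strict key-subsets of their query (rewarded at
        # alpha=0, the substructure reading) and half strict supersets
        # (rewarded at alpha=1, beta=0), so the sum1 grid extremes dominate
        # its middle
        from metmaxstruct import Collection, MoleculeRecord, alpha_grid

        rng = np.random.default_rng(77)
        qmat = (rng.random((12, 166)) < 0.4).astype(np.uint8)
        tmat = qmat.copy()
        for row in tmat[:6]:  # drop half the on-bits -> strict subset
            on = np.flatnonzero(row)
            row[rng.choice(on, size=on.size // 2, replace=False)] = 0
        for row in tmat[6:]:  # set half the off-bits -> strict superset
            off = np.flatnonzero(row == 0)
            row[rng.choice(off, size=off.size // 2, replace=False)] = 1
        mk = lambda tag, m: Collection(
            [MoleculeRecord(f"{tag}{i}", "", 100.0, tag) for i in range(len(m))],
            m,
            "synthetic",
        )
        result = sweep(mk("q", qmat), mk("t", tmat), alpha_grid("sum1", 11))
        means = [p.max_similarity.mean() for p in result.profiles]
        assert means[0] >= means[5]
        assert means[-1] >= means[5]
        # every subset-planted query is a perfect hit at alpha=0, every
        # superset-planted query at alpha=1
        assert (result.profiles[0].max_similarity[:6] == 1.0).all()
        assert (result.profiles[-1].max_similarity[6:] == 1.0).all()

    def test_collection_level_exchange_property(self):
        queries = random_collection(6, seed=31, id_prefix="q")
        targets = random_collection(9, seed=32, id_prefix="t")
        m = similarity_matrix(queries, targets, P)
        mt = similarity_matrix(targets, queries, P.swapped())
        assert sorted(m.values.ravel()) == pytest.approx(
            sorted(mt.values.ravel()), abs=1e-15
        )

    def test_exclude_self_picks_nearest_other(self):
        coll = random_collection(6, density=0.4, seed=33)
        prof = _streamed_profile(coll, coll, TANIMOTO, exclude_self=True)
        assert all(q != t for q, t in zip(prof.query_ids, prof.best_target_id))
        assert (prof.max_similarity < 1.0).all()


class TestNamedHits:
    def test_planted_identical_pair_at_unit_threshold(self):
        targets = random_collection(10, density=0.4, seed=35, id_prefix="t")
        queries = targets.subset([4])
        hits = named_hits_above(queries, targets, TANIMOTO, 1.0)
        assert hits == [(targets.ids[4], targets.ids[4], 1.0)]

    def test_zero_threshold_lists_every_query_once(self):
        queries = random_collection(7, seed=36, id_prefix="q")
        targets = random_collection(9, seed=37, id_prefix="t")
        hits = named_hits_above(queries, targets, P, 0.0)
        assert sorted(q for q, _, _ in hits) == sorted(queries.ids)
        sims = [s for _, _, s in hits]
        assert sims == sorted(sims, reverse=True)

    def test_is_restriction_of_max_profile(self):
        queries = random_collection(20, seed=38, id_prefix="q")
        targets = random_collection(30, seed=39, id_prefix="t")
        prof = max_profile(similarity_matrix(queries, targets, P))
        thresh = float(np.median(prof.max_similarity))
        hits = named_hits_above(queries, targets, P, thresh)
        expect = {
            (q, t, s)
            for q, t, s in zip(prof.query_ids, prof.best_target_id, prof.max_similarity)
            if s >= thresh
        }
        assert {(q, t, round(s, 12)) for q, t, s in hits} == {
            (q, t, round(s, 12)) for q, t, s in expect
        }
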