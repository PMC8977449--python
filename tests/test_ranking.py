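import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painnma.nma_engine import ModelSpec, fit
from painnma.ranking import (
    HIGHER_BETTER,
    LOWER_BETTER,
    RankingResult,
    heatmap,
    rank_probs,
    rank_treatments,
    sucra,
)


def brute_force_rank_probs(draws, direction=LOWER_BETTER):
    """Explicit per-draw recount oracle: argsort each draw, tally ranks.

    Ties share averaged ranks, split between the adjacent integer bins.
    """
    x = np.asarray(draws, dtype=float)
    if direction == HIGHER_BETTER:
        x = -x
    n, T = x.shape
    probs = np.zeros((T, T))
    for row in x:
        order = sorted(range(T), key=lambda i: row[i])
        ranks = [0.0] * T
        i = 0
        while i < T:
            j = i
            while j + 1 < T and row[order[j + 1]] == row[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1  # average of ranks i+1..j+1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        for t, r in enumerate(ranks):
            lo = int(np.floor(r))
            frac = r - lo
            probs[t, lo - 1] += 1 - frac
            if frac > 0:
                probs[t, lo] += frac
    return probs / n


@pytest.fixture(scope="module")
def posterior_draws():
    rng = np.random.default_rng(123)
    centers = np.array([0.0, -0.8, -0.4, 0.3])
    return centers + 0.5 * rng.standard_normal((1000, 4))


class TestRankProbs:
    def test_degenerate_two_treatments(self):
        draws = np.column_stack([np.full(500, -1.0), np.full(500, 1.0)])
        p = rank_probs(draws, LOWER_BETTER)
        assert p[0, 0] == 1.0 and p[1, 1] == 1.0
        s, mr = sucra(p)
        assert s[0] == 1.0 and s[1] == 0.0

    def test_rows_and_columns_sum_to_one(self, posterior_draws):
        p = rank_probs(posterior_draws)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, posterior_draws):
        p = rank_probs(posterior_draws)
        oracle = brute_force_rank_probs(posterior_draws)
        assert np.allclose(p, oracle, atol=1e-12)

    def test_tie_handling_matches_oracle(self):
        draws = np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 1.0], [0.5, 0.2, 0.2]])
        p = rank_probs(draws)
        oracle = brute_force_rank_probs(draws)
        assert np.allclose(p, oracle, atol=1e-12)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_two_seeds_agree_within_mc_noise(self):
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        centers = np.array([0.0, -0.5, -0.25])
        n = 4000
        p1 = rank_probs(centers + 0.4 * rng1.standard_normal((n, 3)))
        p2 = rank_probs(centers + 0.4 * rng2.standard_normal((n, 3)))
        bound = 2 * np.sqrt(np.maximum(p1 * (1 - p1), 0.25 / n) / n) * 2 + 4 / n
        assert np.all(np.abs(p1 - p2) <= np.maximum(bound, 0.05))


class TestSucra:
    def test_uniform_matrix(self):
        T = 5
        p = np.full((T, T), 1.0 / T)
        s, mr = sucra(p)
        assert np.allclose(s, 0.5)
        assert np.allclose(mr, (T + 1) / 2)

    def test_always_last_treatment(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        s, _ = sucra(p)
        assert s[1] == 0.0

    def test_sucra_equals_mean_rank_identity(self, posterior_draws):
        p = rank_probs(posterior_draws)
        s, mr = sucra(p)
        T = p.shape[0]
        assert np.allclose(s, (T - mr) / (T - 1), atol=1e-12)

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_sum_identity_on_random_matrices(self, T, seed):
        # random doubly stochastic-ish matrix via draw ranking
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((200, T))
        s, _ = sucra(rank_probs(draws))
        assert float(s.sum()) == pytest.approx(T / 2, abs=1e-9)

    def test_direction_flip_complements(self, posterior_draws):
        s1, _ = sucra(rank_probs(posterior_draws, LOWER_BETTER))
        s2, _ = sucra(rank_probs(posterior_draws, HIGHER_BETTER))
        assert np.allclose(s1 + s2, 1.0, atol=1e-12)

    def test_relabeling_invariance(self, posterior_draws):
        perm = [2, 0, 3, 1]
        s1, _ = sucra(rank_probs(posterior_draws))
        s2, _ = sucra(rank_probs(posterior_draws[:, perm]))
        assert np.allclose(s1[perm], s2, atol=1e-12)


class TestRankTreatments:
    def test_from_posterior(self, triangle_ds):
        post = fit(triangle_ds, "pain4w", ModelSpec(burn_in=800, samples=2400, seed=31))
        res = rank_treatments(post, LOWER_BETTER)
        assert res.treatments == post.treatment_ids
        # drug01 (true -0.5) should outrank placebo
        i_drug = res.treatments.index("drug01")
        i_pla = res.treatments.index("placebo")
        assert res.sucra[i_drug] > res.sucra[i_pla]


def _result(outcome, treatments, sucras):
    T = len(treatments)
    return RankingResult(
        outcome_id=outcome,
        direction=LOWER_BETTER,
        treatments=tuple(treatments),
        rank_probs=np.full((T, T), 1.0 / T),
        sucra=np.asarray(sucras, dtype=float),
        mean_rank=np.asarray([T - s * (T - 1) for s in sucras]),
    )


class TestHeatmap:
    def test_overall_mean(self):
        hm = heatmap(
            [_result("pain4w", ["A", "B"], [0.9, 0.1]),
             _result("pain8w", ["A", "B"], [0.7, 0.3])]
        )
        assert hm.overall["A"] == pytest.approx(0.8)
        assert hm.treatments[0] == "A"

    def test_missing_cell_stays_na(self):
        hm = heatmap(
            [_result("pain4w", ["A", "B", "C"], [0.9, 0.5, 0.1]),
             _result("serious_ae", ["A", "B"], [0.2, 0.8])]
        )
        assert np.isnan(hm.sucra.loc["serious_ae", "C"])
        assert hm.overall["C"] == pytest.approx(0.1)  # mean over available only

    def test_single_outcome_order_matches_sucra(self):
        hm = heatmap([_result("pain4w", ["A", "B", "C"], [0.3, 0.9, 0.6])])
        assert list(hm.treatments) == ["B", "C", "A"]
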