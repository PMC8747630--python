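"""Activation equation, threshold retrieval, and the boost-help mechanism."""

import numpy as np
import pytest
from scipy import integrate, stats

from adlsim import (
    Chunk,
    DeclarativeMemory,
    MemoryParams,
    RetrievalStatus,
    SimilarityTable,
    UnknownChunkError,
    activation,
    boost,
    retrieve,
)


def logistic_win_prob(delta, scale):
    """P(eps2 - eps1 > delta) for iid logistic(0, scale) noise, by quadrature."""
    f = lambda x: stats.logistic.pdf(x, 0, scale) * stats.logistic.sf(x + delta, 0, scale)
    return integrate.quad(f, -np.inf, np.inf)[0]


def store(chunks, sims=None, assoc=()):
    return DeclarativeMemory(chunks, sims, assoc)


class TestActivation:
    @pytest.mark.parametrize(
        "base,sources,assoc,W,expected",
        [
            # one associated source: full spreading W * S
            (0.0, ["g"], [("g", "x")], 1.0, 2.0),
            # two sources, one associated: attentional weight is W/n = 1/2
            (0.0, ["g", "h"], [("g", "x")], 1.0, 1.0),
            # no sources at all: base level only
            (0.7, [], [], 1.0, 0.7),
        ],
    )
    def test_noise_free_spreading(self, rng, base, sources, assoc, W, expected):
        mem = store([Chunk("x", base_level=base), Chunk("g"), Chunk("h")], assoc=assoc)
        params = MemoryParams(W_total=W, S=2.0, noise_scale_act=0.0)
        assert activation("x", sources, mem, params, rng) == pytest.approx(expected)

    def test_partial_match_penalty_against_cue(self, rng):
        # base 0.5 plus one mismatching-cue penalty P*M = 1 * (-0.5)
        mem = store([Chunk("x", base_level=0.5), Chunk("cue")],
                    SimilarityTable([("x", "cue", -0.5)]))
        params = MemoryParams(P=1.0, noise_scale_act=0.0)
        assert activation("x", [], mem, params, rng, cue="cue") == pytest.approx(0.0)
        # the cue itself takes no penalty
        assert activation("cue", [], mem, params, rng, cue="cue") == pytest.approx(0.0)

    def test_unknown_chunk_raises(self, rng):
        mem = store([Chunk("x")])
        with pytest.raises(UnknownChunkError):
            activation("nope", [], mem, MemoryParams(), rng)

    def test_noise_is_zero_mean(self, rng):
        mem = store([Chunk("x", base_level=0.3)])
        params = MemoryParams(noise_scale_act=0.8)
        draws = np.array([activation("x", [], mem, params, rng) for _ in range(100_000)])
        sd = 0.8 * np.pi / np.sqrt(3)  # logistic SD
        assert abs(draws.mean() - 0.3) < 3 * sd / np.sqrt(draws.size)

    def test_gaussian_noise_option(self, rng):
        mem = store([Chunk("x")])
        params = MemoryParams(noise_scale_act=0.5, noise_dist="gaussian")
        draws = np.array([activation("x", [], mem, params, rng) for _ in range(20_000)])
        assert abs(draws.mean()) < 3 * 0.5 / np.sqrt(draws.size)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MemoryParams(W_total=0.0)
        with pytest.raises(ValueError):
            MemoryParams(noise_scale_act=-1.0)
        with pytest.raises(ValueError):
            MemoryParams(max_attempts=0)


class TestSimilarityTable:
    def test_symmetry_and_self_similarity(self):
        t = SimilarityTable([("a", "b", -0.4)])
        assert t.get("a", "b") == t.get("b", "a") == -0.4
        assert t.get("a", "a") == 0.0
        assert t.get("a", "zzz") is None

    def test_range_enforced(self):
        with pytest.raises(ValueError):
            SimilarityTable([("a", "b", 0.2)])
        with pytest.raises(ValueError):
            SimilarityTable([("a", "b", -1.5)])

    def test_most_similar_partner_is_largest_entry(self):
        t = SimilarityTable([("a", "b", -0.7), ("a", "c", -0.2)])
        assert t.most_similar_partner("a") == "c"

    def test_scaled_clips_to_valid_range(self):
        t = SimilarityTable([("a", "b", -0.8)]).scaled(2.0)
        assert t.get("a", "b") == -1.0


class TestRetrieve:
    def test_success_above_threshold(self, rng):
        mem = store([Chunk("x", base_level=2.0)])
        out = retrieve("x", [], mem, MemoryParams(threshold=0.0), rng)
        assert out.status is RetrievalStatus.SUCCESS and out.winner == "x"

    def test_omission_below_threshold(self, rng):
        mem = store([Chunk("x", base_level=-1.0)])
        out = retrieve("x", [], mem, MemoryParams(threshold=0.0), rng)
        assert out.status is RetrievalStatus.OMISSION and out.winner is None

    def test_commission_when_similar_item_wins(self, rng):
        # competitor noise-free activation beats the target's
        mem = store([Chunk("t", base_level=0.0), Chunk("c", base_level=2.0)],
                    SimilarityTable([("t", "c", -0.1)]))
        out = retrieve("t", [], mem, MemoryParams(P=1.0, threshold=-10.0), rng)
        assert out.status is RetrievalStatus.COMMISSION and out.winner == "c"

    def test_tie_breaks_toward_target(self, rng):
        mem = store([Chunk("t", base_level=1.0), Chunk("c", base_level=1.0)],
                    SimilarityTable([("t", "c", 0.0)]))
        out = retrieve("t", [], mem, MemoryParams(threshold=-10.0), rng)
        assert out.status is RetrievalStatus.SUCCESS

    def test_unknown_target_raises(self, rng):
        with pytest.raises(UnknownChunkError):
            retrieve("nope", [], store([Chunk("x")]), MemoryParams(), rng)

    def test_outcomes_mutually_exclusive_and_exhaustive(self, pair_memory):
        rng = np.random.default_rng(0)
        params = MemoryParams(P=1.0, noise_scale_act=0.6, threshold=0.8)
        seen = set()
        for _ in range(3000):
            out = retrieve("t", [], pair_memory, params, rng)
            seen.add(out.status)
        assert seen == {
            RetrievalStatus.SUCCESS,
            RetrievalStatus.OMISSION,
            RetrievalStatus.COMMISSION,
        }

    def test_commission_rate_matches_pairwise_win_probability(self, pair_memory):
        """Two-candidate retrieval vs the analytic logistic difference law."""
        s = 0.5
        params = MemoryParams(P=1.0, noise_scale_act=s, threshold=-50.0)
        # noise-free: target 1.0; competitor 1.2 + P*(-0.5) = 0.7
        expected = logistic_win_prob(1.0 - 0.7, s)
        rng = np.random.default_rng(7)
        n = 100_000
        hits = sum(
            retrieve("t", [], pair_memory, params, rng).status
            is RetrievalStatus.COMMISSION
            for _ in range(n)
        )
        margin = 3 * np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < margin

    def test_deterministic_given_stream_state(self, pair_memory):
        params = MemoryParams(P=1.0, noise_scale_act=0.6, threshold=0.5)
        a = [retrieve("t", [], pair_memory, params, np.random.default_rng(3)) for _ in range(1)]
        b = [retrieve("t", [], pair_memory, params, np.random.default_rng(3)) for _ in range(1)]
        assert a == b


class TestRetrievalMonotonicity:
    """Success probability responds monotonically to the core parameters."""

    N = 20_000

    def success_rate(self, base=1.0, W=1.0, threshold=1.0, seed=11):
        mem = store([Chunk("t", base_level=base), Chunk("g")], assoc=[("g", "t")])
        params = MemoryParams(W_total=W, noise_scale_act=0.7, threshold=threshold)
        rng = np.random.default_rng(seed)
        return (
            sum(
                retrieve("t", ["g"], mem, params, rng).status is RetrievalStatus.SUCCESS
                for _ in range(self.N)
            )
            / self.N
        )

    def test_monotone_in_base_level(self):
        assert self.success_rate(base=0.2) < self.success_rate(base=1.5)

    def test_monotone_in_attentional_weight(self):
        assert self.success_rate(W=0.4) < self.success_rate(W=1.6)

    def test_monotone_in_threshold(self):
        assert self.success_rate(threshold=2.2) < self.success_rate(threshold=0.2)


class TestBoost:
    def test_boost_raises_base_level_and_counts(self, rng):
        mem = store([Chunk("x", base_level=0.0)])
        boost("x", mem, 1.0)
        assert mem.chunk("x").base_level == 1.0 and mem.chunk("x").boost_count == 1
        boost("x", mem, 1.0)
        boost("x", mem, 1.0)
        assert mem.chunk("x").base_level == 3.0 and mem.chunk("x").boost_count == 3

    def test_boost_unknown_chunk_raises(self):
        with pytest.raises(UnknownChunkError):
            boost("nope", store([Chunk("x")]))

    def test_episode_reset_restores_base_levels(self):
        mem = store([Chunk("x", base_level=0.25)])
        boost("x", mem, 2.0)
        mem.reset_episode()
        assert mem.chunk("x").base_level == 0.25 and mem.chunk("x").boost_count == 0

    def test_boost_strictly_raises_success_probability(self):
        """One boost raises retrieval success odds (Monte-Carlo comparison)."""
        n = 100_000
        params = MemoryParams(noise_scale_act=0.7, threshold=1.0)

        def rate(boosted):
            mem = store([Chunk("t", base_level=0.5)])
            if boosted:
                boost("t", mem, 1.0)
            rng = np.random.default_rng(19)
            return (
                sum(
                    retrieve("t", [], mem, params, rng).status is RetrievalStatus.SUCCESS
                    for _ in range(n)
                )
                / n
            )

        margin = 3 * np.sqrt(0.5 / n)
        assert rate(True) > rate(False) + margin
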