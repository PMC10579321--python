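"""Consensus labels, classifiers, fusion, and Viterbi smoothing."""

import itertools

import numpy as np
import pytest

from somnoloop import (
    Hypnogram, TransitionModel, consensus_hypnogram, fit_transitions,
    fuse_realtime, smooth_offline, viterbi_path,
)
from somnoloop.signal_io import STAGES, UNSCORED
from somnoloop.staging import (N_STAGES, predict_primary, remove_islands,
                               train_primary)

# ---------------------------------------------------------------------------
# Consensus


def _brute_force_consensus(hyps):
    """Independent oracle: recompute pairwise agreements and voting by hand."""
    k, n = len(hyps), len(hyps[0])
    agree = []
    for i in range(k):
        tot = 0
        for j in range(k):
            if i != j:
                tot += sum(a == b for a, b in zip(hyps[i], hyps[j])) / n
        agree.append(tot / (k - 1))
    best = agree.index(max(agree))
    out = []
    for ep in range(n):
        votes = [h[ep] for h in hyps]
        top = max(votes.count(s) for s in set(votes))
        winners = sorted({s for s in votes if votes.count(s) == top},
                         key=votes.index)
        out.append(winners[0] if len(winners) == 1 else hyps[best][ep])
    return out


class TestConsensus:
    def test_majority(self):
        hyps = [Hypnogram(["W"] * 3), Hypnogram(["W", "W", "LS"]),
                Hypnogram(["LS", "W", "LS"])]
        assert consensus_hypnogram(hyps).stages == ["W", "W", "LS"]

    def test_unanimity(self):
        hyps = [Hypnogram(["LS"] * 4)] * 3
        assert consensus_hypnogram(hyps).stages == ["LS"] * 4

    @pytest.mark.parametrize("n_tech,seed", [(3, 0), (3, 5), (5, 1), (5, 9)])
    def test_matches_brute_force_oracle(self, n_tech, seed):
        rng = np.random.default_rng(seed)
        n = 20
        hyps = [Hypnogram([STAGES[i] for i in rng.integers(0, 4, n)])
                for _ in range(n_tech)]
        assert consensus_hypnogram(hyps).stages == _brute_force_consensus(hyps)

    def test_full_tie_uses_most_agreeing_technician(self):
        # A and B agree on 9/10 epochs; C disagrees everywhere.
        a = Hypnogram(["W"] * 9 + ["W"])
        b = Hypnogram(["W"] * 9 + ["LS"])
        c = Hypnogram(["DS"] * 9 + ["DS"])
        out = consensus_hypnogram([a, b, c])
        # epoch 9 votes (W, LS, DS): full tie -> technician A (max agreement,
        # lowest index among A/B which tie) -> "W"
        assert out.stages[9] == "W"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            consensus_hypnogram([Hypnogram(["W"]), Hypnogram(["W", "W"]),
                                 Hypnogram(["W"])])

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            consensus_hypnogram([Hypnogram(["W"]), Hypnogram(["W"])])


# ---------------------------------------------------------------------------
# Transition fitting


class TestTransitions:
    def test_counts_before_smoothing(self):
        tm = fit_transitions([Hypnogram(["W", "W", "LS", "LS"])], eps=0.0)
        assert tm.matrix[0, 0] == pytest.approx(0.5)
        assert tm.matrix[0, 1] == pytest.approx(0.5)

    def test_unseen_transition_zero_without_smoothing(self):
        tm = fit_transitions([Hypnogram(["W", "LS"])], eps=0.0)
        assert tm.matrix[0, 2] == 0.0

    def test_rows_sum_to_one_after_smoothing(self):
        tm = fit_transitions([Hypnogram(["W", "LS", "DS", "R", "W"])])
        assert np.allclose(tm.matrix.sum(axis=1), 1.0)

    def test_unscored_pairs_skipped(self):
        tm = fit_transitions([Hypnogram(["W", "U", "LS"])], eps=0.0)
        assert tm.matrix.sum() == 0.0  # no scored bigram at all


# ---------------------------------------------------------------------------
# Viterbi decoding


def _brute_force_path(emissions, tm):
    n = len(emissions)
    best, best_score = None, -np.inf
    for path in itertools.product(range(N_STAGES), repeat=n):
        score = np.log(tm.initial[path[0]]) + np.log(emissions[0][path[0]])
        for t in range(1, n):
            score += np.log(tm.matrix[path[t - 1], path[t]])
            score += np.log(emissions[t][path[t]])
        if score > best_score:
            best, best_score = path, score
    return np.array(best)


def _random_tm(rng):
    m = rng.uniform(0.05, 1.0, (4, 4))
    m /= m.sum(axis=1, keepdims=True)
    init = rng.uniform(0.05, 1.0, 4)
    return TransitionModel(matrix=m, initial=init / init.sum())


class TestViterbi:
    @pytest.mark.parametrize("n_epochs", [1, 2, 5, 8])
    def test_equals_exhaustive_enumeration(self, n_epochs):
        rng = np.random.default_rng(n_epochs)
        for _ in range(25):
            tm = _random_tm(rng)
            em = rng.uniform(0.01, 1.0, (n_epochs, 4))
            em /= em.sum(axis=1, keepdims=True)
            assert np.array_equal(viterbi_path(em, tm),
                                  _brute_force_path(em, tm))

    def test_one_hot_high_self_transition_returns_argmax(self):
        tm = TransitionModel(matrix=np.full((4, 4), 0.05) + np.eye(4) * 0.85,
                             initial=np.full(4, 0.25))
        labels = [0, 0, 1, 1, 2, 2]
        em = np.full((6, 4), 1e-6)
        for t, s in enumerate(labels):
            em[t, s] = 1.0
        assert list(viterbi_path(em, tm)) == labels


class TestSmoothing:
    tm = TransitionModel(matrix=np.full((4, 4), 0.05) + np.eye(4) * 0.85,
                         initial=np.full(4, 0.25))

    def _one_hot(self, labels):
        em = np.full((len(labels), 4), 0.01)
        for t, s in enumerate(labels):
            em[t, s] = 0.97
        return em

    def test_island_removed_by_rule_pass(self):
        # strong W,LS,W flanked pattern: LS island goes
        em = self._one_hot([0, 0, 1, 0, 0])
        out = smooth_offline(em, self.tm)
        assert out.stages == ["W"] * 5

    def test_unscored_epochs_all_scored(self):
        em = self._one_hot([0, 0, 1, 1, 1, 2, 2])
        em[3] = np.nan
        out = smooth_offline(em, self.tm)
        assert UNSCORED not in out.stages

    def test_no_single_epoch_islands_in_output(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            em = rng.uniform(0.01, 1, (30, 4))
            em /= em.sum(axis=1, keepdims=True)
            s = smooth_offline(em, self.tm).stages
            for i in range(1, len(s) - 1):
                assert not (s[i - 1] == s[i + 1] != s[i])

    def test_remove_islands_cascade(self):
        assert remove_islands(["W", "LS", "W", "LS", "W"]) == ["W"] * 5


# ---------------------------------------------------------------------------
# Fusion


def _dist_stream(labels):
    out = np.full((len(labels), 4), np.nan)
    for t, s in enumerate(labels):
        if s is not None:
            out[t] = 0.05
            out[t, s] = 0.85
    return out


class TestFusion:
    def test_all_primary(self):
        p = _dist_stream([0, 1, 1, 2])
        s = _dist_stream([3, 3, 3, 3])
        hyp, tags = fuse_realtime(p, s)
        assert hyp.stages == ["W", "LS", "LS", "DS"]
        assert tags == ["primary"] * 4

    def test_full_outage_uses_secondary_after_gap(self):
        n = 30
        p = _dist_stream([None] * n)
        s = _dist_stream([1] * n)
        hyp, tags = fuse_realtime(p, s, gap_min=5.0)
        assert tags[:10] == ["unscored"] * 10
        assert tags[10:] == ["secondary"] * 20
        assert all(x == "LS" for x in hyp.stages[10:])

    def test_mid_night_outage_epochs_beyond_gap(self):
        labels = [0] * 20 + [None] * 40 + [0] * 20
        p = _dist_stream(labels)
        s = _dist_stream([1] * 80)
        _, tags = fuse_realtime(p, s, gap_min=5.0)
        assert tags[20:30] == ["unscored"] * 10
        assert tags[30:60] == ["secondary"] * 30
        assert tags[60:] == ["primary"] * 20

    def test_causal_prefix_stability(self):
        rng = np.random.default_rng(1)
        labels = [None if rng.random() < 0.3 else int(rng.integers(4))
                  for _ in range(50)]
        p = _dist_stream(labels)
        s = _dist_stream([2] * 50)
        full_hyp, full_tags = fuse_realtime(p, s)
        for k in (1, 10, 25, 49):
            hk, tk = fuse_realtime(p[:k], s[:k])
            assert hk.stages == full_hyp.stages[:k]
            assert tk == full_tags[:k]

    def test_misaligned_streams_rejected(self):
        with pytest.raises(ValueError):
            fuse_realtime(_dist_stream([0] * 3), _dist_stream([0] * 4))


# ---------------------------------------------------------------------------
# Classifier contracts (fast, tiny synthetic feature problem)


def _toy_features(rng, n_per_class=60):
    """Linearly separable 4-class toy problem in feature space."""
    from somnoloop.features import FEATURE_NAMES
    f = len(FEATURE_NAMES)
    X, y = [], []
    for c in range(4):
        mu = np.zeros(f)
        mu[c] = 3.0
        X.append(rng.normal(mu, 1.0, (n_per_class, f)))
        y.append(np.full(n_per_class, c))
    return np.vstack(X), np.concatenate(y)


class TestClassifierContracts:
    def test_missing_stage_named_in_error(self):
        rng = np.random.default_rng(0)
        X, y = _toy_features(rng)
        keep = y != 2
        with pytest.raises(ValueError, match="DS"):
            train_primary(X[keep], y[keep])

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        X, y = _toy_features(rng)
        m1 = train_primary(X, y, seed=7)
        m2 = train_primary(X, y, seed=7)
        assert np.array_equal(m1.coef, m2.coef)
        p1 = predict_primary(m1, X)
        p2 = predict_primary(m2, X)
        assert np.array_equal(p1, p2)

    def test_probabilities_normalized_and_unscored_routed(self):
        rng = np.random.default_rng(1)
        X, y = _toy_features(rng)
        m = train_primary(X, y)
        usable = np.ones(len(X), dtype=bool)
        usable[5] = False
        p = predict_primary(m, X, usable)
        assert np.isnan(p[5]).all()
        ok = ~np.isnan(p).any(axis=1)
        assert np.allclose(p[ok].sum(axis=1), 1.0, atol=1e-9)

    def test_schema_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        X, y = _toy_features(rng)
        m = train_primary(X, y)
        with pytest.raises(ValueError, match="schema"):
            m.predict_proba(X[:, :10])

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        X, y = _toy_features(rng)
        m = train_primary(X, y)
        path = tmp_path / "pml.json"
        m.save(path)
        back = m.load(path)
        assert back.schema_hash == m.schema_hash
        assert np.allclose(back.predict_proba(X), m.predict_proba(X))
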