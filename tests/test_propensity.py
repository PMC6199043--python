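import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtopo import propensity, seqio
from memtopo.errors import ConfigError, InputError, TrainingError
from memtopo.propensity import (
    MassAssignment,
    OetknnModel,
    PropensityTrack,
    WindowConfig,
    classify,
    classify_batch,
    combine_masses,
    pignistic_tmh,
    predict_propensity,
    train_oetknn,
    window_feature_matrix,
    window_features,
)

from conftest import random_profile


# ---------------------------------------------------------------------------
# independent Dempster oracle: exhaustive focal-set enumeration
# ---------------------------------------------------------------------------

def dempster_oracle(neighbor_masses):
    """Enumerate all 3^k focal-set products of k two-class assignments.

    Each assignment is (m_tmh, m_non, m_theta).  Focal sets are
    {T}, {N}, Theta; an intersection product lands on the intersection
    of the chosen focal sets, or is conflict when empty.  Returns the
    pignistic TMH probability.
    """
    FOCALS = ("T", "N", "TH")

    def intersect(a, b):
        if a == "TH":
            return b
        if b == "TH":
            return a
        return a if a == b else None

    accum = {"T": 0.0, "N": 0.0, "TH": 0.0}
    conflict = 0.0
    k = len(neighbor_masses)
    for combo in itertools.product(range(3), repeat=k):
        weight = 1.0
        focal = "TH"
        for mass, choice in zip(neighbor_masses, combo):
            weight *= mass[choice]
            focal = intersect(focal, FOCALS[choice]) if focal is not None else None
        if focal is None:
            conflict += weight
        else:
            accum[focal] += weight
    norm = 1.0 - conflict
    m_t, m_th = accum["T"] / norm, accum["TH"] / norm
    return m_t + 0.5 * m_th


def neighbor_mass(label, d2, alpha0, gamma):
    m = alpha0 * np.exp(-gamma * d2)
    return (m, 0.0, 1.0 - m) if label == 1 else (0.0, m, 1.0 - m)


def make_model(X, y, k=3, alpha0=0.95, g_t=1.0, g_n=1.0):
    return OetknnModel(reference_vectors=X, labels=y, k=k, alpha0=alpha0,
                       gamma_tmh=g_t, gamma_non=g_n)


# ---------------------------------------------------------------------------
# window features
# ---------------------------------------------------------------------------

class TestWindowFeatures:
    def test_interior_no_padding(self, rng):
        prof = random_profile(rng, 20)
        v = window_features(prof, 10, 13)
        assert v.shape == (260,)
        assert np.allclose(v, prof.scaled[3:16].ravel())

    def test_terminal_padding(self, rng):
        prof = random_profile(rng, 20)
        v = window_features(prof, 1, 13).reshape(13, 20)
        assert np.allclose(v[:6], 0.5)
        assert np.allclose(v[6:], prof.scaled[:7])

    def test_identical_contexts_identical_vectors(self, rng):
        block = rng.normal(size=(13, 20))
        raw = np.vstack([block, rng.normal(size=(5, 20)), block])
        prof = seqio.Profile(record_id="r", raw=raw)
        assert np.array_equal(window_features(prof, 7, 13),
                              window_features(prof, 25, 13))

    def test_even_window_rejected(self, rng):
        with pytest.raises(ConfigError):
            window_features(random_profile(rng, 10), 3, 12)

    def test_position_out_of_range(self, rng):
        with pytest.raises(InputError):
            window_features(random_profile(rng, 10), 11, 5)

    def test_matrix_agrees_with_single(self, rng):
        prof = random_profile(rng, 17)
        M = window_feature_matrix(prof, 9)
        for i in range(1, 18):
            assert np.allclose(M[i - 1], window_features(prof, i, 9))


# ---------------------------------------------------------------------------
# mass combination / classify
# ---------------------------------------------------------------------------

class TestCombineMasses:
    def test_single_certain_tmh_neighbor(self):
        # k=1, d=0, alpha0=0.95 -> 0.95 + 0.05/2 = 0.975
        m = MassAssignment(m_tmh=0.95, m_non=0.0, m_theta=0.05)
        assert pignistic_tmh(combine_masses([m])) == pytest.approx(0.975)

    def test_symmetric_neighbors_give_half(self):
        a = MassAssignment(m_tmh=0.6, m_non=0.0, m_theta=0.4)
        b = MassAssignment(m_tmh=0.0, m_non=0.6, m_theta=0.4)
        assert pignistic_tmh(combine_masses([a, b])) == pytest.approx(0.5)

    def test_matches_oracle_k3(self, rng):
        for _ in range(50):
            masses = []
            tuples = []
            for _k in range(3):
                lab = int(rng.integers(2))
                m = float(rng.uniform(0, 0.95))
                tuples.append(neighbor_mass(lab, 0.0, m, 0.0))
                mt, mn, mth = tuples[-1]
                masses.append(MassAssignment(m_tmh=mt, m_non=mn, m_theta=mth))
            assert pignistic_tmh(combine_masses(masses)) == pytest.approx(
                dempster_oracle(tuples), abs=1e-12
            )

    @given(st.permutations(range(4)), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_order_invariance(self, perm, seed):
        rng = np.random.default_rng(seed)
        masses = []
        for _ in range(4):
            lab = int(rng.integers(2))
            m = float(rng.uniform(0, 0.9))
            masses.append(MassAssignment(
                m_tmh=m if lab else 0.0, m_non=0.0 if lab else m, m_theta=1 - m))
        base = pignistic_tmh(combine_masses(masses))
        shuffled = [masses[i] for i in perm]
        assert pignistic_tmh(combine_masses(shuffled)) == pytest.approx(base, abs=1e-12)


class TestClassify:
    def test_zero_distance_tmh_neighbor(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([1, 0])
        model = make_model(X, y, k=1, g_t=1.0, g_n=1.0)
        assert classify(model, np.zeros(2)) == pytest.approx(0.975, abs=1e-9)

    def test_equidistant_opposite_neighbors(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, 0])
        model = make_model(X, y, k=2)
        assert classify(model, np.zeros(2)) == pytest.approx(0.5, abs=1e-12)

    def test_matches_oracle_random_cases(self, rng):
        for _ in range(100):
            n, d = 8, 3
            X = rng.normal(size=(n, d))
            y = np.array([0, 1] * 4)
            k = int(rng.integers(1, 6))
            g_t, g_n = rng.uniform(0.1, 2.0, size=2)
            model = make_model(X, y, k=k, g_t=g_t, g_n=g_n)
            q = rng.normal(size=d)
            d2 = np.sum((X - q) ** 2, axis=1)
            order = np.argsort(d2)
            kth = d2[order[k - 1]]
            sel = d2 <= kth
            tuples = [neighbor_mass(y[i], d2[i], 0.95, g_t if y[i] else g_n)
                      for i in np.flatnonzero(sel)]
            assert classify(model, q) == pytest.approx(dempster_oracle(tuples), abs=1e-9)

    def test_feature_length_mismatch(self):
        model = make_model(np.zeros((4, 3)), np.array([0, 1, 0, 1]), k=2)
        with pytest.raises(InputError):
            classify(model, np.zeros(5))

    def test_reference_order_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([0, 1] * 15)
        model = make_model(X, y, k=5, g_t=0.7, g_n=0.9)
        perm = rng.permutation(30)
        shuffled = make_model(X[perm], y[perm], k=5, g_t=0.7, g_n=0.9)
        Q = rng.normal(size=(10, 4))
        assert np.allclose(classify_batch(model, Q), classify_batch(shuffled, Q),
                           atol=1e-12)

    def test_tied_distances_include_all(self):
        # four references at identical distance; k=1 must include them all
        X = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        y = np.array([1, 1, 0, 0])
        model = make_model(X, y, k=1)
        assert classify(model, np.zeros(2)) == pytest.approx(0.5, abs=1e-12)

    def test_moving_onto_tmh_reference_increases_propensity(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        model = make_model(X, y, k=5, g_t=0.5, g_n=0.5)
        target = X[y == 1][0]
        q = target + np.array([2.0, 0, 0])
        steps = [classify(model, target + (q - target) * t)
                 for t in (1.0, 0.5, 0.0)]
        assert steps[-1] >= steps[0] - 1e-9


class TestTrainOetknn:
    def _clouds(self, rng, n=60, sep=6.0):
        X0 = rng.normal(0, 1, size=(n, 4))
        X1 = rng.normal(0, 1, size=(n, 4)) + sep
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_separated_clouds_low_loo_error(self, rng):
        X, y = self._clouds(rng)
        model = train_oetknn(X, y, k=5, seed=0)
        # leave-one-out on the training corpus with the trained model
        wrong = 0
        for i in range(len(X)):
            sub = OetknnModel(
                reference_vectors=np.delete(X, i, axis=0),
                labels=np.delete(y, i), k=5, alpha0=model.alpha0,
                gamma_tmh=model.gamma_tmh, gamma_non=model.gamma_non)
            wrong += int((classify(sub, X[i]) >= 0.5) != bool(y[i]))
        assert wrong / len(X) <= 0.05

    def test_gamma_search_never_worse_than_init(self, rng):
        from memtopo.propensity import (
            _loo_error,
            _loo_neighbors,
            _mean_squared_pairwise_distance,
        )

        X, y = self._clouds(rng, n=40, sep=1.5)  # overlapping: room to improve
        model = train_oetknn(X, y, k=7, seed=1)
        g_t0 = 1.0 / _mean_squared_pairwise_distance(X[y == 1])
        g_n0 = 1.0 / _mean_squared_pairwise_distance(X[y == 0])
        idx = np.arange(len(X))
        d2, labs = _loo_neighbors(X, y, idx, 7)
        init_err = _loo_error(d2, labs, y, 0.95, g_t0, g_n0)
        final_err = _loo_error(d2, labs, y, 0.95, model.gamma_tmh, model.gamma_non)
        assert final_err <= init_err

    def test_duplicated_references_doubled_k_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        model = train_oetknn(X, y, k=4, seed=0)
        doubled = OetknnModel(
            reference_vectors=np.vstack([X, X]), labels=np.concatenate([y, y]),
            k=8, alpha0=model.alpha0, gamma_tmh=model.gamma_tmh,
            gamma_non=model.gamma_non)
        single = OetknnModel(
            reference_vectors=X, labels=y, k=4, alpha0=model.alpha0,
            gamma_tmh=model.gamma_tmh, gamma_non=model.gamma_non)
        Q = rng.normal(size=(15, 3))
        # duplicating every reference doubles every evidence mass, which
        # squares the per-class residual products; the decision boundary
        # (product comparison) is invariant under squaring, so the hard
        # labels must agree exactly even though the propensities sharpen
        p1 = classify_batch(single, Q)
        p2 = classify_batch(doubled, Q)
        assert np.array_equal(p1 >= 0.5, p2 >= 0.5)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        with pytest.raises(TrainingError):
            train_oetknn(X, np.ones(30, dtype=int), k=3)

    def test_too_few_per_class(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([1] + [0] * 9)
        with pytest.raises(TrainingError):
            train_oetknn(X, y, k=3)

    def test_max_refs_downsampling(self, rng):
        X = rng.normal(size=(500, 3))
        y = (rng.random(500) < 0.5).astype(int)
        model = train_oetknn(X, y, k=3, max_refs=100, seed=0)
        assert len(model.labels) <= 110
        assert set(np.unique(model.labels)) == {0, 1}

    def test_model_persistence_roundtrip(self, rng, tmp_path):
        X, y = self._clouds(rng, n=20)
        model = train_oetknn(X, y, k=3, window_size=13, seed=0)
        p = tmp_path / "m.npz"
        model.save(p)
        back = OetknnModel.load(p)
        Q = rng.normal(size=(5, 4))
        assert np.allclose(classify_batch(model, Q), classify_batch(back, Q))
        assert back.window_size == 13


class TestPredictPropensity:
    def _models(self, rng, windows=(13, 15)):
        models = {}
        for w in windows:
            X = rng.normal(size=(40, w * 20))
            y = np.array([0, 1] * 20)
            models[w] = make_model(X, y, k=3)
        return models

    def test_track_length(self, rng):
        prof = random_profile(rng, 30)
        track = predict_propensity(prof, self._models(rng))
        assert len(track) == 30
        assert np.all(track.values >= 0) and np.all(track.values <= 1)

    def test_mean_of_window_tracks(self, rng, monkeypatch):
        calls = {}

        def fake_classify_batch(model, X):
            v = 0.6 if model.window_size == 13 else 1.0
            calls[model.window_size] = True
            return np.full(len(X), v)

        prof = random_profile(rng, 10)
        models = self._models(rng)
        models[13].window_size = 13
        models[15].window_size = 15
        monkeypatch.setattr(propensity, "classify_batch", fake_classify_batch)
        track = predict_propensity(prof, models)
        assert np.allclose(track.values, 0.8)

    def test_missing_model_rejected(self, rng):
        prof = random_profile(rng, 10)
        with pytest.raises(ConfigError):
            predict_propensity(prof, self._models(rng, windows=(13,)),
                               WindowConfig(sizes=(13, 15)))


class TestMassAssignmentInvariants:
    def test_masses_must_sum_to_one(self):
        with pytest.raises(InputError):
            MassAssignment(m_tmh=0.5, m_non=0.5, m_theta=0.5)

    def test_negative_mass_rejected(self):
        with pytest.raises(InputError):
            MassAssignment(m_tmh=-0.1, m_non=0.6, m_theta=0.5)
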