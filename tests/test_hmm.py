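"""Supervised HMM estimation and Viterbi/posterior decoding.

Decoding is checked against exhaustive path enumeration: for two states and
T scans there are 2^T candidate paths, each scored directly as
pi * prod(a) * prod(b), which is tractable for T <= 10.
"""

import itertools

import numpy as np
import pytest

from octcyst.errors import DegenerateError, DimensionError, ParameterError
from octcyst.hmm import (
    CystHMM,
    HmmParams,
    emission_score,
    estimate_patient_params,
    posterior_scores,
    train,
    viterbi,
)
from octcyst.synthetic import generate_patient_sequences

from conftest import make_sim_spec

# ---------------------------------------------------------------------------
# oracles


def path_score(path, params, obs_probs):
    """Linear-domain probability of one hidden path.  ``obs_probs`` is the
    (2, T) matrix of per-state emission scores."""
    p = params.pi[path[0]] * obs_probs[path[0], 0]
    for t in range(1, len(path)):
        p *= params.A[path[t - 1], path[t]] * obs_probs[path[t], t]
    return p


def brute_force_decode(params, observations):
    """Best path by exhaustive enumeration; ties resolved like the decoder
    (prefer state 1 = index 0, scanning in lexicographic path order)."""
    w = np.abs(observations)
    w = w / w.sum(axis=1, keepdims=True)
    obs_probs = params.B @ w.T
    T = observations.shape[0]
    best, best_p = None, -1.0
    for path in itertools.product((0, 1), repeat=T):
        p = path_score(path, params, obs_probs)
        if p > best_p + 1e-15 * max(best_p, 1e-300):
            best, best_p = path, p
    return np.array(best) + 1, best_p


def brute_force_posterior(params, observations):
    w = np.abs(observations)
    w = w / w.sum(axis=1, keepdims=True)
    obs_probs = params.B @ w.T
    T = observations.shape[0]
    num = np.zeros(T)
    den = 0.0
    for path in itertools.product((0, 1), repeat=T):
        p = path_score(path, params, obs_probs)
        den += p
        for t, s in enumerate(path):
            if s == 0:
                num[t] += p
    return num / den


def random_params(rng, K):
    A = rng.dirichlet(np.ones(2), size=2)
    B = rng.dirichlet(np.ones(K), size=2)
    pi = rng.dirichlet(np.ones(2))
    return HmmParams(A=A, B=B, pi=pi)


# ---------------------------------------------------------------------------
# per-patient estimation


class TestEstimatePatientParams:
    def test_alternating_labels_hand_count(self):
        """labels [2,1,2]: one 2->1 and one 1->2 transition."""
        obs = np.ones((3, 4))
        est = estimate_patient_params([2, 1, 2], obs)
        assert np.allclose(est.A, [[0, 1], [1, 0]])
        assert np.allclose(est.pi, [0, 1])

    def test_single_state_fallback_row(self):
        est = estimate_patient_params([1, 1, 1], np.ones((3, 4)))
        assert np.allclose(est.A[0], [1, 0])
        assert np.allclose(est.A[1], [0.5, 0.5])
        assert est.fallback_A == (2,)
        assert est.fallback_B == (2,)
        assert np.allclose(est.B[1], 0.25)

    def test_absolute_value_then_normalise(self):
        """Cystic observations (1,3) and (-3,1): |.| sums to (4,4) -> (0.5, 0.5)."""
        est = estimate_patient_params([1, 1], np.array([[1.0, 3.0], [-3.0, 1.0]]))
        assert np.allclose(est.B[0], [0.5, 0.5])

    def test_rows_stochastic(self, rng):
        labels = rng.integers(1, 3, size=20)
        obs = rng.random((20, 6))
        est = estimate_patient_params(labels, obs)
        assert np.allclose(est.A.sum(axis=1), 1)
        assert np.allclose(est.B.sum(axis=1), 1)
        assert np.isclose(est.pi.sum(), 1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DegenerateError):
            estimate_patient_params([], np.empty((0, 3)))

    def test_zero_mass_emission_rejected(self):
        with pytest.raises(DegenerateError):
            estimate_patient_params([1, 2], np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestTrain:
    def test_single_patient_identity(self, rng):
        labels = np.array([1, 2, 1, 1])
        obs = rng.random((4, 5))
        est = estimate_patient_params(labels, obs)
        params = train([(labels, obs)])
        assert np.allclose(params.A, est.A)
        assert np.allclose(params.B, est.B)
        assert np.allclose(params.pi, est.pi)

    def test_mean_of_patient_matrices(self):
        # patient 1 alternates, patient 2 stays put
        obs = np.ones((4, 3))
        p1 = ([1, 2, 1, 2], obs)
        p2 = ([1, 1, 2, 2], obs)
        params = train([p1, p2])
        A1 = estimate_patient_params(*p1).A
        A2 = estimate_patient_params(*p2).A
        assert np.allclose(params.A, (A1 + A2) / 2)

    def test_pi_mean_of_one_hots(self):
        obs = np.ones((2, 3))
        data = [([1, 1], obs), ([2, 2], obs), ([1, 2], obs), ([2, 1], obs)]
        params = train(data)
        assert np.allclose(params.pi, [0.5, 0.5])

    def test_mean_preserves_stochastic_rows(self, rng):
        spec = make_sim_spec(seed=3, n_patients=30, T=12)
        params = train(generate_patient_sequences(spec))
        assert np.allclose(params.A.sum(axis=1), 1, atol=1e-9)
        assert np.allclose(params.B.sum(axis=1), 1, atol=1e-9)
        assert np.isclose(params.pi.sum(), 1, atol=1e-9)

    def test_inconsistent_K_rejected(self):
        with pytest.raises(DimensionError):
            train([([1, 2], np.ones((2, 3))), ([1, 2], np.ones((2, 4)))])

    def test_no_patients_rejected(self):
        with pytest.raises(DegenerateError):
            train([])


class TestEmissionScore:
    def test_uniform_row_gives_one_over_K(self, rng):
        K = 8
        o = rng.standard_normal(K)
        assert np.isclose(emission_score(np.full(K, 1 / K), o), 1 / K)

    def test_one_hot_observation_picks_entry(self, rng):
        B_row = rng.dirichlet(np.ones(5))
        o = np.zeros(5)
        o[3] = 7.0
        assert np.isclose(emission_score(B_row, o), B_row[3])

    def test_matches_direct_sum(self, rng):
        B_row = rng.dirichlet(np.ones(3))
        o = rng.standard_normal(3)
        expected = sum(B_row[k] * abs(o[k]) for k in range(3)) / np.abs(o).sum()
        assert np.isclose(emission_score(B_row, o), expected)

    def test_zero_observation_rejected(self):
        with pytest.raises(DegenerateError):
            emission_score(np.array([0.5, 0.5]), np.zeros(2))


# ---------------------------------------------------------------------------
# decoding


class TestViterbi:
    def test_single_scan_decided_by_pi(self, rng):
        params = HmmParams(A=np.full((2, 2), 0.5), B=rng.dirichlet(np.ones(4), 2),
                           pi=np.array([1.0, 0.0]))
        assert viterbi(params, rng.random((1, 4))).qP.tolist() == [1]

    def test_small_case_equals_enumeration(self):
        params = HmmParams(
            A=np.array([[0.9, 0.1], [0.2, 0.8]]),
            B=np.array([[0.8, 0.2], [0.3, 0.7]]),
            pi=np.array([1.0, 0.0]),
        )
        obs = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        expected, _ = brute_force_decode(params, obs)
        assert np.array_equal(viterbi(params, obs).qP, expected)

    def test_random_instances_equal_enumeration(self):
        """Seeded random (A, B, pi, obs) with T <= 10, K <= 5: decoded path
        always equals the exhaustive 2^T maximiser."""
        for seed in range(40):
            rng = np.random.default_rng(seed)
            K = int(rng.integers(2, 6))
            T = int(rng.integers(1, 11))
            params = random_params(rng, K)
            obs = rng.random((T, K)) + 1e-3
            expected, best_p = brute_force_decode(params, obs)
            tr = viterbi(params, obs)
            assert np.array_equal(tr.qP, expected), f"seed {seed}"
            # log-domain terminal score equals the linear-domain maximum
            assert np.isclose(np.exp(tr.delta[:, -1].max()), best_p, rtol=1e-9)

    def test_all_ties_resolve_to_state_one(self):
        params = HmmParams(
            A=np.full((2, 2), 0.5),
            B=np.array([[0.5, 0.5], [0.5, 0.5]]),
            pi=np.array([0.5, 0.5]),
        )
        obs = np.ones((5, 2))
        assert (viterbi(params, obs).qP == 1).all()

    def test_trellis_shapes(self, rng):
        params = random_params(rng, 4)
        tr = viterbi(params, rng.random((7, 4)))
        assert tr.delta.shape == (2, 7) and tr.phi.shape == (2, 7)
        assert (tr.phi[:, 0] == 0).all()
        assert set(np.unique(tr.qP)) <= {1, 2}

    def test_dimension_mismatch_rejected(self, rng):
        params = random_params(rng, 4)
        with pytest.raises(DimensionError):
            viterbi(params, rng.random((5, 3)))


class TestPosterior:
    def test_absorbing_chain_posterior_one(self, rng):
        params = HmmParams(A=np.eye(2), B=rng.dirichlet(np.ones(4), 2),
                           pi=np.array([1.0, 0.0]))
        post = posterior_scores(params, rng.random((6, 4)) + 0.1)
        assert np.allclose(post, 1.0)

    def test_single_scan_is_bayes_rule(self, rng):
        params = random_params(rng, 4)
        o = rng.random((1, 4)) + 0.1
        w = np.abs(o[0]) / np.abs(o[0]).sum()
        b = params.B @ w
        expected = params.pi[0] * b[0] / (params.pi @ b)
        assert np.isclose(posterior_scores(params, o)[0], expected)

    def test_matches_exhaustive_marginalisation(self):
        """T = 4: smoothed posteriors equal the brute-force sum over all 16
        hidden paths."""
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            params = random_params(rng, 3)
            obs = rng.random((4, 3)) + 1e-3
            expected = brute_force_posterior(params, obs)
            got = posterior_scores(params, obs)
            assert np.allclose(got, expected, atol=1e-10), f"seed {seed}"

    def test_values_in_unit_interval(self, rng):
        params = random_params(rng, 5)
        post = posterior_scores(params, rng.random((20, 5)) + 1e-3)
        assert (post >= 0).all() and (post <= 1).all()


# ---------------------------------------------------------------------------
# model/results surface


class TestCystHMM:
    def test_parameter_recovery_from_simulation(self):
        """Supervised averaging over 200 simulated patients recovers the
        generator's transition and emission parameters."""
        spec = make_sim_spec(seed=1, n_patients=200, T=31, K=20, obs_total=500,
                             a11=0.7, a22=0.7)
        res = CystHMM(generate_patient_sequences(spec)).fit()
        assert np.abs(res.transition_matrix - spec.A_true).max() <= 0.05
        assert np.abs(res.emission_matrix - spec.B_true).max() <= 0.05
        assert np.abs(res.initial_probs - spec.pi_true).max() <= 0.05

    def test_from_dataframe_matches_list_construction(self, rng):
        import pandas as pd

        spec = make_sim_spec(seed=6, n_patients=4, T=5, K=3)
        data = generate_patient_sequences(spec)
        rows = []
        for i, (labels, obs) in enumerate(data):
            for t in range(len(labels)):
                rows.append({"patient_id": f"p{i}", "scan_index": t,
                             "label": labels[t],
                             **{f"f{k}": obs[t, k] for k in range(3)}})
        df = pd.DataFrame(rows).sample(frac=1.0, random_state=0)  # shuffled rows
        res_df = CystHMM.from_dataframe(df, [f"f{k}" for k in range(3)]).fit()
        res_li = CystHMM(data).fit()
        assert np.allclose(res_df.transition_matrix, res_li.transition_matrix)
        assert np.allclose(res_df.emission_matrix, res_li.emission_matrix)

    def test_summary_reports_fit(self):
        spec = make_sim_spec(seed=2, n_patients=10, T=8, K=4)
        res = CystHMM(generate_patient_sequences(spec)).fit()
        text = res.summary()
        assert "Transition matrix" in text and "a11=" in text
        assert f"Patients: {res.n_patients}" in text

    def test_simulate_round_trip_shapes(self):
        spec = make_sim_spec(seed=3, n_patients=10, T=8, K=4)
        res = CystHMM(generate_patient_sequences(spec)).fit()
        sims = res.simulate(T=6, n_patients=3, seed=1)
        assert len(sims) == 3
        for states, obs in sims:
            assert len(states) == 6 and obs.shape == (6, 4)

    def test_monotone_persistence_mechanism(self):
        """Raising a11 in the generator raises the decoded probability that a
        scan following a cystic scan is itself called cystic."""
        def decoded_persistence(a11, seed=0):
            spec = make_sim_spec(seed=seed, n_patients=60, T=20, K=10,
                                 obs_total=20, a11=a11, a22=0.8)
            data = generate_patient_sequences(spec)
            res = CystHMM(data[:40], emission_mode="multinomial").fit()
            follow, tot = 0, 0
            for _, obs in data[40:]:
                q = res.decode(obs)
                prev = q[:-1] == 1
                follow += (q[1:][prev] == 1).sum()
                tot += prev.sum()
            return follow / tot

        assert decoded_persistence(0.95) > decoded_persistence(0.55)

    def test_exclude_fallback_rows_option(self):
        obs = np.ones((3, 4))
        data = [([1, 1, 1], obs), ([1, 2, 1], obs)]
        res_incl = CystHMM(data).fit()
        res_excl = CystHMM(data, exclude_fallback_rows=True).fit()
        # patient 1 contributes a uniform row 2 only in the inclusive average
        assert np.allclose(res_excl.transition_matrix[1], [1.0, 0.0])
        assert np.allclose(res_incl.transition_matrix[1], [0.75, 0.25])

    def test_invalid_labels_rejected(self):
        with pytest.raises(ParameterError):
            CystHMM([([0, 1], np.ones((2, 3)))]).fit()

    def test_emission_calibration_centres_training_llr(self):
        """Balanced scaled-likelihood offsets: after calibration, the mean
        training log-likelihood ratios of the two classes are symmetric
        about zero."""
        from octcyst.hmm import _log_emissions

        spec = make_sim_spec(seed=11, n_patients=30, T=12, K=8, obs_total=40)
        data = generate_patient_sequences(spec)
        res = CystHMM(data, emission_mode="multinomial", emission_mass=10,
                      calibrate_emissions=True).fit()
        llr1, llr2 = [], []
        for labels, obs in data:
            llr = np.subtract(*_log_emissions(res.params, obs))
            llr1.extend(llr[labels == 1])
            llr2.extend(llr[labels == 2])
        assert np.isclose(np.mean(llr1) + np.mean(llr2), 0.0, atol=1e-9)
        assert np.mean(llr1) > 0 > np.mean(llr2)

    def test_calibration_requires_multinomial_mode(self):
        spec = make_sim_spec(seed=12, n_patients=4, T=6, K=4)
        with pytest.raises(ParameterError):
            CystHMM(generate_patient_sequences(spec),
                    calibrate_emissions=True).fit()
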