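import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coremix as cm
from conftest import random_sparse_instance

simplex = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=6
).map(lambda xs: np.asarray(xs) / np.sum(xs))


def test_estimate_theta_posterior_mean():
    assert np.allclose(cm.estimate_theta([3, 1], 1.0), [2 / 3, 1 / 3])
    assert np.allclose(cm.estimate_theta([0, 0], 1.0), [0.5, 0.5])


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=8),
    st.floats(min_value=0.01, max_value=10),
)
def test_estimate_theta_normalized(counts, alpha):
    theta = cm.estimate_theta(counts, alpha)
    assert abs(theta.sum() - 1.0) < 1e-9
    assert np.all(theta >= 0)


def test_theta_to_abundance_length_correction():
    assert np.allclose(
        cm.theta_to_abundance([0.5, 0.5], [100, 300]), [0.75, 0.25]
    )
    assert np.allclose(
        cm.theta_to_abundance([0.3, 0.7], [50, 50]), [0.3, 0.7]
    )
    assert cm.theta_to_abundance([1.0], [123]) == pytest.approx([1.0])
    with pytest.raises(ValueError):
        cm.theta_to_abundance([0.5, 0.5], [100, 0])


@settings(deadline=None, derandomize=True)
@given(simplex, st.data())
def test_abundance_theta_bijection(a, data):
    lengths = data.draw(
        st.lists(
            st.integers(min_value=1, max_value=10_000),
            min_size=len(a),
            max_size=len(a),
        )
    )
    theta = cm.abundance_to_theta(a, lengths)
    back = cm.theta_to_abundance(theta, lengths)
    assert np.allclose(back, a, atol=1e-12)
    assert abs(theta.sum() - 1.0) < 1e-9


def test_full_conditional_arithmetic():
    phi = cm.PhiMatrix.from_dense(np.array([[0.2, 0.1]]))
    state = cm.AssignmentState(
        z=np.array([0]),
        n=np.array([3.0, 5.0]),  # counts already exclude the occurrence
        occ_row=np.array([0]),
    )
    probs = cm.full_conditional(0, state, phi, 1.0)
    assert np.allclose(probs, [4 / 7, 3 / 7])


def test_full_conditional_degenerate_and_symmetric():
    phi = cm.PhiMatrix.from_dense(np.array([[0.0, 0.4]]))
    state = cm.AssignmentState(
        z=np.array([1]), n=np.array([2.0, 9.0]), occ_row=np.array([0])
    )
    assert np.allclose(cm.full_conditional(0, state, phi, 1.0), [0, 1])
    phi2 = cm.PhiMatrix.from_dense(np.array([[0.5, 0.5]]))
    state2 = cm.AssignmentState(
        z=np.array([0]), n=np.array([0.0, 0.0]), occ_row=np.array([0])
    )
    assert np.allclose(cm.full_conditional(0, state2, phi2, 2.0), [0.5, 0.5])


def test_initialize_state_forced_and_consistent():
    phi = cm.PhiMatrix.from_dense(
        np.array([[0.0, 1.0], [0.5, 0.5], [0.2, 0.0]])
    )
    table = cm.ReadTable.from_sequences(["a", "b", "c", "a", "b"])
    state = cm.initialize_state(table, phi, seed=3)
    assert state.z[0] == 1 and state.z[3] == 1  # single-candidate reads
    assert state.z[2] == 0
    assert np.array_equal(state.recount(2), state.n)
    again = cm.initialize_state(table, phi, seed=3)
    assert np.array_equal(state.z, again.z)


def test_initialize_state_rejects_uncovered_occurrence():
    phi = cm.PhiMatrix.from_dense(np.array([[0.0, 0.0]]))
    table = cm.ReadTable.from_sequences(["a"])
    with pytest.raises(ValueError, match="no candidate"):
        cm.initialize_state(table, phi, seed=0)


def test_unambiguous_reads_give_closed_form_exactly():
    """With one candidate per read the chain is frozen and θ̂ is the
    conjugate posterior mean applied to the raw counts."""
    phi = cm.PhiMatrix.from_dense(
        np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    )
    seqs = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
    table = cm.ReadTable.from_sequences(seqs)
    lengths = [100, 200, 400]
    cfg = cm.GibbsConfig(burn_in_sweeps=10, kept_samples=50, seed=7)
    summary = cm.run_gibbs(table, phi, 1.0, cfg, lengths)
    n = np.array([5.0, 3.0, 2.0])
    theta_expected = (n + 1.0) / (10.0 + 3.0)
    assert np.array_equal(summary.mean_counts, n)
    assert np.array_equal(summary.theta_hat, theta_expected)
    w = theta_expected / np.array(lengths)
    assert np.array_equal(summary.abundance_hat, w / w.sum())


def test_run_gibbs_deterministic_for_fixed_seed(small_profile):
    table, phi, refset, _ = small_profile
    cfg = cm.GibbsConfig(burn_in_sweeps=50, kept_samples=100, seed=9)
    a = cm.run_gibbs(table, phi, 1.0, cfg, refset.lengths)
    b = cm.run_gibbs(table, phi, 1.0, cfg, refset.lengths)
    assert np.array_equal(a.mean_counts, b.mean_counts)
    assert np.array_equal(a.abundance_hat, b.abundance_hat)


def test_count_conservation_every_kept_sample(small_profile):
    table, phi, refset, _ = small_profile
    cfg = cm.GibbsConfig(
        burn_in_sweeps=20, kept_samples=40, seed=2, keep_trace=True
    )
    summary = cm.run_gibbs(table, phi, 1.0, cfg, refset.lengths)
    sums = summary.sample_trace.sum(axis=1)
    assert np.all(sums == summary.n_assigned)


def _oracle_by_hand(table, phi_dense, alpha):
    """Independent enumeration with explicit Γ arithmetic."""
    N, M = table.N, phi_dense.shape[1]
    rows = phi_dense[table.occurrence_index]
    weights, counts = [], []
    for z in itertools.product(range(M), repeat=N):
        w = 1.0
        for i, zi in enumerate(z):
            w *= rows[i, zi]
        n = [z.count(m) for m in range(M)]
        delta = math.prod(
            math.gamma(n[m] + alpha) for m in range(M)
        ) / math.gamma(sum(n) + M * alpha)
        weights.append(w * delta)
        counts.append(n)
    weights = np.asarray(weights)
    weights /= weights.sum()
    return weights @ np.asarray(counts, dtype=float)


def test_oracle_matches_hand_enumeration():
    phi = np.array([[0.6, 0.4], [0.1, 0.9], [0.5, 0.5]])
    table = cm.ReadTable.from_sequences(["a", "b", "c"])
    oracle = cm.exact_posterior_oracle(table, cm.PhiMatrix.from_dense(phi), 1.0)
    expected = _oracle_by_hand(table, phi, 1.0)
    assert np.allclose(oracle.expected_counts, expected, atol=1e-12)
    assert oracle.probabilities.sum() == pytest.approx(1.0)


def test_oracle_single_read_collapses_to_phi():
    phi = cm.PhiMatrix.from_dense(np.array([[0.3, 0.7]]))
    table = cm.ReadTable.from_sequences(["a"])
    oracle = cm.exact_posterior_oracle(table, phi, 1.0)
    assert np.allclose(oracle.expected_counts, [0.3, 0.7])
    assert oracle.prob_of([1]) == pytest.approx(0.7)


def test_oracle_symmetry_uniform():
    phi = cm.PhiMatrix.from_dense(np.full((2, 3), 0.25))
    table = cm.ReadTable.from_sequences(["a", "b"])
    oracle = cm.exact_posterior_oracle(table, phi, 2.0)
    assert np.allclose(oracle.expected_counts, [2 / 3, 2 / 3, 2 / 3])


def test_oracle_rejects_large_instance():
    phi = cm.PhiMatrix.from_dense(np.full((1, 4), 0.25))
    table = cm.ReadTable.from_sequences(["a"] * 12)
    with pytest.raises(ValueError, match="run_gibbs"):
        cm.exact_posterior_oracle(table, phi, 1.0, max_states=10**5)


def test_oracle_label_equivariance():
    rng = np.random.default_rng(0)
    table, phi = random_sparse_instance(rng, M=3, N=5)
    dense = phi.matrix.toarray()
    perm = np.array([2, 0, 1])
    permuted = cm.PhiMatrix.from_dense(dense[:, perm])
    base = cm.exact_posterior_oracle(table, phi, 1.0)
    swapped = cm.exact_posterior_oracle(table, permuted, 1.0)
    assert np.allclose(
        swapped.expected_counts, base.expected_counts[perm], atol=1e-12
    )


def test_gibbs_converges_to_oracle_small_instance():
    rng = np.random.default_rng(123)
    table, phi = random_sparse_instance(rng, M=2, N=4)
    oracle = cm.exact_posterior_oracle(table, phi, 1.0)
    cfg = cm.GibbsConfig(burn_in_sweeps=2000, kept_samples=20000, seed=4)
    summary = cm.run_gibbs(table, phi, 1.0, cfg, [1.0, 1.0])
    # 3 Monte-Carlo standard errors at 20,000 kept samples, conservatively
    # ignoring autocorrelation would be ~0.02; allow 0.05 for mixing
    assert np.abs(summary.mean_counts - oracle.expected_counts).max() < 0.05


def test_aggregate_abundance_roll_up():
    a = {"strain1": 0.3, "strain2": 0.2, "strain3": 0.5}
    taxa = {"strain1": "spX", "strain2": "spX", "strain3": "spY"}
    rolled = cm.aggregate_abundance(a, taxa)
    assert rolled == pytest.approx({"spX": 0.5, "spY": 0.5})
    identity = cm.aggregate_abundance(a, {k: k for k in a})
    assert identity == pytest.approx(a)
    one = cm.aggregate_abundance(a, {k: "all" for k in a})
    assert one["all"] == pytest.approx(1.0)
    with pytest.raises(KeyError, match="strain3"):
        cm.aggregate_abundance(a, {"strain1": "spX", "strain2": "spX"})


def test_posterior_normalisation(small_profile):
    table, phi, refset, _ = small_profile
    cfg = cm.GibbsConfig(burn_in_sweeps=50, kept_samples=100, seed=1)
    s = cm.run_gibbs(table, phi, [0.5, 1.0, 2.0, 1.0], cfg, refset.lengths)
    assert abs(s.theta_hat.sum() - 1.0) < 1e-9
    assert abs(s.abundance_hat.sum() - 1.0) < 1e-9
    assert np.all(s.theta_hat >= 0) and np.all(s.abundance_hat >= 0)


def test_detected_only_renormalises():
    phi = cm.PhiMatrix.from_dense(np.array([[1.0, 0.0, 0.0]]))
    table = cm.ReadTable.from_sequences(["a", "a"])
    cfg = cm.GibbsConfig(burn_in_sweeps=5, kept_samples=10, seed=0)
    s = cm.run_gibbs(table, phi, 1.0, cfg, [10, 10, 10])
    assert np.all(s.theta_hat > 0)  # undetected keep prior mass
    d = s.detected_only()
    assert d.theta_hat[1] == d.theta_hat[2] == 0.0
    assert d.theta_hat[0] == 1.0
    assert abs(d.abundance_hat.sum() - 1.0) < 1e-9
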