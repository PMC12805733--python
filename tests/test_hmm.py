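"""Behavioural-state HMM: discretization, exact-inference oracles, Gibbs."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mosaicmove as mm
from mosaicmove.hmm import (
    Burst,
    _emission_matrix,
    _label_permutation,
)
from mosaicmove.synthetic import DEFAULT_HMM_PARAMS

SCHEME = mm.DiscretizationScheme()


def _random_params(rng):
    pi = rng.dirichlet(np.ones(2))
    phi = np.vstack([rng.dirichlet(np.ones(2)) for _ in range(2)])
    lam_s = np.vstack([rng.dirichlet(np.ones(8)) for _ in range(2)])
    lam_a = np.vstack([rng.dirichlet(np.ones(8)) for _ in range(2)])
    return pi, phi, lam_s, lam_a


def _random_burst(rng, t_len):
    sbin = rng.integers(0, 8, t_len)
    abin = rng.integers(0, 8, t_len)
    abin[0] = -1
    return Burst("x", [f"x:{i}" for i in range(t_len)], sbin, abin)


def _enumeration_marginals(burst, pi, phi, lam_s, lam_a):
    """Brute-force posterior state marginals over all 2^T sequences."""
    b = _emission_matrix(burst, lam_s, lam_a)
    t_len = len(burst)
    probs = np.zeros((t_len, 2))
    total = 0.0
    for z in itertools.product((0, 1), repeat=t_len):
        p = pi[z[0]] * b[0, z[0]]
        for t in range(1, t_len):
            p *= phi[z[t - 1], z[t]] * b[t, z[t]]
        total += p
        for t in range(t_len):
            probs[t, z[t]] += p
    return probs / total


# -- discretization ----------------------------------------------------------

@pytest.mark.parametrize(
    "d, expected",
    [(15.0, 0), (30.0, 1), (0.0, 0), (209.9, 6), (210.0, 7), (511.9, 7), (512.0, 7), (900.0, 7)],
)
def test_step_bin_boundaries_half_open(d, expected):
    assert SCHEME.step_bin(np.array([d]))[0] == expected


def test_angle_bin_edges_and_missing():
    bins = SCHEME.angle_bin(np.array([-np.pi, np.pi - 1e-9, np.pi, np.nan]))
    assert bins.tolist() == [0, 7, 7, -1]


def test_bin_counts_match_histogram_oracle():
    rng = np.random.default_rng(0)
    d = rng.uniform(0, 600, 10_000)
    bins = SCHEME.step_bin(d)
    edges = list(SCHEME.step_breaks) + [np.inf]
    oracle, _ = np.histogram(d, bins=edges)
    oracle[7] += oracle[8] if len(oracle) > 8 else 0
    expected = np.histogram(np.minimum(d, 511.999), bins=SCHEME.step_breaks)[0]
    assert np.array_equal(np.bincount(bins, minlength=8), expected)


def test_discretize_splits_bursts_at_removed_steps():
    ts = pd.Timestamp("2018-01-01T00:00:00Z") + pd.to_timedelta(
        np.arange(7) * 20, unit="m"
    )
    traj = mm.Trajectory(
        "b", fixes=pd.DataFrame({"timestamp": ts, "x": 50.0 * np.arange(7), "y": 0.0})
    )
    steps = mm.build_steps(traj)
    steps.loc[2, "removed_speed"] = True
    bursts = mm.discretize(steps)
    assert [len(b) for b in bursts] == [2, 3]
    # the first step of each burst has no turning angle
    assert all(b.angle_bin[0] == -1 for b in bursts)


def test_negative_length_rejected():
    df = pd.DataFrame(
        {
            "individual_id": ["a"], "step_id": ["a:0"], "fix_index": [0],
            "d": [-1.0], "theta": [np.nan], "t_min": [20.0],
            "removed_speed": [False], "removed_gap": [False],
        }
    )
    with pytest.raises(ValueError):
        mm.discretize(df)


# -- exact inference oracles -------------------------------------------------

def test_forward_backward_matches_enumeration_at_t8():
    rng = np.random.default_rng(1)
    for _ in range(5):
        burst = _random_burst(rng, 8)
        pi, phi, lam_s, lam_a = _random_params(rng)
        b = _emission_matrix(burst, lam_s, lam_a)
        gamma, _ = mm.forward_backward(b, pi, phi)
        oracle = _enumeration_marginals(burst, pi, phi, lam_s, lam_a)
        assert np.max(np.abs(gamma - oracle)) < 1e-10


def test_decode_matches_enumeration(mosaic_landscape):
    rng = np.random.default_rng(2)
    burst = _random_burst(rng, 8)
    pi, phi, lam_s, lam_a = _random_params(rng)
    dec = mm.decode([burst], pi, phi, lam_s, lam_a)
    oracle = _enumeration_marginals(burst, pi, phi, lam_s, lam_a)
    assert np.allclose(dec["p_active"].to_numpy(), oracle[:, 1], atol=1e-10)


def test_ffbs_frequencies_match_enumeration():
    """Sampled state paths at fixed parameters reproduce the exact
    marginals within Monte-Carlo error (sampler-correctness check)."""
    rng = np.random.default_rng(3)
    burst = _random_burst(rng, 6)
    pi, phi, lam_s, lam_a = _random_params(rng)
    b = _emission_matrix(burst, lam_s, lam_a)
    n_draws = 20_000
    freq = np.zeros(6)
    for _ in range(n_draws):
        z, _ = mm.ffbs(b, pi, phi, rng)
        freq += z
    freq /= n_draws
    oracle = _enumeration_marginals(burst, pi, phi, lam_s, lam_a)[:, 1]
    se = np.sqrt(oracle * (1 - oracle) / n_draws)
    assert np.all(np.abs(freq - oracle) < 4 * np.maximum(se, 1e-3))


def test_decode_uninformative_model_returns_prior_marginals():
    """Uniform emissions carry no information: P(active) is the chain's
    prior marginal — pi_active at the first step, the uniform-transition
    stationary value (1/2) thereafter."""
    burst = _random_burst(np.random.default_rng(4), 10)
    pi = np.array([0.3, 0.7])
    phi = np.full((2, 2), 0.5)
    lam = np.full((2, 8), 1 / 8)
    dec = mm.decode([burst], pi, phi, lam, lam)
    assert dec["p_active"].iloc[0] == pytest.approx(0.7, abs=1e-12)
    assert np.allclose(dec["p_active"].iloc[1:], 0.5, atol=1e-12)
    stat = mm.decode([burst], np.array([0.5, 0.5]), phi, lam, lam)
    assert np.allclose(stat["p_active"], 0.5, atol=1e-12)


# -- Gibbs sampler -----------------------------------------------------------

def test_fixed_states_give_closed_form_dirichlet_moments():
    """With latent states pinned, emission rows are conjugate Dirichlet."""
    rng = np.random.default_rng(5)
    t_len = 400
    z = rng.integers(0, 2, t_len).astype(np.int8)
    sbin = np.where(z == 0, rng.integers(0, 3, t_len), rng.integers(3, 8, t_len))
    abin = rng.integers(0, 8, t_len)
    abin[0] = -1
    burst = Burst("x", [f"x:{i}" for i in range(t_len)], sbin, abin)
    fit = mm.fit_hmm_gibbs(
        [burst], n_iter=4000, n_burn=500, seed=7, fixed_states=[z]
    )
    counts = np.zeros((2, 8))
    np.add.at(counts, (z, sbin), 1)
    # states are relabeled: resting (index 0) is the short-step state here
    expected = (1.0 + counts) / (8.0 + counts.sum(axis=1, keepdims=True))
    got = fit.draws["lam_step"].mean(axis=0)
    assert np.max(np.abs(got - expected)) < 0.02


def test_every_stored_row_is_a_probability_vector():
    rng = np.random.default_rng(6)
    burst = _random_burst(rng, 300)
    fit = mm.fit_hmm_gibbs([burst], n_iter=200, n_burn=100, seed=1)
    assert np.allclose(fit.draws["pi"].sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(fit.draws["Phi"].sum(axis=2), 1.0, atol=1e-12)
    assert np.allclose(fit.draws["lam_step"].sum(axis=2), 1.0, atol=1e-12)
    assert np.allclose(fit.draws["lam_angle"].sum(axis=2), 1.0, atol=1e-12)
    assert np.all((fit.draws["Phi"] >= 0) & (fit.draws["Phi"] <= 1))


def test_loglik_trace_finite_and_geweke_in_range(clean_steps):
    bursts = mm.discretize(clean_steps)
    fit = mm.fit_hmm_gibbs(bursts, n_iter=600, n_burn=300, seed=2)
    assert np.all(np.isfinite(fit.loglik_trace))
    assert abs(mm.geweke_z(fit.loglik_trace[fit.n_burn :])) < 3.0


def test_burst_order_does_not_change_posterior():
    rng = np.random.default_rng(8)
    p = DEFAULT_HMM_PARAMS
    bursts = []
    for i in range(4):
        t_len = 400
        z = np.empty(t_len, int)
        z[0] = rng.choice(2)
        phi = np.array(p["Phi"])
        for t in range(1, t_len):
            z[t] = rng.choice(2, p=phi[z[t - 1]])
        sbin = np.array([rng.choice(8, p=np.array(p["lam_step"])[s]) for s in z])
        abin = np.array([rng.choice(8, p=np.array(p["lam_angle"])[s]) for s in z])
        abin[0] = -1
        bursts.append(Burst("x", [f"x:{i}:{t}" for t in range(t_len)], sbin, abin))
    f1 = mm.fit_hmm_gibbs(bursts, n_iter=600, n_burn=300, seed=3)
    f2 = mm.fit_hmm_gibbs(bursts[::-1], n_iter=600, n_burn=300, seed=3)
    assert np.allclose(
        f1.draws["Phi"].mean(axis=0), f2.draws["Phi"].mean(axis=0), atol=0.05
    )


def test_single_bin_data_warns_but_runs():
    burst = Burst("x", ["x:0", "x:1", "x:2"], np.zeros(3, int), np.array([-1, 2, 3]))
    with pytest.warns(UserWarning, match="single step bin"):
        fit = mm.fit_hmm_gibbs([burst], n_iter=100, n_burn=50, seed=0)
    assert np.all(np.isfinite(fit.loglik_trace))


def test_modal_state_recovery_well_separated():
    rng = np.random.default_rng(10)
    p = DEFAULT_HMM_PARAMS
    phi = np.array(p["Phi"])
    t_len = 1500
    z = np.empty(t_len, int)
    z[0] = 0
    for t in range(1, t_len):
        z[t] = rng.choice(2, p=phi[z[t - 1]])
    sbin = np.array([rng.choice(8, p=np.array(p["lam_step"])[s]) for s in z])
    abin = np.array([rng.choice(8, p=np.array(p["lam_angle"])[s]) for s in z])
    abin[0] = -1
    burst = Burst("x", [f"x:{t}" for t in range(t_len)], sbin, abin)
    fit = mm.fit_hmm_gibbs([burst], n_iter=600, n_burn=300, seed=4)
    modal = (fit.state_probs["p_active_sampled"] >= 0.5).astype(int).to_numpy()
    assert (modal == z).mean() >= 0.9


# -- label switching ---------------------------------------------------------

def test_labeling_by_expected_step_bin():
    lam = np.array([[0.0] * 5 + [1.0, 0.0, 0.0], [1.0] + [0.0] * 7])
    perm = _label_permutation(lam)
    assert perm.tolist() == [1, 0]  # bin-1-concentrated state becomes resting


def test_label_states_permutation_invariant_and_idempotent():
    rng = np.random.default_rng(9)
    n = 50
    draws = {
        "pi": rng.dirichlet(np.ones(2), n),
        "Phi": np.stack([np.vstack([rng.dirichlet(np.ones(2)) for _ in range(2)]) for _ in range(n)]),
        "lam_step": np.stack([np.vstack([rng.dirichlet(np.ones(8)) for _ in range(2)]) for _ in range(n)]),
        "lam_angle": np.stack([np.vstack([rng.dirichlet(np.ones(8)) for _ in range(2)]) for _ in range(n)]),
    }
    flipped = {
        "pi": draws["pi"][:, ::-1],
        "Phi": draws["Phi"][:, ::-1, :][:, :, ::-1],
        "lam_step": draws["lam_step"][:, ::-1, :],
        "lam_angle": draws["lam_angle"][:, ::-1, :],
    }
    a = mm.label_states(draws)
    b = mm.label_states(flipped)
    for key in a:
        assert np.allclose(a[key], b[key])
        assert np.allclose(mm.label_states(a)[key], a[key])  # idempotent
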